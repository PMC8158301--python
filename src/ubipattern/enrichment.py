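"""Single-sample gene-set enrichment (ssGSEA) and pattern characterization.

The enrichment statistic for a set S in one sample walks the genes in
decreasing-expression order and accumulates, at every position, the
difference between the weighted in-set ECDF (weights = rank^alpha, ranks
assigned ascending with ties averaged) and the uniform out-of-set ECDF.
One engine serves both immune-cell abundance and pathway-signature scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ubipattern.consensus import PatternAssignment
from ubipattern.io import GeneSetCollection


class EnrichmentError(ValueError):
    pass


def _sample_es(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment statistic for one sample; ``in_set`` is a boolean mask."""
    order = np.argsort(-values, kind="stable")
    ranks = stats.rankdata(values)  # ascending, ties -> average rank
    s = in_set[order]
    w = np.where(s, ranks[order] ** alpha, 0.0)
    n_out = len(values) - int(in_set.sum())
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~s) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Score every gene set in every sample.

    With ``normalize`` the whole score matrix is divided by its global
    (max - min), the conventional ssGSEA normalization; otherwise raw
    statistics are returned.
    """
    universe = pd.Index(expr.index)
    masks: dict[str, np.ndarray] = {}
    for name in sets:
        mask = universe.isin(sets[name])
        if not mask.any():
            raise EnrichmentError(f"gene set {name!r} shares no genes with the matrix")
        if mask.all():
            raise EnrichmentError(f"gene set {name!r} covers the entire gene universe")
        masks[name] = mask

    x = expr.to_numpy(dtype=float)
    scores = np.empty((len(masks), x.shape[1]))
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(-col, kind="stable")
        ranks = stats.rankdata(col)
        ranked_w = ranks[order] ** alpha
        for i, name in enumerate(masks):
            s = masks[name][order]
            w = np.where(s, ranked_w, 0.0)
            n_out = len(col) - int(masks[name].sum())
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~s) / n_out
            scores[i, j] = np.sum(p_in - p_out)

    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return pd.DataFrame(scores, index=pd.Index(list(masks), name="gene_set"),
                        columns=expr.columns)


def characterize_patterns(
    enr: pd.DataFrame,
    labels: PatternAssignment | pd.Series,
    diff_threshold: float = 0.15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Welch t-test of enrichment scores per (pattern, set).

    A pair is flagged when the pattern-vs-rest mean difference exceeds
    ``diff_threshold`` and the BH-adjusted p (across sets, within the
    pattern) is below ``alpha``.
    """
    lab = labels.labels if isinstance(labels, PatternAssignment) else labels
    lab = lab.astype(str)
    missing = [s for s in enr.columns if s not in lab.index]
    if missing:
        raise EnrichmentError(f"samples without a pattern label: {missing}")
    lab = lab.loc[enr.columns]
    counts = lab.value_counts()
    small = sorted(counts.index[counts < 2])
    if small:
        raise EnrichmentError(f"pattern(s) with < 2 samples: {small}")

    rows = []
    for pattern in sorted(lab.unique()):
        in_mask = (lab == pattern).to_numpy()
        if (~in_mask).sum() < 2:
            raise EnrichmentError(
                f"pattern {pattern!r} leaves < 2 samples on the rest side"
            )
        xin = enr.to_numpy()[:, in_mask]
        xout = enr.to_numpy()[:, ~in_mask]
        diff = xin.mean(axis=1) - xout.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(xin, xout, axis=1, equal_var=False)
        p = np.clip(np.nan_to_num(np.asarray(p, dtype=float), nan=1.0), 0.0, 1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]
        for i, gene_set in enumerate(enr.index):
            rows.append(
                {
                    "pattern": pattern,
                    "gene_set": gene_set,
                    "mean_diff": diff[i],
                    "p": p[i],
                    "p_adj": p_adj[i],
                    "flagged": bool(diff[i] > diff_threshold and p_adj[i] < alpha),
                }
            )
    return pd.DataFrame(rows)
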