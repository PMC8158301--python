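"""MAD filtering, Welch-t differential expression, and cohort intersection."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class DEError(ValueError):
    pass


def mad_filter(expr: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Drop low-variability genes by unscaled median absolute deviation.

    A gene is retained only when median(|x - median(x)|) is strictly greater
    than ``threshold``; genes at or below the cutoff are excluded.  No
    consistency constant is applied.
    """
    if expr.empty:
        raise DEError("expression matrix is empty")
    med = expr.median(axis=1)
    mad = (expr.sub(med, axis=0)).abs().median(axis=1)
    keep = mad > threshold
    if not keep.any():
        raise DEError(
            f"MAD filter at threshold {threshold} removed every gene; "
            "lower the threshold or check the input scale"
        )
    return expr.loc[keep]


def two_group_de(expr: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene Welch t-test between two sample groups on log-scale values.

    Parameters
    ----------
    groups
        Maps sample id to one of exactly two group labels.  logFC is
        group2 minus group1 means where groups are taken in sorted label
        order, so callers with tumor/normal labels get tumor - normal.

    Returns
    -------
    DataFrame indexed by gene with columns ``logFC``, ``p``, ``p_adj``,
    ``mean_<g1>``, ``mean_<g2>``.
    """
    groups = groups.astype(str)
    common = [s for s in expr.columns if s in groups.index]
    if len(common) < len(expr.columns):
        missing = sorted(set(expr.columns) - set(common))
        raise DEError(f"samples missing from group map: {missing}")
    labels = sorted(groups.loc[common].unique())
    if len(labels) != 2:
        raise DEError(f"expected exactly 2 groups, got {labels}")
    g1, g2 = labels
    idx1 = [s for s in common if groups[s] == g1]
    idx2 = [s for s in common if groups[s] == g2]
    if len(idx1) < 2 or len(idx2) < 2:
        raise DEError(
            f"each group needs >= 2 samples (got {g1}: {len(idx1)}, {g2}: {len(idx2)})"
        )

    x1 = expr[idx1].to_numpy(dtype=float)
    x2 = expr[idx2].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    logfc = m2 - m1
    # zero variance in both groups: p=1 when means tie, p=0 otherwise
    degenerate = (x1.var(axis=1) == 0) & (x2.var(axis=1) == 0)
    pval = np.asarray(pval, dtype=float)
    pval[degenerate & (m1 == m2)] = 1.0
    pval[degenerate & (m1 != m2)] = 0.0
    logfc[degenerate & (m1 == m2)] = 0.0
    pval = np.clip(np.nan_to_num(pval, nan=1.0), 0.0, 1.0)

    p_adj = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "logFC": logfc,
            "p": pval,
            "p_adj": p_adj,
            f"mean_{g1}": m1,
            f"mean_{g2}": m2,
        },
        index=expr.index,
    )


def intersect_regulators(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    alpha_a: float = 0.01,
    alpha_b: float = 0.05,
    require_same_sign: bool = False,
) -> list[str]:
    """Genes significant in both cohorts at their cohort-specific thresholds.

    Returns the lexicographically sorted intersection.  With
    ``require_same_sign`` the fold-change direction must also agree.
    """
    shared = de_a.index.intersection(de_b.index)
    if shared.empty:
        raise DEError("DE results share no genes")
    a = de_a.loc[shared]
    b = de_b.loc[shared]
    mask = (a["p_adj"] < alpha_a) & (b["p_adj"] < alpha_b)
    if require_same_sign:
        mask &= np.sign(a["logFC"]) == np.sign(b["logFC"])
    hits = sorted(shared[mask])
    if not hits:
        log.warning("regulator intersection is empty at alpha_a=%s, alpha_b=%s",
                    alpha_a, alpha_b)
    return hits
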