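"""Signature-gene selection and the per-sample PC1-difference score.

Genes are split into positive and negative pools by Pearson correlation with
the ordinal pattern encoding, each pool is reduced with a Boruta-style
all-relevant selector (random-forest importances against shuffled shadow
features, binomial confirm/reject), and the final score for each sample is
PC1(signature A) - PC1(signature B) with deterministic PC1 orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from ubipattern.consensus import PatternAssignment

log = logging.getLogger(__name__)


class ScoreError(ValueError):
    pass


@dataclass
class SignaturePartition:
    genes_a: list[str]              # positively pattern-correlated, confirmed
    genes_b: list[str]              # negatively pattern-correlated, confirmed
    correlations: pd.Series         # per-gene Pearson r with the encoding
    boruta_status: pd.Series        # per-gene confirmed | rejected | tentative
    degenerate: pd.Series           # per-gene flag for zero-variance genes

    def __post_init__(self) -> None:
        if set(self.genes_a) & set(self.genes_b):
            raise ScoreError("signature pools A and B overlap")


@dataclass
class ScoreResult:
    pc1_a: pd.Series
    pc1_b: pd.Series
    score: pd.Series                # pc1_a - pc1_b, per sample
    loadings_a: pd.Series
    loadings_b: pd.Series


def _encode(labels: PatternAssignment | pd.Series) -> pd.Series:
    if isinstance(labels, PatternAssignment):
        return labels.ordinal()
    lab = labels.astype(str)
    codes = {v: i + 1 for i, v in enumerate(sorted(lab.unique()))}
    return lab.map(codes)


def pattern_correlation(
    expr: pd.DataFrame, labels: PatternAssignment | pd.Series
) -> pd.DataFrame:
    """Pearson r of each gene with the ordinal pattern encoding (A=1, B=2, ...).

    Constant genes get r = 0 with a ``degenerate`` flag instead of NaN.
    """
    enc = _encode(labels)
    if expr.shape[1] < 3:
        raise ScoreError("need >= 3 samples for correlation")
    if enc.loc[expr.columns].nunique() < 2:
        raise ScoreError("all samples share one pattern; correlation undefined")
    y = enc.loc[expr.columns].to_numpy(dtype=float)
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    degenerate = sx == 0
    denom = np.where(degenerate, 1.0, sx * sy)
    r = (xc @ yc) / denom
    r[degenerate] = 0.0
    return pd.DataFrame({"r": r, "degenerate": degenerate}, index=expr.index)


def boruta_select(
    features: pd.DataFrame,
    response: pd.Series,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    n_trees: int = 500,
    shadow_copies: int = 4,
) -> pd.Series:
    """All-relevant feature selection with shadow features.

    ``features`` is genes x samples; ``response`` maps sample to class label.
    Each iteration shuffles ``shadow_copies`` shadow replicates of every
    feature, fits a random forest, and scores a "hit" for features whose
    impurity importance beats the best shadow.  Accumulated hits feed two
    one-sided binomial tests at ``alpha`` (split across tails) with
    Bonferroni correction over the initial feature count; rejected features
    leave the model, but every original feature keeps contributing shadow
    copies so the best-shadow bar never collapses as the active set shrinks
    (several copies per feature keep the false-confirm rate of by-chance
    correlated noise features near zero).  Features still undecided after ``max_iter``
    remain tentative: a hit means beating the best shadow of the same
    iteration, so any importance-vs-shadow comparison is already folded
    into the binomial decision, and only binomial evidence confirms.

    Returns a Series mapping each feature to confirmed / rejected / tentative.
    """
    if features.shape[0] < 2:
        raise ScoreError("Boruta needs >= 2 features")
    if features.shape[1] < 10:
        raise ScoreError("Boruta needs >= 10 samples")
    y = response.loc[features.columns]
    if y.nunique() < 2:
        raise ScoreError("response has a single class")

    rng = np.random.default_rng(seed)
    x_all = features.to_numpy(dtype=float).T  # samples x features
    names = list(features.index)
    n_feat = len(names)
    y_codes = pd.Categorical(y).codes

    status = pd.Series("undecided", index=names)
    hits = pd.Series(0, index=names, dtype=int)
    trials = 0
    threshold = alpha / (2 * n_feat)  # two-sided at alpha, Bonferroni over features

    for _ in range(max_iter):
        active = status.index[status == "undecided"].tolist()
        if not active:
            break
        cols = [names.index(g) for g in active]
        x = x_all[:, cols]
        shadows = np.hstack([x_all.copy() for _ in range(shadow_copies)])
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([x, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(design, y_codes)
        imp = forest.feature_importances_
        real_imp = imp[: len(cols)]
        shadow_max = imp[len(cols):].max()
        trials += 1
        for g, v in zip(active, real_imp):
            if v > shadow_max:
                hits[g] += 1
        for g in active:
            p_confirm = stats.binom.sf(hits[g] - 1, trials, 0.5)
            p_reject = stats.binom.cdf(hits[g], trials, 0.5)
            if p_confirm < threshold:
                status[g] = "confirmed"
            elif p_reject < threshold:
                status[g] = "rejected"

    status[status == "undecided"] = "tentative"
    status.name = "boruta_status"
    return status


def derive_partition(
    expr: pd.DataFrame,
    labels: PatternAssignment | pd.Series,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    min_abs_r: float = 0.0,
    n_trees: int = 500,
) -> SignaturePartition:
    """Correlation split plus per-pool Boruta -> signature genes A and B."""
    corr = pattern_correlation(expr, labels)
    usable = ~corr["degenerate"]
    pos = corr.index[usable & (corr["r"] > min_abs_r)].tolist()
    neg = corr.index[usable & (corr["r"] < -min_abs_r)].tolist()
    enc = _encode(labels).loc[expr.columns]

    status = pd.Series("rejected", index=expr.index, dtype=object)
    genes_a: list[str] = []
    genes_b: list[str] = []
    for pool, out in ((pos, genes_a), (neg, genes_b)):
        if len(pool) < 2:
            log.warning("correlation pool with %d genes skipped (needs >= 2)", len(pool))
            continue
        pool_status = boruta_select(
            expr.loc[pool], enc, max_iter=max_iter, alpha=alpha, seed=seed,
            n_trees=n_trees,
        )
        status.loc[pool] = pool_status
        out.extend(g for g in pool if pool_status[g] == "confirmed")

    return SignaturePartition(
        genes_a=genes_a,
        genes_b=genes_b,
        correlations=corr["r"],
        boruta_status=status,
        degenerate=corr["degenerate"],
    )


def _oriented_pc1(expr: pd.DataFrame, genes: list[str], side: str) -> tuple[pd.Series, pd.Series]:
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        log.warning("dropping zero-variance signature gene(s) on side %s: %s", side, dropped)
        sub = sub.drop(index=dropped)
        sd = sd.drop(index=dropped)
    if sub.shape[0] < 2:
        raise ScoreError(f"signature side {side} has < 2 usable genes")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)  # genes x samples, standardized
    x = z.to_numpy().T                                     # samples x genes
    _, _, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    v1 = vt[0]
    pc1 = x @ v1
    # orient so PC1 tracks the set's own mean expression
    mean_expr = z.mean(axis=0).to_numpy()
    if np.corrcoef(pc1, mean_expr)[0, 1] < 0:
        v1 = -v1
        pc1 = -pc1
    return (
        pd.Series(pc1, index=expr.columns, name=f"pc1_{side}"),
        pd.Series(v1, index=sub.index, name=f"loading_{side}"),
    )


def pc1_score(expr: pd.DataFrame, partition: SignaturePartition) -> ScoreResult:
    """Per-sample score = PC1 over signature A minus PC1 over signature B.

    Genes are standardized before PCA; each PC1 is sign-oriented to correlate
    positively with the mean expression of its own gene set.
    """
    for side, genes in (("A", partition.genes_a), ("B", partition.genes_b)):
        if len(genes) < 2:
            raise ScoreError(f"signature side {side} has < 2 genes")
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise ScoreError(f"signature side {side} genes absent from matrix: {missing}")
    pc1_a, load_a = _oriented_pc1(expr, partition.genes_a, "a")
    pc1_b, load_b = _oriented_pc1(expr, partition.genes_b, "b")
    score = (pc1_a - pc1_b).rename("score")
    return ScoreResult(pc1_a=pc1_a, pc1_b=pc1_b, score=score,
                       loadings_a=load_a, loadings_b=load_b)
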