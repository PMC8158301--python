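"""Resampled k-means consensus clustering with CDF/delta-area model selection.

For each candidate k, samples are repeatedly subsampled without replacement,
k-means (Euclidean, k-means++ init) is run on gene-standardized profiles, and
pairwise co-clustering frequencies are accumulated into a consensus matrix.
Model selection follows the empirical-CDF / delta-area heuristic; the final
partition comes from an average-linkage cut of 1 - consensus.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

log = logging.getLogger(__name__)

_CDF_GRID = np.linspace(0.0, 1.0, 101)


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusResult:
    """Per-k consensus matrices plus the projection used for canonical naming."""

    samples: list[str]
    consensus: dict[int, np.ndarray]        # k -> (n, n) consensus proportions
    cosample_counts: dict[int, np.ndarray]  # k -> (n, n) times a pair was co-sampled
    pc1_projection: np.ndarray              # (n,) PC1 of standardized input
    seed: int
    subsample: float
    reps: int

    def k_values(self) -> list[int]:
        return sorted(self.consensus)


@dataclass
class PatternAssignment:
    labels: pd.Series          # sample -> 'A', 'B', ...
    k: int
    silhouette: pd.Series      # per-sample silhouette on 1 - consensus

    def ordinal(self) -> pd.Series:
        """Numeric encoding of the canonical order: A=1, B=2, ..."""
        codes = {lab: i + 1 for i, lab in enumerate(sorted(self.labels.unique()))}
        return self.labels.map(codes)


def _standardize_genes(expr: pd.DataFrame) -> np.ndarray:
    """Samples x genes array with each gene centered and scaled to unit SD."""
    x = expr.to_numpy(dtype=float).T
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def consensus_cluster(
    expr: pd.DataFrame,
    k_range: list[int],
    reps: int = 1000,
    subsample: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Accumulate consensus matrices over resampled k-means runs.

    ``consensus[k][i, j]`` is the fraction of subsamples containing both i
    and j in which they landed in the same k-means cluster; the diagonal is
    forced to 1.  Each k uses its own reproducible child seed sequence.
    """
    n = expr.shape[1]
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ConsensusError("empty k_range")
    if min(k_range) < 2:
        raise ConsensusError(f"k must be >= 2, got {min(k_range)}")
    if max(k_range) >= n:
        raise ConsensusError(f"k={max(k_range)} >= n_samples={n}")
    if n < 2 * max(k_range):
        raise ConsensusError(f"need >= {2 * max(k_range)} samples for k={max(k_range)}")
    if reps < 1:
        raise ConsensusError("reps must be >= 1")
    if not (0 < subsample <= 1):
        raise ConsensusError("subsample must be in (0, 1]")

    x = _standardize_genes(expr)
    n_sub = max(max(k_range) + 1, int(round(subsample * n)))
    samples = [str(s) for s in expr.columns]

    consensus: dict[int, np.ndarray] = {}
    cosample: dict[int, np.ndarray] = {}
    for k in k_range:
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        co_cluster = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=n_sub, replace=False)
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=10,
                max_iter=100,
                tol=1e-6,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            assign = km.fit_predict(x[idx])
            ind = np.zeros((n, k))
            ind[idx, assign] = 1.0
            co_cluster += ind @ ind.T
            mask = np.zeros(n)
            mask[idx] = 1.0
            co_sampled += np.outer(mask, mask)
        if (co_sampled[np.triu_indices(n, 1)] == 0).any():
            log.warning("some sample pairs were never co-sampled at k=%d; "
                        "their consensus is undefined (set to 0)", k)
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        consensus[k] = cons
        cosample[k] = co_sampled

    # deterministic PC1 projection for canonical pattern naming
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    v1 = vt[0]
    if v1[np.argmax(np.abs(v1))] < 0:  # sign fixed by largest-loading rule
        v1 = -v1
    proj = xc @ v1

    return ConsensusResult(
        samples=samples,
        consensus=consensus,
        cosample_counts=cosample,
        pc1_projection=proj,
        seed=seed,
        subsample=subsample,
        reps=reps,
    )


def cdf_delta_area(result: ConsensusResult) -> pd.DataFrame:
    """Area under the consensus-value CDF per k, and the relative gain.

    The CDF is evaluated on a fixed 101-point grid over [0, 1]; area is the
    trapezoid rule on that grid.  delta_area at the smallest k is the area
    itself; for larger k it is (area(k) - area(k-1)) / area(k-1).
    """
    ks = result.k_values()
    if len(ks) < 2:
        raise ConsensusError("need >= 2 values of k for delta-area analysis")
    areas = {}
    for k in ks:
        vals = result.consensus[k][np.triu_indices(len(result.samples), 1)]
        if np.allclose(vals, vals[0]):
            log.warning("degenerate consensus matrix at k=%d (all entries equal)", k)
        cdf = np.searchsorted(np.sort(vals), _CDF_GRID, side="right") / len(vals)
        areas[k] = float(np.trapezoid(cdf, _CDF_GRID))
    rows = []
    for i, k in enumerate(ks):
        if i == 0:
            delta = areas[k]
        else:
            prev = areas[ks[i - 1]]
            delta = (areas[k] - prev) / prev if prev > 0 else np.inf
        rows.append({"k": k, "area": areas[k], "delta_area": delta})
    return pd.DataFrame(rows).set_index("k")


def assign_patterns(result: ConsensusResult, k: int) -> PatternAssignment:
    """Cut average-linkage tree of 1 - consensus at k; name patterns A, B, ...

    Canonical naming: clusters are ordered by the ascending mean PC1
    projection of their member samples (PC1 of the standardized matrix the
    consensus run saw), then lettered in that order.
    """
    if k not in result.consensus:
        raise ConsensusError(f"k={k} not in computed range {result.k_values()}")
    cons = result.consensus[k]
    dist = 1.0 - cons
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    found = np.unique(raw)
    if len(found) != k:
        raise ConsensusError(
            f"consensus tree cut produced {len(found)} clusters instead of k={k}"
        )

    order = sorted(found, key=lambda c: result.pc1_projection[raw == c].mean())
    letters = _pattern_names(k)
    mapping = {c: letters[i] for i, c in enumerate(order)}
    labels = pd.Series([mapping[c] for c in raw], index=result.samples, name="pattern")

    if len(result.samples) > k:
        sil = silhouette_samples(dist, raw, metric="precomputed")
    else:  # silhouette undefined for singleton-only partitions
        sil = np.zeros(len(result.samples))
    silhouette = pd.Series(sil, index=result.samples, name="silhouette")
    return PatternAssignment(labels=labels, k=k, silhouette=silhouette)


def _pattern_names(k: int) -> list[str]:
    names = []
    for i in range(k):
        if i < 26:
            names.append(string.ascii_uppercase[i])
        else:
            names.append(string.ascii_uppercase[i // 26 - 1] + string.ascii_uppercase[i % 26])
    return names
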