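"""Kaplan-Meier curves, log-rank tests, Cox PH fitting, and cutpoint search.

The Cox model maximizes the Breslow partial likelihood by Newton-Raphson
with step halving; the log-rank statistic is the standard k-group
observed-minus-expected quadratic form with hypergeometric variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


class SurvivalError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit estimator; one row per distinct event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ut = np.unique(time[event == 1])
    rows = []
    surv = 1.0
    for t in ut:
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / n_at_risk
        rows.append({"time": t, "n_at_risk": n_at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def median_survival(curve: pd.DataFrame) -> float:
    """First event time at which the KM estimate drops to <= 0.5 (step time)."""
    below = curve[curve["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("nan")


def _logrank_stat(time: np.ndarray, event: np.ndarray, group_codes: np.ndarray,
                  n_groups: int) -> tuple[float, int]:
    ut = np.unique(time[event == 1])
    if len(ut) == 0:
        raise SurvivalError("no events in the pooled data")
    # per group: at-risk counts and event counts at each distinct event time
    n_gt = np.empty((n_groups, len(ut)))
    d_gt = np.empty((n_groups, len(ut)))
    for g in range(n_groups):
        tg = np.sort(time[group_codes == g])
        n_gt[g] = len(tg) - np.searchsorted(tg, ut, side="left")
        te = np.sort(time[(group_codes == g) & (event == 1)])
        d_gt[g] = (np.searchsorted(te, ut, side="right")
                   - np.searchsorted(te, ut, side="left"))
    n_t = n_gt.sum(axis=0)
    d_t = d_gt.sum(axis=0)
    p_gt = n_gt / n_t
    observed = d_gt.sum(axis=1)
    expected = (p_gt * d_t).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_t = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
    # V = sum_t c_t * (diag(p_t) - p_t p_t')
    v = np.einsum("t,gt,ht->gh", c_t, p_gt, p_gt) * -1.0
    v[np.diag_indices(n_groups)] += np.einsum("t,gt->g", c_t, p_gt)
    d = (observed - expected)[: n_groups - 1]
    v_sub = v[: n_groups - 1, : n_groups - 1]
    chi2 = float(d @ np.linalg.pinv(v_sub) @ d) if n_groups > 1 else 0.0
    return max(chi2, 0.0), n_groups - 1


def km_logrank(groups: pd.Series, clinical: pd.DataFrame):
    """Per-group KM curves plus the k-group log-rank chi-square test.

    Parameters
    ----------
    groups
        Maps sample id to a group label; must cover the clinical samples.

    Returns
    -------
    (curves, statistic, p) where curves maps group label -> KM DataFrame.
    """
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    missing = [s for s in clin.index if s not in groups.index]
    if missing:
        raise SurvivalError(f"samples without a group label: {missing[:10]}")
    lab = groups.loc[clin.index].astype(str)
    levels = sorted(lab.unique())
    if len(levels) < 2:
        raise SurvivalError("need >= 2 groups for a log-rank test")
    for lev in levels:
        if (lab == lev).sum() == 0:
            raise SurvivalError(f"group {lev!r} is empty")
    time = clin["time_months"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    codes = lab.map({lev: i for i, lev in enumerate(levels)}).to_numpy()

    curves = {
        lev: km_curve(time[codes == i], event[codes == i])
        for i, lev in enumerate(levels)
    }
    chi2, df = _logrank_stat(time, event, codes, len(levels))
    p = float(stats.chi2.sf(chi2, df))
    return curves, chi2, p


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)


@dataclass
class CoxFit:
    summary: pd.DataFrame       # coef, hr, ci lower/upper, se, wald p per covariate
    log_likelihood: float
    converged: bool
    n_iter: int

    @property
    def coefficients(self) -> pd.Series:
        return self.summary["coef"]


def _cox_ll_grad_hess(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                      beta: np.ndarray):
    order = np.argsort(time, kind="stable")
    t, e, xs = time[order], event[order], x[order]
    eta = xs @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    # reverse cumulative risk-set sums, read at the first index of each tie block
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * xs)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * xs[:, :, None] * xs[:, None, :])[::-1], axis=0)[::-1]
    first = np.searchsorted(t, t, side="left")
    ev = e == 1
    fi = first[ev]
    s0e, s1e, s2e = s0[fi], s1[fi], s2[fi]
    ll = float(np.sum(eta[ev] - np.log(s0e)))
    mu = s1e / s0e[:, None]
    grad = (xs[ev] - mu).sum(axis=0)
    hess = -(s2e / s0e[:, None, None] - mu[:, :, None] * mu[:, None, :]).sum(axis=0)
    return ll, grad, hess


def cox_fit(
    covariates: pd.DataFrame,
    clinical: pd.DataFrame,
    adjust: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox PH model by maximizing the Breslow partial likelihood.

    ``covariates`` has one row per sample (indexed by sample id); ``adjust``
    selects a subset of columns (default: all).  Constant covariates are
    dropped with a warning.  Convergence means gradient norm < ``tol``.
    """
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    cols = list(adjust) if adjust else list(covariates.columns)
    missing_cols = [c for c in cols if c not in covariates.columns]
    if missing_cols:
        raise SurvivalError(f"covariates not found: {missing_cols}")
    missing = [s for s in clin.index if s not in covariates.index]
    if missing:
        raise SurvivalError(f"samples without covariates: {missing[:10]}")
    x_df = covariates.loc[clin.index, cols].astype(float)
    constant = [c for c in x_df.columns if x_df[c].nunique() <= 1]
    if constant:
        log.warning("dropping constant covariate(s): %s", constant)
        warnings.warn(f"dropping constant covariate(s): {constant}", stacklevel=2)
        x_df = x_df.drop(columns=constant)
    if x_df.shape[1] == 0:
        raise SurvivalError("no usable covariates after dropping constants")
    time = clin["time_months"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    if event.sum() < x_df.shape[1]:
        raise SurvivalError(
            f"{int(event.sum())} events cannot support {x_df.shape[1]} covariates"
        )

    x = x_df.to_numpy()
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    xw = (x - center) / scale  # conditioning only; coefficients rescaled at the end

    beta = np.zeros(x.shape[1])
    ll, grad, hess = _cox_ll_grad_hess(xw, time, event, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        step = np.linalg.solve(hess, grad)
        factor = 1.0
        for _ in range(30):  # step halving keeps the likelihood ascending
            cand = beta - factor * step
            ll_new, grad_new, hess_new = _cox_ll_grad_hess(xw, time, event, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
                break
            factor /= 2.0
        else:
            raise ConvergenceError(f"step halving failed at iteration {it}, ll={ll}")
    else:
        if np.linalg.norm(grad) >= tol:
            raise ConvergenceError(
                f"Cox fit did not converge in {max_iter} iterations "
                f"(|grad|={np.linalg.norm(grad):.3e}, beta={beta})"
            )
    if not converged and np.linalg.norm(grad) < tol:
        converged = True

    cov = np.linalg.inv(-hess)
    se_w = np.sqrt(np.diag(cov))
    coef = beta / scale
    se = se_w / scale
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "se": se,
            "ci_lower": np.exp(coef - zcrit * se),
            "ci_upper": np.exp(coef + zcrit * se),
            "p": p,
        },
        index=x_df.columns,
    )
    return CoxFit(summary=summary, log_likelihood=ll, converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# Best-separation cutpoint


@dataclass
class CutpointResult:
    cutoff: float
    labels: pd.Series           # sample -> 'high' | 'low'
    p: float                    # minimal log-rank p across candidate cutoffs
    statistic: float
    selection_biased: bool = True   # the minimal p is optimistically biased

    def __post_init__(self) -> None:
        self.selection_biased = True  # always flagged; no correction applied


def best_cutpoint(
    score: pd.Series,
    clinical: pd.DataFrame,
    min_prop: float = 0.1,
) -> CutpointResult:
    """Scan candidate cutoffs for the minimal-log-rank-p high/low split.

    Candidates are midpoints of adjacent sorted unique scores that leave at
    least ``min_prop`` of the samples on each side; ties in p resolve to the
    lower cutoff.  The reported p carries a permanent selection-bias flag.
    """
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    missing = [s for s in clin.index if s not in score.index]
    if missing:
        raise SurvivalError(f"samples without a score: {missing[:10]}")
    s = score.loc[clin.index].to_numpy(dtype=float)
    time = clin["time_months"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    n = len(s)
    if int(event.sum()) < 20:
        raise SurvivalError("best_cutpoint needs >= 20 samples with events")

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    min_n = int(np.ceil(min_prop * n))
    candidates = [c for c in mids
                  if (s > c).sum() >= min_n and (s <= c).sum() >= min_n]
    if not candidates:
        raise SurvivalError(
            f"no cutoff leaves >= {min_n} samples on each side (min_prop={min_prop})"
        )

    best_p, best_chi2, best_cut = np.inf, 0.0, None
    for c in candidates:
        codes = (s > c).astype(int)
        if event[codes == 0].sum() + event[codes == 1].sum() == 0:
            continue
        chi2, df = _logrank_stat(time, event, codes, 2)
        p = float(stats.chi2.sf(chi2, df))
        if p < best_p - 1e-15:  # strict improvement; ties keep the lower cutoff
            best_p, best_chi2, best_cut = p, chi2, c
    if best_cut is None:
        raise SurvivalError("no evaluable cutoff found")
    labels = pd.Series(np.where(score.loc[clin.index] > best_cut, "high", "low"),
                       index=clin.index, name="score_group")
    return CutpointResult(cutoff=float(best_cut), labels=labels, p=best_p,
                          statistic=best_chi2)
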