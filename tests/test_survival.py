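import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from ubipattern.survival import (
    SurvivalError,
    _cox_ll_grad_hess,
    best_cutpoint,
    cox_fit,
    km_curve,
    km_logrank,
    median_survival,
)

# hand-computed log-rank table for the 2x2-event toy:
# t=1: n=4, n1=2, d=1 -> E1=1/2, V=1/4 ; t=2: n=3, n1=1, d=1 -> E1=1/3, V=2/9
# t=3, t=4: all remaining at-risk are in group 2 -> E contributions 0, V=0
# O1=2, E1=5/6, V=17/36, chi2 = (7/6)^2 / (17/36) = 49/17
TOY_CHI2 = 49.0 / 17.0


def clin(time, event, samples=None):
    samples = samples or [f"s{i}" for i in range(len(time))]
    return pd.DataFrame({"sample": samples, "time_months": time, "event": event})


class TestKaplanMeier:
    def test_nonincreasing_from_one(self, rng):
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, size=50)
        e[0] = 1
        curve = km_curve(t, e)
        surv = curve["survival"].to_numpy()
        assert (surv <= 1.0 + 1e-12).all()
        assert (np.diff(surv) <= 1e-12).all()

    def test_matches_lifelines(self, rng):
        t = rng.exponential(10, size=80)
        e = rng.integers(0, 2, size=80)
        e[:5] = 1
        curve = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in curve.iterrows():
            expected = float(kmf.survival_function_at_times(row["time"]).iloc[0])
            assert row["survival"] == pytest.approx(expected, abs=1e-10)

    def test_median_reads_step_time(self):
        curve = km_curve(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 1, 1]))
        assert median_survival(curve) == 2.0


class TestLogrank:
    def test_identical_duplicated_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 1, 0, 1] * 2)
        groups = pd.Series(["a"] * 4 + ["b"] * 4,
                           index=[f"s{i}" for i in range(8)])
        _, chi2, p = km_logrank(groups, clin(t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_toy(self):
        groups = pd.Series(["g1", "g1", "g2", "g2"],
                           index=["s0", "s1", "s2", "s3"])
        _, chi2, _ = km_logrank(groups, clin([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]))
        assert chi2 == pytest.approx(TOY_CHI2, abs=1e-10)

    def test_power_under_hazard_ratio_three(self):
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            t1 = r.exponential(1 / 0.03, size=200)
            t2 = r.exponential(1 / 0.01, size=200)
            t = np.concatenate([t1, t2])
            e = np.ones(400, dtype=int)
            groups = pd.Series(["hi"] * 200 + ["lo"] * 200,
                               index=[f"s{i}" for i in range(400)])
            _, _, p = km_logrank(groups, clin(t, e))
            if p < 0.001:
                hits += 1
        assert hits >= int(0.95 * 50)

    def test_row_order_invariance(self, rng):
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[:3] = 1
        samples = [f"s{i}" for i in range(40)]
        groups = pd.Series(rng.choice(["a", "b"], size=40), index=samples)
        table = clin(t, e, samples)
        _, chi2_a, _ = km_logrank(groups, table)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        _, chi2_b, _ = km_logrank(groups, shuffled)
        assert chi2_a == pytest.approx(chi2_b, abs=1e-12)

    def test_matches_lifelines_three_groups(self, rng):
        t = rng.exponential(10, size=90)
        e = rng.integers(0, 2, size=90)
        e[:5] = 1
        g = rng.choice(["a", "b", "c"], size=90)
        samples = [f"s{i}" for i in range(90)]
        _, chi2, _ = km_logrank(pd.Series(g, index=samples), clin(t, e, samples))
        expected = multivariate_logrank_test(t, g, e).test_statistic
        assert chi2 == pytest.approx(expected, abs=1e-8)

    def test_single_group_rejected(self):
        groups = pd.Series(["a"] * 4, index=[f"s{i}" for i in range(4)])
        with pytest.raises(SurvivalError, match=">= 2 groups"):
            km_logrank(groups, clin([1, 2, 3, 4], [1, 1, 1, 1]))


class TestCoxFit:
    def simulate(self, seed, n=500, beta=np.log(2.0), censor=False):
        r = np.random.default_rng(seed)
        x = r.integers(0, 2, size=n).astype(float)
        t = r.exponential(1.0 / (0.02 * np.exp(beta * x)))
        if censor:
            c = r.exponential(60, size=n)
            e = (t <= c).astype(int)
            t = np.minimum(t, c)
        else:
            e = np.ones(n, dtype=int)
        samples = [f"s{i}" for i in range(n)]
        covs = pd.DataFrame({"x": x}, index=samples)
        return covs, clin(t, e, samples)

    def test_true_hr_within_ci(self):
        covs, table = self.simulate(seed=0)
        fit = cox_fit(covs, table)
        row = fit.summary.loc["x"]
        assert row["ci_lower"] <= 2.0 <= row["ci_upper"]
        assert fit.converged

    def test_matches_lifelines_breslow(self):
        covs, table = self.simulate(seed=1, n=200, censor=True)
        fit = cox_fit(covs, table)
        df = pd.DataFrame({"T": table["time_months"], "E": table["event"],
                           "x": covs["x"].to_numpy()})
        cph = CoxPHFitter()
        cph.fit(df, "T", "E")  # lifelines default tie handling is Breslow
        # tolerance limited by lifelines' own convergence threshold
        assert fit.summary.loc["x", "coef"] == pytest.approx(
            cph.summary.loc["x", "coef"], abs=1e-4)
        assert fit.summary.loc["x", "se"] == pytest.approx(
            cph.summary.loc["x", "se(coef)"], abs=1e-4)

    def test_gradient_norm_at_solution(self):
        covs, table = self.simulate(seed=2, n=300)
        fit = cox_fit(covs, table)
        x = covs.loc[table["sample"]].to_numpy()
        _, grad, _ = _cox_ll_grad_hess(
            x, table["time_months"].to_numpy(),
            table["event"].to_numpy(), fit.summary["coef"].to_numpy(),
        )
        assert np.linalg.norm(grad) < 1e-8

    def test_constant_covariate_dropped_with_warning(self):
        covs, table = self.simulate(seed=3, n=100)
        covs["zeros"] = 0.0
        with pytest.warns(UserWarning, match="zeros"):
            fit = cox_fit(covs, table)
        assert "zeros" not in fit.summary.index

    def test_coverage_simulation(self):
        """95% CI covers the true log-HR in 95% +/- 4% of 200 runs."""
        true = np.log(2.0)
        covered = 0
        for seed in range(200):
            covs, table = self.simulate(seed=seed, n=300, censor=True)
            fit = cox_fit(covs, table)
            row = fit.summary.loc["x"]
            lo = np.log(row["ci_lower"])
            hi = np.log(row["ci_upper"])
            if lo <= true <= hi:
                covered += 1
        assert 0.91 <= covered / 200 <= 0.99

    def test_hr_equals_exp_coef(self):
        covs, table = self.simulate(seed=4, n=150)
        fit = cox_fit(covs, table)
        assert np.allclose(fit.summary["hr"], np.exp(fit.summary["coef"]))


class TestBestCutpoint:
    def simulate_step(self, seed, n=400):
        r = np.random.default_rng(seed)
        score = r.normal(size=n)
        haz = np.where(score > 0, 0.03, 0.01)
        t = r.exponential(1.0 / haz)
        c = r.exponential(200, size=n)
        e = (t <= c).astype(int)
        samples = [f"s{i}" for i in range(n)]
        return (pd.Series(score, index=samples),
                clin(np.minimum(t, c), e, samples))

    def test_recovers_planted_step(self):
        hits = 0
        for seed in range(25):
            score, table = self.simulate_step(seed)
            cut = best_cutpoint(score, table)
            lo, hi = np.quantile(score, [0.4, 0.6])
            if lo <= cut.cutoff <= hi:
                hits += 1
        assert hits >= int(0.9 * 25)

    def test_min_prop_respected(self):
        score, table = self.simulate_step(seed=1, n=100)
        cut = best_cutpoint(score, table, min_prop=0.25)
        assert (cut.labels == "high").sum() >= 25
        assert (cut.labels == "low").sum() >= 25

    def test_selection_bias_flag_always_set(self):
        score, table = self.simulate_step(seed=2, n=60)
        cut = best_cutpoint(score, table)
        assert cut.selection_biased is True

    def test_too_few_events_rejected(self):
        score, table = self.simulate_step(seed=3, n=30)
        table = table.copy()
        table["event"] = [1] * 10 + [0] * 20
        with pytest.raises(SurvivalError, match=">= 20"):
            best_cutpoint(score, table)

    def test_impossible_min_prop_rejected(self):
        score, table = self.simulate_step(seed=4, n=40)
        with pytest.raises(SurvivalError, match="min_prop"):
            best_cutpoint(score, table, min_prop=0.6)
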