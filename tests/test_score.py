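import numpy as np
import pandas as pd
import pytest

from ubipattern.score import (
    ScoreError,
    SignaturePartition,
    boruta_select,
    pattern_correlation,
    pc1_score,
)


def label_series(values):
    return pd.Series(values, index=[f"s{i}" for i in range(len(values))])


class TestPatternCorrelation:
    @pytest.fixture
    def labels(self):
        return label_series(["A", "A", "B", "B", "C", "C"])

    def test_gene_equal_to_encoding(self, labels):
        enc = [1, 1, 2, 2, 3, 3]
        expr = pd.DataFrame({"up": enc, "down": [-v for v in enc],
                             "flat": [5] * 6}).T
        expr.columns = labels.index
        res = pattern_correlation(expr, labels)
        assert res.loc["up", "r"] == pytest.approx(1.0)
        assert res.loc["down", "r"] == pytest.approx(-1.0)
        assert res.loc["flat", "r"] == 0.0
        assert bool(res.loc["flat", "degenerate"])
        assert not bool(res.loc["up", "degenerate"])

    def test_single_pattern_rejected(self, rng):
        labels = label_series(["A"] * 6)
        expr = pd.DataFrame(rng.normal(size=(3, 6)), columns=labels.index)
        with pytest.raises(ScoreError, match="one pattern"):
            pattern_correlation(expr, labels)


class TestBorutaSelect:
    def test_null_features_not_confirmed(self):
        """Label-permuted responses: no feature should be confirmed."""
        clean = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            samples = [f"s{i}" for i in range(200)]
            features = pd.DataFrame(r.normal(size=(50, 200)),
                                    index=[f"f{i}" for i in range(50)],
                                    columns=samples)
            response = pd.Series(r.permutation([0, 1, 2] * 67)[:200], index=samples)
            status = boruta_select(features, response, max_iter=40, seed=seed,
                                   n_trees=80)
            if (status == "confirmed").sum() == 0:
                clean += 1
        assert clean >= int(0.95 * n_seeds)

    def test_strong_signal_confirmed(self):
        r = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(120)]
        classes = np.array([0, 1, 2] * 40)
        x = r.normal(size=(10, 120))
        x[0] = classes + r.normal(0, 0.01, size=120)
        features = pd.DataFrame(x, index=[f"f{i}" for i in range(10)],
                                columns=samples)
        status = boruta_select(features, pd.Series(classes, index=samples),
                               max_iter=50, seed=1, n_trees=100)
        assert status["f0"] == "confirmed"

    def test_duplicate_informative_feature_both_confirmed(self):
        """All-relevant property: an exact duplicate is confirmed too."""
        r = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(150)]
        classes = np.array([0, 1, 2] * 50)
        x = r.normal(size=(8, 150))
        x[0] = classes + r.normal(0, 0.05, size=150)
        x[1] = x[0].copy()
        features = pd.DataFrame(x, index=[f"f{i}" for i in range(8)],
                                columns=samples)
        status = boruta_select(features, pd.Series(classes, index=samples),
                               max_iter=60, seed=2, n_trees=150)
        assert status["f0"] == "confirmed"
        assert status["f1"] == "confirmed"

    def test_single_class_rejected(self, rng):
        samples = [f"s{i}" for i in range(20)]
        features = pd.DataFrame(rng.normal(size=(3, 20)), columns=samples)
        with pytest.raises(ScoreError, match="single class"):
            boruta_select(features, pd.Series([1] * 20, index=samples))

    def test_deterministic_under_seed(self, rng):
        samples = [f"s{i}" for i in range(60)]
        classes = np.array([0, 1] * 30)
        x = rng.normal(size=(6, 60))
        x[0] = classes + rng.normal(0, 0.1, size=60)
        features = pd.DataFrame(x, index=[f"f{i}" for i in range(6)],
                                columns=samples)
        y = pd.Series(classes, index=samples)
        s1 = boruta_select(features, y, max_iter=15, seed=9, n_trees=50)
        s2 = boruta_select(features, y, max_iter=15, seed=9, n_trees=50)
        pd.testing.assert_series_equal(s1, s2)


def make_partition(genes_a, genes_b, universe):
    return SignaturePartition(
        genes_a=genes_a,
        genes_b=genes_b,
        correlations=pd.Series(0.0, index=universe),
        boruta_status=pd.Series("confirmed", index=universe),
        degenerate=pd.Series(False, index=universe),
    )


class TestPc1Score:
    @pytest.fixture
    def latent_expr(self, rng):
        """Two 5-gene blocks each driven by its own latent factor."""
        n = 80
        f_a = rng.normal(size=n)
        f_b = rng.normal(size=n)
        rows = {}
        for i in range(5):
            rows[f"a{i}"] = f_a + rng.normal(0, 0.05, size=n)
        for i in range(5):
            rows[f"b{i}"] = f_b + rng.normal(0, 0.05, size=n)
        expr = pd.DataFrame(rows).T
        expr.columns = [f"s{i}" for i in range(n)]
        return expr, f_a, f_b

    def test_swap_negates_score_exactly(self, latent_expr):
        expr, _, _ = latent_expr
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        fwd = pc1_score(expr, make_partition(a, b, list(expr.index)))
        rev = pc1_score(expr, make_partition(b, a, list(expr.index)))
        assert np.allclose(fwd.score, -rev.score, atol=1e-10)

    def test_pc1_tracks_latent_factor(self, latent_expr):
        expr, f_a, _ = latent_expr
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        res = pc1_score(expr, make_partition(a, b, list(expr.index)))
        r = np.corrcoef(res.pc1_a, f_a)[0, 1]
        assert abs(r) >= 0.99
        assert r > 0  # orientation follows the set's own mean expression

    def test_negating_matrix_negates_score(self, latent_expr):
        expr, _, _ = latent_expr
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        part = make_partition(a, b, list(expr.index))
        fwd = pc1_score(expr, part)
        neg = pc1_score(-expr, part)
        assert np.allclose(fwd.score, -neg.score, atol=1e-10)

    def test_score_equals_difference(self, latent_expr):
        expr, _, _ = latent_expr
        res = pc1_score(expr, make_partition([f"a{i}" for i in range(5)],
                                             [f"b{i}" for i in range(5)],
                                             list(expr.index)))
        assert np.array_equal(res.score.to_numpy(),
                              (res.pc1_a - res.pc1_b).to_numpy())

    def test_gene_and_sample_permutation_invariance(self, latent_expr, rng):
        expr, _, _ = latent_expr
        part = make_partition([f"a{i}" for i in range(5)],
                              [f"b{i}" for i in range(5)], list(expr.index))
        base = pc1_score(expr, part)
        perm_genes = rng.permutation(expr.index)
        perm_samples = rng.permutation(expr.columns)
        shuffled = expr.loc[perm_genes, perm_samples]
        again = pc1_score(shuffled, part)
        assert np.allclose(base.score.loc[again.score.index], again.score,
                           atol=1e-9)

    def test_too_few_genes_rejected(self, latent_expr):
        expr, _, _ = latent_expr
        with pytest.raises(ScoreError, match="side A"):
            pc1_score(expr, make_partition(["a0"], ["b0", "b1"], list(expr.index)))

    def test_zero_variance_genes_dropped_with_warning(self, latent_expr, caplog):
        expr, _, _ = latent_expr
        expr = expr.copy()
        expr.loc["a0"] = 3.0
        part = make_partition([f"a{i}" for i in range(5)],
                              [f"b{i}" for i in range(5)], list(expr.index))
        with caplog.at_level("WARNING"):
            res = pc1_score(expr, part)
        assert "a0" in caplog.text
        assert "a0" not in res.loadings_a.index

    def test_overlapping_pools_rejected(self, latent_expr):
        expr, _, _ = latent_expr
        with pytest.raises(ScoreError, match="overlap"):
            make_partition(["a0", "a1"], ["a1", "b0"], list(expr.index))


class TestEndToEndScore:
    def test_partition_pools_are_disjoint_and_confirmed(self, partition):
        assert not set(partition.genes_a) & set(partition.genes_b)
        for g in partition.genes_a + partition.genes_b:
            assert partition.boruta_status[g] == "confirmed"

    def test_score_recovers_planted_score(self, planted, score_result):
        r = np.corrcoef(score_result.score, planted.planted_score)[0, 1]
        assert abs(r) >= 0.8

    def test_score_increases_with_canonical_order(self, assignment, score_result):
        enc = assignment.ordinal().loc[score_result.score.index]
        r = np.corrcoef(score_result.score, enc)[0, 1]
        assert r > 0
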