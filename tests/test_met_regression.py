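import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.outliers_influence import variance_inflation_factor

from pnetcohort import met_regression as mr
from pnetcohort.errors import RegressionError
from conftest import make_matrix


def design_from_arrays(X, y, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return mr.DesignMatrix(X=pd.DataFrame(X, columns=names), y=pd.Series(y))


class TestBuildDesign:
    def _matrix(self, freqs_primary, freqs_met, n=200):
        rng = np.random.default_rng(11)
        profiles = {}
        genes = sorted(freqs_primary)
        for i in range(n):
            profiles[f"P{i:04d}"] = (
                "primary",
                {g for g in genes if rng.random() < freqs_primary[g]},
            )
            profiles[f"M{i:04d}"] = (
                "metastasis",
                {g for g in genes if rng.random() < freqs_met[g]},
            )
        return make_matrix(profiles, genes)

    def test_or_rule_threshold(self):
        m = self._matrix({"A": 0.01, "B": 0.3, "C": 0.0}, {"A": 0.2, "B": 0.3, "C": 0.0})
        d = mr.build_design(m, min_freq=0.05)
        # A passes via metastases despite rarity in primaries; C never passes
        assert "A" in d.covariates and "C" not in d.covariates
        # brute-force scan agrees
        expected = [
            g
            for g in m.genes
            if max(
                m.indicator.loc[m.stratum == s, g].mean()
                for s in ("primary", "metastasis")
            )
            >= 0.05
        ]
        assert sorted(d.covariates) == sorted(expected)

    def test_column_order_descending_pooled_frequency(self):
        m = self._matrix({"A": 0.3, "B": 0.6}, {"A": 0.3, "B": 0.6})
        d = mr.build_design(m)
        assert d.covariates == ["B", "A"]

    def test_outcome_is_metastasis_indicator(self):
        m = self._matrix({"A": 0.3}, {"A": 0.3})
        d = mr.build_design(m)
        assert set(d.y.unique()) == {0, 1}
        assert d.y.sum() == (m.stratum == "metastasis").sum()


class TestDropAliased:
    def test_identical_column_dropped_keeping_first(self):
        x = np.array([0, 1, 0, 1, 1, 0], float)
        d = design_from_arrays(np.column_stack([x, x]), [0, 1, 0, 1, 0, 1], ["a", "b"])
        kept, removed = mr.drop_aliased(d)
        assert kept.covariates == ["a"] and removed == ["b"]

    def test_perfect_negative_correlation_dropped(self):
        x = np.array([0, 1, 0, 1, 1, 0], float)
        d = design_from_arrays(np.column_stack([x, 1 - x]), [0, 1, 0, 1, 0, 1], ["a", "b"])
        _, removed = mr.drop_aliased(d)
        assert removed == ["b"]

    def test_orthogonal_columns_untouched(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(50, 4)).astype(float)
        d = design_from_arrays(X, rng.integers(0, 2, 50))
        kept, removed = mr.drop_aliased(d)
        assert removed == [] and kept.covariates == d.covariates


class TestVif:
    def test_orthogonal_design_gives_one(self):
        # balanced 2^3 factorial: pairwise-uncorrelated binary columns
        from itertools import product

        X = np.array(list(product([0, 1], repeat=3)), float)
        X = np.tile(X, (4, 1))
        d = design_from_arrays(X, np.tile([0, 1], 16))
        for c in d.covariates:
            assert mr.vif(d, c) == pytest.approx(1.0, abs=1e-8)

    def test_closed_form_for_correlation_09(self):
        # construct exact sample correlation r = 0.9 via orthonormal basis
        n = 40
        rng = np.random.default_rng(5)
        u = rng.normal(size=(n, 2))
        u -= u.mean(axis=0)
        q, _ = np.linalg.qr(u)
        x1 = q[:, 0]
        x2 = 0.9 * q[:, 0] + np.sqrt(1 - 0.81) * q[:, 1]
        d = design_from_arrays(np.column_stack([x1, x2]), rng.integers(0, 2, n))
        assert mr.vif(d, "x0") == pytest.approx(1 / (1 - 0.81), abs=1e-8)

    def test_two_routes_agree(self):
        # R^2 route vs inverse-correlation-matrix route (via statsmodels)
        rng = np.random.default_rng(9)
        for _ in range(10):
            X = rng.integers(0, 2, size=(120, 5)).astype(float)
            X[:, 4] = np.where(rng.random(120) < 0.8, X[:, 0], X[:, 4])
            d = design_from_arrays(X, rng.integers(0, 2, 120))
            import statsmodels.api as sm

            Xc = sm.add_constant(pd.DataFrame(X), prepend=True)
            for j, c in enumerate(d.covariates):
                ours = mr.vif(d, c)
                theirs = variance_inflation_factor(Xc.to_numpy(), j + 1)
                assert ours == pytest.approx(theirs, abs=1e-8)


class TestPruneByVif:
    def test_compliant_design_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(100, 4)).astype(float)
        d = design_from_arrays(X, rng.integers(0, 2, 100))
        pruned, removed = mr.prune_by_vif(d, threshold=4.0)
        assert removed == [] and pruned.covariates == d.covariates

    def test_collinear_trio_pruned_until_compliant(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 2, size=200).astype(float)
        noise = lambda: (rng.random(200) < 0.05).astype(float)
        X = np.column_stack(
            [np.abs(base - noise()), np.abs(base - noise()), np.abs(base - noise())]
        )
        d = design_from_arrays(X, rng.integers(0, 2, 200))
        pruned, removed = mr.prune_by_vif(d, threshold=4.0)
        assert removed  # something had to go
        max_vif = (
            max(mr.vif(pruned, c) for c in pruned.covariates)
            if len(pruned.covariates) > 1
            else 1.0
        )
        assert max_vif <= 4.0

    def test_single_covariate_untouched(self):
        d = design_from_arrays(np.array([[0.0], [1.0], [1.0], [0.0]]), [0, 1, 1, 0])
        pruned, removed = mr.prune_by_vif(d)
        assert removed == [] and pruned.covariates == ["x0"]


class TestFitLogistic:
    def test_single_binary_covariate_closed_form(self):
        # mutated: 10 met / 20 primary; WT: 30 met / 90 primary
        x = np.array([1] * 30 + [0] * 120, float)
        y = np.array([1] * 10 + [0] * 20 + [1] * 30 + [0] * 90)
        res = mr.fit_logistic(design_from_arrays(x[:, None], y, ["G"]))
        beta = res.params["G"]
        assert beta == pytest.approx(np.log(10 * 90 / (20 * 30)), abs=1e-6)
        assert res.odds_ratios["G"] == pytest.approx(np.exp(beta))

    def test_intercept_only_closed_form(self):
        k, n = 30, 100
        y = np.array([1] * k + [0] * (n - k))
        # constant covariate is aliased with the intercept; use a null gene
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, n).astype(float)
        res = mr.fit_logistic(design_from_arrays(x[:, None], y, ["G"]))
        # the intercept of the saturated 2x2 fit is logit(k0/n0) of the x=0 arm
        k0 = y[x == 0].sum()
        n0 = (x == 0).sum()
        intercept = res.table.set_index("covariate").loc["intercept", "beta"]
        assert intercept == pytest.approx(np.log(k0 / (n0 - k0)), abs=1e-6)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(4)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        y = rng.integers(0, 2, n)
        res = mr.fit_logistic(design_from_arrays(x[:, None], y, ["G"]))
        assert abs(res.params["G"]) < 0.15
        assert res.pvalues["G"] > 0.01

    def test_separation_flagged(self):
        x = np.array([1] * 10 + [0] * 10, float)
        y = np.array([1] * 10 + [0] * 10)
        res = mr.fit_logistic(design_from_arrays(x[:, None], y, ["G"]))
        assert res.separation_flag

    def test_outcome_must_have_both_classes(self):
        with pytest.raises(RegressionError):
            mr.MetastasisLogit(design_from_arrays(np.zeros((4, 1)), [1, 1, 1, 1]))


def test_parameter_recovery_known_effect():
    """n=1000 cohorts with a log-odds 1.0 TP53 effect and null genes:
    the estimate's mean over 100 seeds is within 0.15 of truth and its
    BH-corrected q is below 0.05 in at least 90% of replicates."""
    betas = []
    significant = 0
    n = 1000
    for seed in range(100):
        rng = np.random.default_rng(10_000 + seed)
        tp53 = (rng.random(n) < 0.12).astype(float)
        others = (rng.random((n, 4)) < 0.2).astype(float)
        logit = -1.0 + 1.0 * tp53
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        X = np.column_stack([tp53, others])
        d = design_from_arrays(X, y, ["TP53", "A", "B", "C", "D"])
        res = mr.MetastasisLogit(d).fit()
        betas.append(res.params["TP53"])
        if res.qvalues["TP53"] < 0.05:
            significant += 1
    assert abs(np.mean(betas) - 1.0) < 0.15
    assert significant >= 90
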