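import itertools

import numpy as np
import pandas as pd
import pytest

from echotex.errors import CollinearityError, InputError
from echotex.stats import (
    bonferroni_threshold,
    compute_vif,
    fit_linear_model,
    mann_whitney_test,
    prune_collinear,
    univariate_screen,
)
from echotex.synth import simulate_feature_table
from echotex.tables import FeatureTable


def u_counting_oracle(x, y):
    """U as the smaller all-pairs win count (ties count half)."""
    ux = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in x for b in y)
    return min(ux, len(x) * len(y) - ux)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact_p(self):
        u, p = mann_whitney_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # 2 of the C(6,3) = 20 labelings are at least as extreme two-sided
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_test([1.0, 2.0, 3.0, 4.0] * 5, [1.0, 2.0, 3.0, 4.0] * 5)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_u_matches_counting_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 25))
            y = rng.normal(size=rng.integers(3, 25))
            u, _ = mann_whitney_test(x, y)
            assert u == pytest.approx(u_counting_oracle(x, y))

    def test_exact_p_against_full_enumeration(self, rng):
        """Oracle: enumerate every labeling of the pooled sample."""
        x, y = rng.normal(size=4), rng.normal(size=4)
        u_obs, p = mann_whitney_test(x, y)
        pooled = np.concatenate([x, y])
        n = len(pooled)
        us = [
            u_counting_oracle(pooled[list(ix)], np.delete(pooled, list(ix)))
            for ix in itertools.combinations(range(n), 4)
        ]
        # two-sided: the min-U statistic already pools both tails
        p_oracle = min(1.0, float(np.mean([u <= u_obs + 1e-12 for u in us])))
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_p_invariant_under_monotone_transform(self, rng):
        x, y = rng.normal(size=30), rng.normal(0.6, 1.0, size=25)
        _, p1 = mann_whitney_test(x, y)
        _, p2 = mann_whitney_test(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestBonferroni:
    def test_family_of_thirty_floors_to_00016(self):
        assert bonferroni_threshold(0.05, 30) == 0.0016

    def test_single_test_unchanged(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_exact_division(self):
        assert bonferroni_threshold(0.05, 5) == 0.01

    def test_zero_family_rejected(self):
        with pytest.raises(InputError):
            bonferroni_threshold(0.05, 0)


class TestUnivariateScreen:
    def test_injected_shift_flagged(self, rng):
        hits = 0
        reps = 40
        for i in range(reps):
            t = simulate_feature_table(
                n_per_class=(26, 30), n_informative=1, n_noise=2, shift_sd=2.0, seed=i
            )
            res = univariate_screen(t, 0.0016)
            hits += "inf01" in res.retained
        assert hits / reps >= 0.95

    def test_constant_column_not_flagged(self):
        idx = pd.Index([f"l{i}" for i in range(20)], name="lesion_id")
        t = FeatureTable(
            pd.DataFrame({"const": np.ones(20)}, index=idx),
            pd.Series([0, 1] * 10, index=idx),
        )
        res = univariate_screen(t, 0.05)
        assert res.per_feature.loc["const", "p"] == pytest.approx(1.0)
        assert not res.per_feature.loc["const", "significant"]

    def test_medians_and_iqr_reported_per_class(self, rng):
        t = simulate_feature_table(n_per_class=10, n_informative=1, n_noise=0, seed=0)
        res = univariate_screen(t, 0.05)
        hoc, en = t.class_values("inf01")
        row = res.per_feature.loc["inf01"]
        assert row["median_en"] == pytest.approx(np.median(en))
        assert row["iqr_hoc_low"] == pytest.approx(np.percentile(hoc, 25))


class TestLinearModel:
    def test_hand_ols_single_predictor(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        m = fit_linear_model(X, [0, 0, 1, 1])
        assert m.coefficients["x"] == pytest.approx(0.4)
        assert m.coefficients["const"] == pytest.approx(-0.5)
        assert m.r2 == pytest.approx(0.8)
        assert m.multiple_r == pytest.approx(np.sqrt(0.8))
        assert m.r2_adj <= m.r2

    def test_orthogonal_predictors_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]}, dtype=float)
        m = fit_linear_model(X, [0, 1, 0, 1])
        assert m.vif["a"] == pytest.approx(1.0)
        assert m.vif["b"] == pytest.approx(1.0)

    def test_exact_collinearity_raises_named_error(self):
        x1 = np.arange(8, dtype=float)
        X = pd.DataFrame({"x1": x1, "x2": 2.0 * x1, "ok": np.r_[np.zeros(4), np.ones(4)]})
        with pytest.raises(CollinearityError) as err:
            fit_linear_model(X, [0, 0, 0, 0, 1, 1, 1, 1])
        assert {"x1", "x2"}.issubset(set(err.value.columns))

    def test_residuals_orthogonal_to_predictors(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, size=40)
        m = fit_linear_model(X, y)
        resid = y - m.fitted
        for c in X:
            assert abs(np.dot(resid, X[c])) / len(y) < 1e-8

    def test_vif_matches_inverse_correlation_route(self, rng):
        """Dual route: regression-definition VIF vs the diagonal of the
        inverse correlation matrix on a standardized design."""
        Z = rng.normal(size=(60, 4))
        Z[:, 1] = 0.7 * Z[:, 0] + 0.7 * Z[:, 1]
        X = pd.DataFrame((Z - Z.mean(0)) / Z.std(0), columns=list("wxyz"))
        vif = compute_vif(X)
        inv = np.linalg.inv(np.corrcoef(X.to_numpy(), rowvar=False))
        assert np.allclose(vif.to_numpy(), np.diag(inv), atol=1e-8)

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 4)), columns=list("abcd"))
        with pytest.raises(InputError):
            fit_linear_model(X, [0, 1, 0, 1])


class TestPruneCollinear:
    def test_near_duplicate_column_removed(self, rng):
        a = rng.normal(size=200)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(0, 1e-4, 200), "c": rng.normal(size=200)})
        pruned, dropped = prune_collinear(X, limit=1e4)
        assert len(dropped) == 1
        assert dropped[0] in {"a", "b"}
        assert "c" in pruned.columns

    def test_orthogonal_design_untouched(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        pruned, dropped = prune_collinear(X)
        assert dropped == []
        assert pruned.shape == X.shape

    def test_three_near_identical_columns_leave_one(self, rng):
        a = rng.normal(size=300)
        X = pd.DataFrame(
            {
                "a": a,
                "b": a + rng.normal(0, 1e-5, 300),
                "c": a + rng.normal(0, 1e-5, 300),
                "d": rng.normal(size=300),
            }
        )
        pruned, dropped = prune_collinear(X, limit=1e4)
        assert len(dropped) == 2
        assert len({"a", "b", "c"} & set(pruned.columns)) == 1
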