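import numpy as np
import pandas as pd
import pytest

from echotex.errors import InputError
from echotex.selection import (
    combine_unique,
    fisher_score,
    mutual_information_score,
    poe_acc_select,
    poe_single,
    select_top,
)
from echotex.synth import simulate_feature_table
from echotex.tables import FeatureTable


def table_from(columns: dict, labels) -> FeatureTable:
    data = pd.DataFrame(columns)
    data.index.name = "lesion_id"
    return FeatureTable(data=data, labels=pd.Series(labels, index=data.index))


class TestFisherScore:
    def test_hand_computed_ratio(self):
        assert fisher_score([[1, 2, 3], [4, 5, 6]]) == pytest.approx(3.375)

    def test_equal_means_score_zero(self):
        assert fisher_score([[1, 2, 3], [3, 2, 1]]) == 0.0

    def test_perfect_separation_is_infinite(self):
        assert fisher_score([[0, 0], [1, 1]]) == np.inf

    def test_empty_class_rejected(self):
        with pytest.raises(InputError):
            fisher_score([[1, 2], []])

    def test_affine_invariance(self, rng):
        a, b = rng.normal(size=30), rng.normal(1.0, 1.0, size=30)
        f1 = fisher_score([a, b])
        f2 = fisher_score([3.5 * a + 2, 3.5 * b + 2])
        assert f1 == pytest.approx(f2, rel=1e-12)


class TestPOE:
    def test_perfect_feature_zero_error(self):
        labels = np.array([0, 0, 1, 1])
        poe, _, _ = poe_single(np.array([0.0, 0.0, 1.0, 1.0]), labels)
        assert poe == 0.0

    def test_interleaved_classes_exhaustive_threshold(self):
        # class0 = {1, 3}, class1 = {2, 4}: best single threshold errs once
        poe, thr, orient = poe_single(np.array([1.0, 3.0, 2.0, 4.0]), np.array([0, 0, 1, 1]))
        assert poe == 0.25
        assert thr == 1.5
        assert orient == ">"

    def test_never_exceeds_half(self, rng):
        for _ in range(20):
            vals = rng.normal(size=24)
            labels = rng.integers(0, 2, size=24)
            if len(set(labels)) < 2:
                continue
            poe, _, _ = poe_single(vals, labels)
            assert poe <= 0.5

    def test_constant_feature_majority_rule(self):
        poe, _, _ = poe_single(np.zeros(10), np.array([0] * 7 + [1] * 3))
        assert poe == pytest.approx(0.3)

    def test_correlation_penalty_prefers_decorrelated_pick(self):
        # f1 separates perfectly; f2 is a near-copy (POE .25, high |r|);
        # f3 is uninformative but uncorrelated -> picked second
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        f1 = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        f2 = f1 + np.array([0, 0, 0, 0.9, -0.9, 0, 0, 0])
        f3 = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        t = table_from({"f1": f1, "f2": f2, "f3": f3}, labels)
        sel = poe_acc_select(t, 2)
        assert sel.ranked[0] == "f1"
        assert sel.ranked[1] == "f3"


class TestMutualInformation:
    def test_feature_equal_to_balanced_labels_is_one_bit(self):
        labels = np.array([0] * 50 + [1] * 50)
        with pytest.warns(UserWarning):  # binary feature: bins reduced
            mi = mutual_information_score(labels.astype(float), labels)
        assert mi == pytest.approx(1.0)

    def test_independent_feature_near_zero(self, rng):
        labels = np.array([0, 1] * 100)
        mi = mutual_information_score(rng.normal(size=200), labels)
        assert mi <= 0.05

    def test_constant_feature_zero_bits(self):
        with pytest.warns(UserWarning):
            assert mutual_information_score(np.ones(20), np.array([0, 1] * 10)) == 0.0

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=80)
        labels = (vals + rng.normal(size=80) > 0).astype(int)
        m1 = mutual_information_score(vals, labels)
        m2 = mutual_information_score(np.exp(vals), labels)
        assert m1 == pytest.approx(m2, abs=1e-12)


class TestSelectTop:
    def test_fisher_recovers_injected_shift_columns(self, rng):
        n = 28
        labels = [0] * n + [1] * n
        cols = {}
        for i in range(1, 11):
            base = rng.normal(size=2 * n)
            base[n:] += 2.5  # strong injected shift
            cols[f"c{i:02d}"] = base
        cols["c11"] = rng.normal(size=2 * n)
        cols["c12"] = rng.normal(size=2 * n)
        sel = select_top(table_from(cols, labels), "fisher", k=10)
        assert set(sel.ranked) == {f"c{i:02d}" for i in range(1, 11)}

    @pytest.mark.parametrize("method", ["fisher", "poe_acc", "mi"])
    def test_deterministic_given_table(self, method, rng):
        t = simulate_feature_table(n_per_class=14, n_informative=3, n_noise=20, seed=5)
        with np.errstate(all="ignore"):
            s1 = select_top(t, method, k=5)
            s2 = select_top(t, method, k=5)
        assert s1.ranked == s2.ranked

    def test_exactly_k_unique_names(self):
        t = simulate_feature_table(n_per_class=15, n_informative=5, n_noise=270, seed=1)
        sel = select_top(t, "fisher", k=10)
        assert len(sel.ranked) == 10
        assert len(set(sel.ranked)) == 10

    def test_k_above_column_count_rejected(self):
        t = simulate_feature_table(n_per_class=10, n_informative=2, n_noise=3, seed=0)
        with pytest.raises(InputError):
            select_top(t, "fisher", k=6)


class TestCombineUnique:
    def test_three_pairwise_shares_give_27(self):
        a = [f"a{i}" for i in range(10)]
        b = [f"b{i}" for i in range(9)] + ["a0"]
        c = [f"c{i}" for i in range(8)] + ["a1", "b0"]
        import types

        sels = [
            types.SimpleNamespace(method=m, ranked=r)
            for m, r in [("fisher", a), ("poe_acc", b), ("mi", c)]
        ]
        union, members = combine_unique(sels)
        assert len(union) == 27
        assert members["a0"] == ["fisher", "poe_acc"]

    def test_identical_sets_give_10(self):
        import types

        s = types.SimpleNamespace(method="fisher", ranked=[f"x{i}" for i in range(10)])
        union, _ = combine_unique([s, s, s])
        assert len(union) == 10

    def test_disjoint_sets_give_30(self):
        import types

        sels = [
            types.SimpleNamespace(method=m, ranked=[f"{m}{i}" for i in range(10)])
            for m in ("fisher", "poe_acc", "mi")
        ]
        union, _ = combine_unique(sels)
        assert len(union) == 30
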