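import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fuzzysel import (
    AttributeFuzzifier,
    BinaryTable,
    DecisionTable,
    FuzzyScheme,
    RelevanceVerdicts,
    binarize_table,
    binarize_value,
    fuzzy_feature_selection,
    fuzzy_object_selection,
    subtable,
    threshold_ffs,
    threshold_fos,
)
from fuzzysel.datasets import (
    SONAR_V9_OBJECT4_VALUE,
    SONAR_V9_OBJECT5_VALUE,
)


class TestBinarizeValue:
    def test_worked_example_confirmed_range(self, v9_scheme, v9_verdicts):
        assert binarize_value(SONAR_V9_OBJECT4_VALUE, "V9", v9_scheme, v9_verdicts) == 1

    def test_worked_example_rejected_ranges(self, v9_scheme, v9_verdicts):
        assert binarize_value(SONAR_V9_OBJECT5_VALUE, "V9", v9_scheme, v9_verdicts) == 0

    def test_all_confirmed_covers_range(self, v9_scheme):
        fz = v9_scheme["V9"]
        all_conf = RelevanceVerdicts.from_map(
            {f"V9.LV{j}": "confirmed" for j in range(1, fz.k + 1)}
        )
        for x in np.linspace(fz.attr_min, fz.attr_max, 50):
            assert binarize_value(x, "V9", v9_scheme, all_conf) == 1

    def test_unknown_attribute(self, v9_scheme, v9_verdicts):
        with pytest.raises(KeyError):
            binarize_value(0.1, "V10", v9_scheme, v9_verdicts)

    def test_tentative_conservative_by_default(self, v9_scheme):
        v = RelevanceVerdicts.from_map(
            {f"V9.LV{j}": "tentative" for j in range(1, v9_scheme["V9"].k + 1)}
        )
        assert binarize_value(0.0598, "V9", v9_scheme, v) == 0
        assert binarize_value(0.0598, "V9", v9_scheme, v, tentative_as_confirmed=True) == 1


class TestBinarizeTable:
    def _toy(self):
        table = DecisionTable(
            values=np.array([[0.5, 1.0], [2.5, 5.0], [4.5, 10.0]]),
            attributes=("a", "b"),
            decision=np.array(["x", "y", "x"]),
        )
        scheme = FuzzyScheme(
            {
                "a": AttributeFuzzifier.from_boundaries([0, 2, 4, 6]),
                "b": AttributeFuzzifier.from_boundaries([0, 6, 12]),
            }
        )
        return table, scheme

    def test_hand_computed_pattern(self):
        table, scheme = self._toy()
        # a: centers 1,3,5 -> LV2 support [1,5]; b: centers 3,9 -> LV1 support [0,9]
        v = RelevanceVerdicts.from_map(
            {
                "a.LV1": "rejected",
                "a.LV2": "confirmed",
                "a.LV3": "rejected",
                "b.LV1": "confirmed",
                "b.LV2": "rejected",
            }
        )
        binary = binarize_table(table, scheme, v)
        assert binary.matrix.tolist() == [[0, 1], [1, 1], [1, 0]]

    @pytest.mark.parametrize("verdict,expected", [("rejected", 0), ("confirmed", 1)])
    def test_uniform_verdicts(self, verdict, expected):
        table, scheme = self._toy()
        v = RelevanceVerdicts.from_map(
            {f"{a}.LV{j}": verdict for a in ("a", "b") for j in range(1, 4) if not (a == "b" and j == 3)}
        )
        binary = binarize_table(table, scheme, v)
        assert np.all(binary.matrix == expected)
        assert binary.matrix.shape == table.values.shape


class TestThresholds:
    @pytest.mark.parametrize(
        "fn,eps,size,expected",
        [
            (threshold_ffs, 0.10, 208, 20.80),
            (threshold_ffs, 0.11, 208, 22.88),
            (threshold_fos, 0.06, 60, 3.60),
            (threshold_fos, 0.07, 60, 4.20),
        ],
    )
    def test_published_products(self, fn, eps, size, expected):
        assert fn(eps, size) == pytest.approx(expected)

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.2, 1.3])
    def test_eps_domain(self, eps):
        with pytest.raises(ValueError):
            threshold_ffs(eps, 10)

    def test_tiny_eps_selects_every_nonzero_unit(self):
        binary = BinaryTable(
            matrix=np.array([[1, 0], [1, 0], [0, 0]]),
            attributes=("a", "b"),
            objects=(0, 1, 2),
        )
        fs = fuzzy_feature_selection(binary, 1e-9)
        os_ = fuzzy_object_selection(binary, 1e-9)
        assert fs.selected == ("a",)
        assert os_.selected == (0, 1)


class TestSelectors:
    def test_column_sums_vs_strict_threshold(self):
        matrix = np.zeros((5, 3), dtype=int)
        matrix[:, 0] = 1  # sum 5
        matrix[:2, 1] = 1  # sum 2
        binary = BinaryTable(matrix=matrix, attributes=("f1", "f2", "f3"), objects=range(5))
        res = fuzzy_feature_selection(binary, 0.5)  # threshold 2.5
        assert res.selected == ("f1",)
        assert res.counts == {"f1": 5, "f2": 2, "f3": 0}

    def test_count_equal_to_threshold_excluded(self):
        matrix = np.ones((4, 1), dtype=int)
        matrix[2:, 0] = 0  # column sum 2 == 0.5 * 4
        binary = BinaryTable(matrix=matrix, attributes=("f",), objects=range(4))
        assert fuzzy_feature_selection(binary, 0.5).selected == ()

    def test_row_sums_worked_thresholds(self):
        matrix = np.zeros((3, 60), dtype=int)
        matrix[0, :4] = 1
        matrix[1, :3] = 1
        binary = BinaryTable(
            matrix=matrix, attributes=[f"V{i}" for i in range(60)], objects=(0, 1, 2)
        )
        res = fuzzy_object_selection(binary, 0.06)  # threshold 3.60
        assert res.selected == (0,)

    def test_all_zero_table_empty_selection(self):
        binary = BinaryTable(
            matrix=np.zeros((4, 6), dtype=int), attributes=[f"a{i}" for i in range(6)],
            objects=range(4),
        )
        for eps in (0.01, 0.5, 0.99):
            assert fuzzy_object_selection(binary, eps).selected == ()

    def test_eps_above_max_rowsum_fraction_empties_selection(self):
        matrix = np.zeros((3, 10), dtype=int)
        matrix[0, :4] = 1
        binary = BinaryTable(
            matrix=matrix, attributes=[f"a{i}" for i in range(10)], objects=range(3)
        )
        assert fuzzy_object_selection(binary, 0.41).selected == ()

    @given(st.integers(0, 10_000))
    def test_anti_monotone_and_dual(self, seed):
        from conftest import random_binary_table

        rng = np.random.default_rng(seed)
        binary = random_binary_table(rng)
        e1, e2 = sorted(rng.uniform(0.01, 0.99, 2))
        fs1, fs2 = (fuzzy_feature_selection(binary, e) for e in (e1, e2))
        os1, os2 = (fuzzy_object_selection(binary, e) for e in (e1, e2))
        assert set(fs2.selected) <= set(fs1.selected)
        assert set(os2.selected) <= set(os1.selected)
        # duality: object selection == feature selection on the transpose
        dual = fuzzy_feature_selection(binary.transpose(), e1)
        assert tuple(map(str, os1.selected)) == dual.selected

    def test_selection_invariant_to_object_order(self):
        rng = np.random.default_rng(9)
        matrix = rng.integers(0, 2, (8, 5))
        binary = BinaryTable(
            matrix=matrix, attributes=[f"a{i}" for i in range(5)], objects=range(8)
        )
        perm = rng.permutation(8)
        shuffled = BinaryTable(
            matrix=matrix[perm], attributes=binary.attributes,
            objects=[int(i) for i in perm],
        )
        r1 = fuzzy_feature_selection(binary, 0.3)
        r2 = fuzzy_feature_selection(shuffled, 0.3)
        assert r1.selected == r2.selected


class TestSubtable:
    def _table(self):
        rng = np.random.default_rng(0)
        return DecisionTable(
            values=rng.random((6, 4)),
            attributes=("a", "b", "c", "d"),
            decision=np.array(["x", "y"] * 3),
        )

    def test_full_subsets_identity(self):
        t = self._table()
        s = subtable(t, features=t.attributes, objects=t.objects)
        assert np.array_equal(s.values, t.values)
        assert s.attributes == t.attributes

    def test_shape_restriction(self):
        t = self._table()
        s = subtable(t, features=("b", "d"), objects=(0, 2, 5))
        assert (s.m, s.n) == (3, 2)
        assert s.attributes == ("b", "d")
        assert list(s.decision) == ["x", "x", "y"]

    def test_order_preserved_regardless_of_request_order(self):
        t = self._table()
        s = subtable(t, features=("d", "a"))
        assert s.attributes == ("a", "d")

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            subtable(self._table(), features=())
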