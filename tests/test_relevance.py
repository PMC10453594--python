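import numpy as np
import pandas as pd
import pytest

from fuzzysel import (
    RelevanceVerdicts,
    forest_importance,
    select_relevant,
    shadow_extend,
)
from fuzzysel.fuzzify import FuzzyTable
from fuzzysel.relevance import SHADOW_PREFIX


def make_fuzzy(degrees: dict, labels) -> FuzzyTable:
    return FuzzyTable(
        degrees=pd.DataFrame(degrees),
        decision=np.asarray(labels),
        source_attributes=tuple(degrees),
    )


class TestShadowExtend:
    def test_doubles_columns_and_preserves_marginals(self):
        rng = np.random.default_rng(0)
        deg = {f"c{i}": rng.random(30) for i in range(5)}
        ft = make_fuzzy(deg, rng.choice(["a", "b"], 30))
        ext = shadow_extend(ft, seed=1)
        assert ext.degrees.shape[1] == 10
        for c in deg:
            assert sorted(ext.degrees[SHADOW_PREFIX + c]) == sorted(deg[c])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        ft = make_fuzzy({"c": rng.random(20)}, rng.choice(["a", "b"], 20))
        e1 = shadow_extend(ft, seed=7)
        e2 = shadow_extend(ft, seed=7)
        assert e1.degrees.equals(e2.degrees)
        e3 = shadow_extend(ft, seed=8)
        assert not e1.degrees.equals(e3.degrees)

    def test_shadow_class_correlation_near_zero(self):
        cors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = (rng.random(200) < 0.5).astype(float)
            col = y + rng.normal(0, 0.3, 200)  # strongly class-linked column
            ft = make_fuzzy({"c": col}, y)
            ext = shadow_extend(ft, seed=seed)
            cors.append(np.corrcoef(ext.degrees[SHADOW_PREFIX + "c"], y)[0, 1])
        assert abs(np.mean(cors)) < 0.02


class TestForestImportance:
    def test_informative_column_ranks_first(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            y = np.array(["a"] * 100 + ["b"] * 100)
            rng.shuffle(y)
            info = (y == "a").astype(float)
            X = np.column_stack([info] + [rng.random(200) for _ in range(10)])
            imp = forest_importance(X, y, n_trees=50, seed=seed)
            wins += int(np.argmax(imp) == 0)
        assert wins >= 95

    def test_constant_column_zero_importance(self):
        rng = np.random.default_rng(2)
        y = rng.choice(["a", "b"], 100)
        X = np.column_stack([np.full(100, 3.0), (y == "a").astype(float)])
        imp = forest_importance(X, y, n_trees=50, seed=0)
        assert imp[0] == 0.0

    def test_duplicated_column_shares_importance(self):
        # frozen from a 20-seed paired simulation: the two copies split the
        # credit and their sum stays close to the single-copy importance
        sums, singles = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            y = np.array(["a"] * 100 + ["b"] * 100)
            rng.shuffle(y)
            info = (y == "a").astype(float) + rng.normal(0, 0.1, 200)
            noise = rng.random((200, 8))
            imp1 = forest_importance(np.column_stack([info, noise]), y, n_trees=100, seed=s)
            imp2 = forest_importance(
                np.column_stack([info, info, noise]), y, n_trees=100, seed=s
            )
            singles.append(imp1[0])
            sums.append(imp2[0] + imp2[1])
            assert imp2[0] < imp1[0] and imp2[1] < imp1[0]
        ratio = np.mean(sums) / np.mean(singles)
        assert 0.8 < ratio < 1.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            forest_importance(np.random.default_rng(0).random((10, 2)), ["a"] * 10)


class TestSelectRelevant:
    def _signal_table(self, seed, m=200, n_noise=15):
        rng = np.random.default_rng(seed)
        y = np.array(["a"] * (m // 2) + ["b"] * (m - m // 2))
        rng.shuffle(y)
        deg = {"signal": (y == "a") * 0.8 + rng.random(m) * 0.2}
        for i in range(n_noise):
            deg[f"noise{i}"] = rng.random(m)
        return make_fuzzy(deg, y)

    def test_perfect_signal_confirmed_noise_not(self):
        """Columns that separate the classes perfectly are confirmed and pure
        noise columns are not, in nearly every seeded run (20 LVs, m=200)."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = 200
            y = np.array(["a"] * 100 + ["b"] * 100)
            rng.shuffle(y)
            deg = {
                f"sig{i}": np.where(
                    y == "a", rng.uniform(0.6, 1.0, m), rng.uniform(0.0, 0.4, m)
                )
                for i in range(4)
            }
            for i in range(16):
                deg[f"noise{i}"] = rng.random(m)
            v = select_relevant(make_fuzzy(deg, y), n_trees=40, max_iterations=20, seed=seed)
            ok += all(v[f"sig{i}"] == "confirmed" for i in range(4)) and all(
                v[f"noise{i}"] != "confirmed" for i in range(16)
            )
        assert ok >= 19

    def test_all_noise_rarely_confirms(self):
        runs_with_confirms = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.choice(["a", "b"], 200)
            deg = {f"n{i}": rng.random(200) for i in range(10)}
            v = select_relevant(make_fuzzy(deg, y), n_trees=40, max_iterations=15, seed=seed)
            runs_with_confirms += len(v.confirmed()) > 0
        assert runs_with_confirms <= 1

    def test_verdicts_partition_and_bookkeeping(self):
        ft = self._signal_table(0, m=80, n_noise=5)
        v = select_relevant(ft, n_trees=30, max_iterations=10, seed=0)
        assert set(v.verdicts) == set(ft.degrees.columns)
        assert set(v.confirmed()) & set(v.rejected()) == set()
        for lv in v.verdicts:
            assert v.hits[lv] <= v.iterations[lv] <= 10
        assert len(v.msa_history) == v.total_iterations

    def test_deterministic_given_seed(self):
        ft = self._signal_table(3, m=60, n_noise=4)
        v1 = select_relevant(ft, n_trees=20, max_iterations=8, seed=42)
        v2 = select_relevant(ft, n_trees=20, max_iterations=8, seed=42)
        assert v1.verdicts == v2.verdicts
        assert v1.hits == v2.hits
        assert v1.msa_history == v2.msa_history

    def test_monotone_signal_confirmation(self):
        """Raising the class-explained share of an LV never lowers its
        empirical confirmation frequency (3-point effect grid)."""
        freqs = []
        for effect in (0.1, 0.45, 0.8):
            conf = 0
            for seed in range(15):
                rng = np.random.default_rng(seed)
                m = 150
                y = np.array(["a"] * 75 + ["b"] * 75)
                rng.shuffle(y)
                deg = {"lv": (y == "a") * effect + rng.random(m) * (1 - effect)}
                for i in range(6):
                    deg[f"n{i}"] = rng.random(m)
                v = select_relevant(
                    make_fuzzy(deg, y), n_trees=40, max_iterations=15, seed=seed
                )
                conf += v["lv"] == "confirmed"
            freqs.append(conf)
        assert freqs[0] <= freqs[1] <= freqs[2]
        assert freqs[2] >= 13

    def test_invalid_max_iterations(self):
        ft = self._signal_table(0, m=40, n_noise=2)
        with pytest.raises(ValueError):
            select_relevant(ft, max_iterations=0)

    def test_verdict_map_roundtrip(self, tmp_path):
        v = RelevanceVerdicts.from_map({"a.LV1": "confirmed", "a.LV2": "rejected"})
        p = tmp_path / "v.json"
        v.to_json(p)
        back = RelevanceVerdicts.from_json(p)
        assert back.verdicts == v.verdicts
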