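"""All-relevant selection of linguistic variables with shadow attributes.

Each iteration extends the fuzzified table with one shadow per real column
(an independent row permutation, so the marginal is preserved but any link to
the class is destroyed), grows a random forest, and reads off the mean
decrease in Gini impurity per column. The maximum importance among the
shadows (MSA) is the bar a real column must clear to score a *hit*. Columns
whose hit counts are significantly above / below the Binomial(iterations, 1/2)
null are confirmed / rejected; rejected columns drop out of later forests;
whatever is still undecided when the iteration limit is reached stays
*tentative*.

Significance uses the two-step multiple-testing correction of the shadow-
attribute methodology: the one-sided binomial p-values of all undecided
columns are Benjamini-Hochberg corrected across columns, and additionally
Bonferroni-corrected across iterations (p <= alpha / iteration). Without the
across-column correction the column that is luckiest *in the data* — the one
whose in-sample association with the class happens to be the largest among
hundreds of noise columns — would clear the shadow maximum iteration after
iteration and be falsely confirmed at a substantial rate.

This is the Boruta scheme; it is implemented here directly on scikit-learn's
random forest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, false_discovery_control
from sklearn.ensemble import RandomForestClassifier

from ._io import load_json as _load_json
from .fuzzify import FuzzyTable

__all__ = [
    "RelevanceVerdicts",
    "shadow_extend",
    "forest_importance",
    "select_relevant",
    "SHADOW_PREFIX",
]

SHADOW_PREFIX = "shadow_"

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass(frozen=True)
class RelevanceVerdicts:
    """Per-LV verdicts with the evidence that produced them."""

    verdicts: dict[str, str]
    hits: dict[str, int]
    iterations: dict[str, int]  # iterations each LV participated in
    importance_history: dict[str, list[float]]
    msa_history: list[float]
    seed: int
    total_iterations: int = 0

    def __getitem__(self, lv: str) -> str:
        return self.verdicts[lv]

    def confirmed(self) -> list[str]:
        return [lv for lv, v in self.verdicts.items() if v == CONFIRMED]

    def rejected(self) -> list[str]:
        return [lv for lv, v in self.verdicts.items() if v == REJECTED]

    def tentative(self) -> list[str]:
        return [lv for lv, v in self.verdicts.items() if v == TENTATIVE]

    def is_relevant(self, lv: str, tentative_as_confirmed: bool = False) -> bool:
        v = self.verdicts[lv]
        return v == CONFIRMED or (tentative_as_confirmed and v == TENTATIVE)

    @classmethod
    def from_map(cls, verdicts: dict[str, str], seed: int = 0) -> "RelevanceVerdicts":
        """Build a verdict object from a plain {lv: verdict} map (e.g. a
        published worked example used as a fixture)."""
        bad = {v for v in verdicts.values()} - {CONFIRMED, REJECTED, TENTATIVE}
        if bad:
            raise ValueError(f"unknown verdict labels: {bad}")
        return cls(
            verdicts=dict(verdicts),
            hits={lv: 0 for lv in verdicts},
            iterations={lv: 0 for lv in verdicts},
            importance_history={lv: [] for lv in verdicts},
            msa_history=[],
            seed=seed,
        )

    def to_json(self, path=None) -> str:
        payload = {
            lv: {"verdict": v, "hits": self.hits[lv], "iterations": self.iterations[lv]}
            for lv, v in self.verdicts.items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RelevanceVerdicts":
        payload = _load_json(source)
        return cls(
            verdicts={lv: d["verdict"] for lv, d in payload.items()},
            hits={lv: d.get("hits", 0) for lv, d in payload.items()},
            iterations={lv: d.get("iterations", 0) for lv, d in payload.items()},
            importance_history={lv: [] for lv in payload},
            msa_history=[],
            seed=0,
        )


def shadow_extend(table: FuzzyTable, seed: int) -> FuzzyTable:
    """Append one shadow column (independent row permutation) per real column."""
    if table.degrees.shape[1] < 1:
        raise ValueError("need at least one LV column")
    rng = np.random.default_rng(seed)
    shadows = {}
    for col in table.degrees.columns:
        shadows[SHADOW_PREFIX + col] = rng.permutation(table.degrees[col].to_numpy())
    extended = pd.concat(
        [table.degrees, pd.DataFrame(shadows, index=table.degrees.index)], axis=1
    )
    return FuzzyTable(
        degrees=extended, decision=table.decision, source_attributes=table.source_attributes
    )


def forest_importance(table, labels, n_trees: int = 500, seed: int = 0) -> np.ndarray:
    """Per-column mean decrease in Gini impurity from a seeded random forest."""
    X = table.degrees.to_numpy() if isinstance(table, FuzzyTable) else np.asarray(table)
    labels = np.asarray(labels)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain at least 2 classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2**31), n_jobs=1
    )
    forest.fit(X, labels)
    return forest.feature_importances_


def _decide(hits: np.ndarray, n_iter: int, alpha: float):
    """Two-step corrected accept/reject masks for the undecided columns."""
    p_accept = binom.sf(hits - 1, n_iter, 0.5)
    p_reject = binom.cdf(hits, n_iter, 0.5)
    accept = (false_discovery_control(p_accept) <= alpha) & (
        p_accept <= alpha / n_iter
    )
    reject = (false_discovery_control(p_reject) <= alpha) & (
        p_reject <= alpha / n_iter
    )
    return accept, reject


def select_relevant(
    table: FuzzyTable,
    labels=None,
    n_trees: int = 500,
    max_iterations: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> RelevanceVerdicts:
    """Run the shadow-attribute relevance loop over all LV columns.

    Stops early once every column is confirmed or rejected; columns still
    undecided after ``max_iterations`` forests are marked tentative.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    labels = np.asarray(labels if labels is not None else table.decision)
    lvs = list(table.degrees.columns)
    verdicts = {lv: TENTATIVE for lv in lvs}
    hits = {lv: 0 for lv in lvs}
    participated = {lv: 0 for lv in lvs}
    history = {lv: [] for lv in lvs}
    msa_history: list[float] = []
    rng = np.random.default_rng(seed)
    active = list(lvs)  # undecided + confirmed stay in the forest
    undecided = set(lvs)

    it = 0
    while undecided and it < max_iterations:
        it += 1
        sub = FuzzyTable(
            degrees=table.degrees[active],
            decision=table.decision,
            source_attributes=table.source_attributes,
        )
        extended = shadow_extend(sub, seed=int(rng.integers(2**31)))
        imp = forest_importance(
            extended, labels, n_trees=n_trees, seed=int(rng.integers(2**31))
        )
        n_real = len(active)
        real_imp = dict(zip(active, imp[:n_real]))
        msa = float(imp[n_real:].max())
        msa_history.append(msa)
        for lv in active:
            history[lv].append(float(real_imp[lv]))
        undecided_list = sorted(undecided, key=active.index)
        for lv in undecided_list:
            participated[lv] += 1
            if real_imp[lv] > msa:
                hits[lv] += 1
        accept, reject = _decide(
            np.array([hits[lv] for lv in undecided_list]), it, alpha
        )
        for lv, acc, rej in zip(undecided_list, accept, reject):
            if acc:
                verdicts[lv] = CONFIRMED
                undecided.discard(lv)
            elif rej:
                verdicts[lv] = REJECTED
                undecided.discard(lv)
        active = [lv for lv in active if verdicts[lv] != REJECTED]

    return RelevanceVerdicts(
        verdicts=verdicts,
        hits=hits,
        iterations=participated,
        importance_history=history,
        msa_history=msa_history,
        seed=int(seed),
        total_iterations=it,
    )
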