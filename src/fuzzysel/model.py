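"""Model/Results facade over the fuzzy relevance pipeline.

``FuzzyRangeSelector`` is built from a decision table (or DataFrame / CSV)
and ``fit()`` runs the full chain — supervised discretization, triangular
fuzzification, shadow-attribute relevance testing, binarization — returning a
``FuzzyRangeResults`` that carries the fitted schemes and verdicts and
exposes feature/object selection, sub-table extraction, EPS sweeps and a
text summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatable import DecisionTable, read_decision_table
from .discretize import DiscretizationScheme, discretize_table
from .evaluate import SweepRow, TreeParams, eps_sweep, loocv, sweep_frame
from .fuzzify import FuzzyScheme, FuzzyTable, fuzzify_table
from .relevance import RelevanceVerdicts, select_relevant
from .selection import (
    DEFAULT_EPS_GRID,
    BinaryTable,
    SelectionResult,
    binarize_table,
    fuzzy_feature_selection,
    fuzzy_object_selection,
    subtable,
)

__all__ = ["FuzzyRangeSelector", "FuzzyRangeResults"]


class FuzzyRangeSelector:
    """Relevant-range feature and object selector for a decision table."""

    def __init__(self, table: DecisionTable):
        self.table = table

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, decision_column: str = "class"):
        return cls(DecisionTable.from_frame(df, decision_column=decision_column))

    @classmethod
    def from_csv(cls, path, decision_column: str = "class"):
        return cls(read_decision_table(path, decision_column=decision_column))

    def fit(
        self,
        n_trees: int = 500,
        max_iterations: int = 100,
        alpha: float = 0.01,
        seed: int = 0,
        tentative_as_confirmed: bool = False,
    ) -> "FuzzyRangeResults":
        """Discretize, fuzzify, test LV relevance and binarize the table."""
        self.table.require_supervised("fitting the fuzzy relevance pipeline")
        disc = discretize_table(self.table)
        scheme = FuzzyScheme.from_discretization(disc)
        fuzzy = fuzzify_table(self.table, scheme)
        verdicts = select_relevant(
            fuzzy,
            n_trees=n_trees,
            max_iterations=max_iterations,
            alpha=alpha,
            seed=seed,
        )
        binary = binarize_table(
            self.table, scheme, verdicts, tentative_as_confirmed=tentative_as_confirmed
        )
        return FuzzyRangeResults(
            model=self,
            discretization=disc,
            scheme=scheme,
            fuzzy=fuzzy,
            verdicts=verdicts,
            binary=binary,
            seed=seed,
        )


@dataclass
class FuzzyRangeResults:
    """Fitted schemes, verdicts and the binary relevance table."""

    model: FuzzyRangeSelector
    discretization: DiscretizationScheme
    scheme: FuzzyScheme
    fuzzy: FuzzyTable
    verdicts: RelevanceVerdicts
    binary: BinaryTable
    seed: int

    @property
    def table(self) -> DecisionTable:
        return self.model.table

    def select_features(self, eps: float) -> SelectionResult:
        return fuzzy_feature_selection(self.binary, eps)

    def select_objects(self, eps: float) -> SelectionResult:
        return fuzzy_object_selection(self.binary, eps)

    def subtable(self, eps_features: float = None, eps_objects: float = None) -> DecisionTable:
        """Joint reduction: FFS and FOS run independently and intersected."""
        feats = self.select_features(eps_features).selected if eps_features else None
        objs = self.select_objects(eps_objects).selected if eps_objects else None
        return subtable(self.table, features=feats, objects=objs)

    def sweep(
        self,
        mode: str,
        positive,
        grid=DEFAULT_EPS_GRID,
        params: TreeParams = TreeParams(),
    ) -> list[SweepRow]:
        return eps_sweep(
            self.table,
            self.scheme,
            self.verdicts,
            mode=mode,
            positive=positive,
            grid=grid,
            params=params,
            binary=self.binary,
        )

    def sweep_frame(self, mode: str, positive, grid=DEFAULT_EPS_GRID, params=TreeParams()):
        return sweep_frame(self.sweep(mode, positive, grid, params), mode=mode)

    def evaluate(self, positive, params: TreeParams = TreeParams()):
        """LOOCV metrics of the unreduced table (the baseline row)."""
        return loocv(self.table, positive, params)

    def summary(self) -> str:
        t = self.table
        v = self.verdicts
        lines = [
            "Fuzzy relevance-range selection",
            "=" * 47,
            f"objects (m):            {t.m}",
            f"attributes (n):         {t.n}",
            f"classes:                {', '.join(map(str, t.classes))}",
            f"linguistic variables:   {len(v.verdicts)}",
            f"  confirmed:            {len(v.confirmed())}",
            f"  rejected:             {len(v.rejected())}",
            f"  tentative:            {len(v.tentative())}",
            f"relevance iterations:   {v.total_iterations}",
            f"seed:                   {self.seed}",
            "-" * 47,
            "confirmed ranges per attribute:",
        ]
        for attr in t.attributes:
            fz = self.scheme[attr]
            spans = []
            for j in range(1, fz.k + 1):
                name = f"{attr}.LV{j}"
                if v.verdicts.get(name) == "confirmed":
                    lo, hi = fz.support(j)
                    spans.append(f"[{lo:g}, {hi:g}]")
            lines.append(f"  {attr}: {' '.join(spans) if spans else '(none)'}")
        return "\n".join(lines)
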