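"""Leave-one-out evaluation and EPS sweeps.

Classification quality of a (reduced) decision table is measured with a
single decision tree refit in each of the m leave-one-out folds; the m
held-out predictions are pooled into one confusion matrix. A sweep runs the
feature (or object) selector over a grid of EPS values, evaluates each
reduced table, and appends the full-table baseline row last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .datatable import DecisionTable, MetricsReport, compute_metrics, confusion_counts
from .fuzzify import FuzzyScheme
from .relevance import RelevanceVerdicts
from .selection import (
    DEFAULT_EPS_GRID,
    binarize_table,
    fuzzy_feature_selection,
    fuzzy_object_selection,
    subtable,
)

__all__ = ["TreeParams", "SweepRow", "train_tree", "loocv", "eps_sweep", "sweep_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreeParams:
    """Decision-tree settings for evaluation.

    ``criterion`` defaults to the information-based "entropy" split;
    ``min_leaf`` is the minimal leaf size (mild pre-pruning); ``seed`` fixes
    the tie-breaking of equally good splits.
    """

    criterion: str = "entropy"
    min_leaf: int = 1
    max_depth: int | None = None
    seed: int = 0

    def build(self) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion=self.criterion,
            min_samples_leaf=self.min_leaf,
            max_depth=self.max_depth,
            random_state=int(self.seed) % (2**31),
        )


@dataclass(frozen=True)
class SweepRow:
    """One grid point of an EPS sweep (or the baseline row, eps=None)."""

    eps: float | None
    threshold: float | None
    subset_size: int
    metrics: MetricsReport | None


def train_tree(table: DecisionTable, params: TreeParams = TreeParams()) -> DecisionTreeClassifier:
    """Fit a single decision tree on the full table."""
    table.require_supervised("tree induction")
    tree = params.build()
    tree.fit(table.values, table.decision)
    return tree


def loocv(
    table: DecisionTable,
    positive,
    params: TreeParams = TreeParams(),
) -> MetricsReport:
    """Leave-one-out cross-validation with pooled confusion counts."""
    table.require_supervised("LOOCV evaluation")
    if table.m < 3:
        raise ValueError("LOOCV needs at least 3 objects")
    if positive not in set(table.decision.tolist()):
        raise ValueError(f"positive label {positive!r} absent from the decision column")
    m = table.m
    preds = np.empty(m, dtype=object)
    mask = np.ones(m, dtype=bool)
    for i in range(m):
        mask[i] = False
        y_train = table.decision[mask]
        if len(pd.unique(y_train)) < 2:
            logger.info("fold %d trains on a single class; tree predicts that class", i)
        tree = params.build()
        tree.fit(table.values[mask], y_train)
        preds[i] = tree.predict(table.values[i : i + 1])[0]
        mask[i] = True
    counts = confusion_counts(preds, table.decision, positive)
    return compute_metrics(counts)


def eps_sweep(
    table: DecisionTable,
    scheme: FuzzyScheme,
    verdicts: RelevanceVerdicts,
    mode: str,
    positive,
    grid=DEFAULT_EPS_GRID,
    params: TreeParams = TreeParams(),
    binary=None,
) -> list[SweepRow]:
    """Selector + LOOCV over an EPS grid, baseline row appended last.

    Feature mode keeps all objects and evaluates the selected attributes;
    object mode keeps all attributes and evaluates the selected objects.
    Identical selections at different EPS values share one LOOCV run.
    """
    if mode not in ("features", "objects"):
        raise ValueError("mode must be 'features' or 'objects'")
    if binary is None:
        binary = binarize_table(table, scheme, verdicts)
    cache: dict[frozenset, MetricsReport | None] = {}
    rows: list[SweepRow] = []
    for eps in grid:
        if mode == "features":
            sel = fuzzy_feature_selection(binary, eps)
        else:
            sel = fuzzy_object_selection(binary, eps)
        key = frozenset(sel.selected)
        if key not in cache:
            if len(sel.selected) == 0:
                cache[key] = None
            else:
                sub = (
                    subtable(table, features=sel.selected)
                    if mode == "features"
                    else subtable(table, objects=sel.selected)
                )
                try:
                    cache[key] = loocv(sub, positive, params)
                except ValueError:  # e.g. reduced table lost a class or got too small
                    logger.warning("LOOCV undefined at EPS=%s (degenerate subtable)", eps)
                    cache[key] = None
        rows.append(
            SweepRow(
                eps=float(eps),
                threshold=sel.threshold,
                subset_size=len(sel.selected),
                metrics=cache[key],
            )
        )
    baseline = loocv(table, positive, params)
    rows.append(
        SweepRow(
            eps=None,
            threshold=None,
            subset_size=table.n if mode == "features" else table.m,
            metrics=baseline,
        )
    )
    return rows


def sweep_frame(rows: list[SweepRow], mode: str = "features") -> pd.DataFrame:
    """Tabulate sweep rows (one line per EPS, baseline labelled 'original set')."""
    records = []
    size_col = "n_features" if mode == "features" else "n_objects"
    for r in rows:
        rec = {
            size_col: r.subset_size,
            "EPS": r.eps if r.eps is not None else "original set",
            "threshold": r.threshold,
        }
        if r.metrics is None:
            rec.update({k: None for k in ("ACC", "TPR", "TNR", "PPV", "MCC", "F1")})
        else:
            rec.update(
                {
                    k: (None if np.isnan(getattr(r.metrics, k)) else getattr(r.metrics, k))
                    for k in ("ACC", "TPR", "TNR", "PPV", "MCC", "F1")
                }
            )
        records.append(rec)
    return pd.DataFrame(records)
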