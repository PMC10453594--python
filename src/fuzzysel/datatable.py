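"""Decision tables and classification metrics.

A decision table DT = (U, A, D) arranges data as m objects (U) described by n
continuous condition attributes (A) and one categorical decision attribute (D).
This module houses that container, CSV/ARFF ingestion with validation, and the
confusion-matrix quality measures (ACC, TPR, TNR, PPV, MCC, F1) used to judge
classifiers built on reduced tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DecisionTable",
    "MetricsReport",
    "read_decision_table",
    "write_decision_table",
    "confusion_counts",
    "compute_metrics",
]


class SingleClassWarning(UserWarning):
    """The decision column holds a single class label."""


@dataclass(frozen=True)
class DecisionTable:
    """An m x n numeric condition matrix plus a categorical decision vector.

    Parameters
    ----------
    values : (m, n) float array
        Condition-attribute values; must be finite.
    attributes : list of str
        Unique condition-attribute names, column order preserved.
    decision : (m,) array
        Class label per object.
    objects : list
        Object identifiers (defaults to 0..m-1).
    """

    values: np.ndarray
    attributes: tuple[str, ...]
    decision: np.ndarray
    objects: tuple = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        decision = np.asarray(self.decision)
        attributes = tuple(str(a) for a in self.attributes)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = values.shape
        if m < 1 or n < 1:
            raise ValueError("decision table needs at least one object and one attribute")
        if len(attributes) != n:
            raise ValueError(f"{len(attributes)} attribute names for {n} columns")
        if len(set(attributes)) != n:
            raise ValueError("attribute names must be unique")
        if decision.shape != (m,):
            raise ValueError(f"decision vector length {decision.shape} != m={m}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite condition value at object {bad[0]}, attribute "
                f"{attributes[bad[1]]!r}"
            )
        objects = self.objects
        if objects is None:
            objects = tuple(range(m))
        else:
            objects = tuple(objects)
            if len(objects) != m:
                raise ValueError("objects length mismatch")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "decision", decision)
        object.__setattr__(self, "attributes", attributes)
        object.__setattr__(self, "objects", objects)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple:
        return tuple(pd.unique(self.decision))

    @property
    def single_class(self) -> bool:
        return len(self.classes) < 2

    def require_supervised(self, what: str = "this operation") -> None:
        if self.single_class:
            raise ValueError(f"{what} requires at least 2 distinct class labels")

    def to_frame(self, decision_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.attributes), index=list(self.objects))
        df[decision_column] = self.decision
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, decision_column: str = "class") -> "DecisionTable":
        if decision_column not in df.columns:
            raise ValueError(f"decision column {decision_column!r} not in frame")
        cond = df.drop(columns=[decision_column])
        for col in cond.columns:
            coerced = pd.to_numeric(cond[col], errors="coerce")
            bad = coerced.isna() & cond[col].notna()
            if bad.any():
                row = bad.idxmax()
                raise ValueError(
                    f"non-numeric condition value at row {row!r}, column {col!r}: "
                    f"{cond.loc[row, col]!r}"
                )
            if coerced.isna().any():
                row = coerced.isna().idxmax()
                raise ValueError(f"missing condition value at row {row!r}, column {col!r}")
            cond[col] = coerced
        dec = df[decision_column]
        if dec.isna().any():
            row = dec.isna().idxmax()
            raise ValueError(f"missing decision label at row {row!r}")
        table = cls(
            values=cond.to_numpy(dtype=float),
            attributes=tuple(map(str, cond.columns)),
            decision=dec.to_numpy(),
            objects=tuple(df.index),
        )
        if table.single_class:
            warnings.warn(
                "decision table holds a single class; selection is allowed but "
                "supervised evaluation will be refused",
                SingleClassWarning,
                stacklevel=2,
            )
        return table

    def subset(self, objects=None, attributes=None) -> "DecisionTable":
        """Row/column restriction preserving order (see selection.subtable)."""
        rows = np.arange(self.m) if objects is None else np.asarray(objects, dtype=int)
        if attributes is None:
            cols = np.arange(self.n)
        else:
            index = {a: i for i, a in enumerate(self.attributes)}
            cols = np.asarray(
                [index[a] if isinstance(a, str) else int(a) for a in attributes], dtype=int
            )
        if rows.size == 0 or cols.size == 0:
            raise ValueError("subset would produce an empty decision table")
        return DecisionTable(
            values=self.values[np.ix_(rows, cols)],
            attributes=tuple(self.attributes[c] for c in cols),
            decision=self.decision[rows],
            objects=tuple(self.objects[r] for r in rows),
        )


def read_decision_table(path, fmt: str | None = None, decision_column="class") -> DecisionTable:
    """Load a decision table from CSV (RFC-4180, header row) or ARFF.

    ``decision_column`` may be a column name or a 0-based positional index.
    All non-decision columns must be fully numeric; missing values are rejected.
    """
    path = str(path)
    if fmt is None:
        fmt = "arff" if path.lower().endswith(".arff") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "arff":
        from scipy.io import arff

        data, _meta = arff.loadarff(path)
        df = pd.DataFrame(data)
        for col in df.columns:  # scipy yields bytes for nominal attributes
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if isinstance(decision_column, int):
        decision_column = df.columns[decision_column]
    return DecisionTable.from_frame(df, decision_column=decision_column)


def write_decision_table(table: DecisionTable, path, decision_column: str = "class") -> None:
    table.to_frame(decision_column).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived quality scores.

    Scores with a zero denominator are carried as NaN — explicitly *undefined*,
    never silently 0 (reduced tables can lose one class entirely, leaving e.g.
    precision with no positive predictions to average over).
    """

    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float = math.nan
    TPR: float = math.nan
    TNR: float = math.nan
    PPV: float = math.nan
    MCC: float = math.nan
    F1: float = math.nan

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def is_undefined(self, score: str) -> bool:
        return math.isnan(getattr(self, score))

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in ("TP", "TN", "FP", "FN")}
        for k in ("ACC", "TPR", "TNR", "PPV", "MCC", "F1"):
            v = getattr(self, k)
            out[k] = None if math.isnan(v) else v
        return out

    def format_row(self, digits: int = 2) -> str:
        """Scores as a tab-separated row, NaN rendered as '-'."""
        cells = []
        for k in ("ACC", "TPR", "TNR", "PPV", "MCC", "F1"):
            v = getattr(self, k)
            cells.append("-" if math.isnan(v) else f"{round(v, digits):g}")
        return "\t".join(cells)


def confusion_counts(predicted, truth, positive) -> MetricsReport:
    """Pool a prediction/truth pair into TP/TN/FP/FN with ``positive`` as the
    condition-present class. Score fields are left unset (NaN)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    pos_pred = predicted == positive
    pos_true = truth == positive
    return MetricsReport(
        TP=int(np.sum(pos_pred & pos_true)),
        TN=int(np.sum(~pos_pred & ~pos_true)),
        FP=int(np.sum(pos_pred & ~pos_true)),
        FN=int(np.sum(~pos_pred & pos_true)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(counts: MetricsReport) -> MetricsReport:
    """Fill in ACC, TPR, TNR, PPV, MCC and F1 from the four counts.

    F1 is the harmonic mean of PPV and TPR; it is undefined whenever either
    factor is undefined or both are 0 (a table row with no positive
    predictions and no positives prints "-", not 0).
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if tp + tn + fp + fn == 0:
        raise ValueError("all-zero confusion counts")
    acc = _ratio(tp + tn, tp + tn + fp + fn)
    tpr = _ratio(tp, tp + fn)
    tnr = _ratio(tn, fp + tn)
    ppv = _ratio(tp, tp + fp)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan
    if math.isnan(ppv) or math.isnan(tpr) or (ppv + tpr) == 0:
        f1 = math.nan
    else:
        f1 = 2 * ppv * tpr / (ppv + tpr)  # == 2TP/(2TP+FP+FN) when defined
    return replace(counts, ACC=acc, TPR=tpr, TNR=tnr, PPV=ppv, MCC=mcc, F1=f1)
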