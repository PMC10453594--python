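"""Binary relevance table and the two threshold selectors (FFS / FOS).

A raw value scores 1 iff it lies inside the closed support of at least one
*confirmed* linguistic variable of its attribute — crisp containment, OR-ed
over the covering LVs, not max-membership assignment. Column sums of the
resulting 0/1 table drive fuzzy feature selection (keep attributes with more
than EPS*m relevant-range hits) and row sums drive fuzzy object selection
(keep objects with more than EPS*n hits). Both comparisons are strict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatable import DecisionTable
from .fuzzify import FuzzyScheme, lv_name
from .relevance import RelevanceVerdicts

__all__ = [
    "BinaryTable",
    "SelectionResult",
    "binarize_value",
    "binarize_table",
    "threshold_ffs",
    "threshold_fos",
    "fuzzy_feature_selection",
    "fuzzy_object_selection",
    "subtable",
    "DEFAULT_EPS_GRID",
]

# EPS sweep grid used throughout: 0.01 .. 0.29 step 0.01
DEFAULT_EPS_GRID = tuple(round(0.01 * i, 2) for i in range(1, 30))


@dataclass(frozen=True)
class BinaryTable:
    """m x n {0,1} relevance indicators, same shape as the source table."""

    matrix: np.ndarray
    attributes: tuple[str, ...]
    objects: tuple
    scheme: FuzzyScheme = None
    verdicts: RelevanceVerdicts = None

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=np.int8)
        if matrix.ndim != 2:
            raise ValueError("binary matrix must be 2-D")
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        if matrix.shape[1] != len(self.attributes):
            raise ValueError("attribute count mismatch")
        if matrix.shape[0] != len(self.objects):
            raise ValueError("object count mismatch")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "objects", tuple(self.objects))

    @property
    def m(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def transpose(self) -> "BinaryTable":
        return BinaryTable(
            matrix=self.matrix.T, attributes=tuple(map(str, self.objects)),
            objects=tuple(self.attributes),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(self.attributes),
                          index=list(self.objects))
        df.to_csv(path, sep="\t", index_label="object")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one FFS or FOS run at a fixed EPS."""

    mode: str  # "features" | "objects"
    eps: float
    threshold: float
    counts: dict
    selected: tuple

    def __len__(self) -> int:
        return len(self.selected)

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode,
            "EPS": self.eps,
            "threshold": self.threshold,
            "selected": list(map(str, self.selected)),
            "counts": {str(k): int(v) for k, v in self.counts.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _confirmed_supports(attribute, scheme, verdicts, tentative_as_confirmed=False):
    fz = scheme[attribute]
    out = []
    for j in range(1, fz.k + 1):
        name = lv_name(attribute, j)
        if name in verdicts.verdicts and verdicts.is_relevant(name, tentative_as_confirmed):
            out.append(fz.support(j))
    return out


def binarize_value(
    x: float,
    attribute: str,
    scheme: FuzzyScheme,
    verdicts: RelevanceVerdicts,
    tentative_as_confirmed: bool = False,
) -> int:
    """1 iff ``x`` lies within the closed support of some confirmed LV."""
    if attribute not in scheme:
        raise KeyError(f"unknown attribute {attribute!r}")
    fz = scheme[attribute]
    x = min(max(float(x), fz.attr_min), fz.attr_max)
    for lo, hi in _confirmed_supports(attribute, scheme, verdicts, tentative_as_confirmed):
        if lo <= x <= hi:
            return 1
    return 0


def binarize_table(
    table: DecisionTable,
    scheme: FuzzyScheme,
    verdicts: RelevanceVerdicts,
    tentative_as_confirmed: bool = False,
) -> BinaryTable:
    """Element-wise relevant-range test over the whole decision table."""
    missing = [a for a in table.attributes if a not in scheme]
    if missing:
        raise ValueError(f"scheme lacks attributes: {missing}")
    matrix = np.zeros((table.m, table.n), dtype=np.int8)
    for idx, attr in enumerate(table.attributes):
        fz = scheme[attr]
        col = np.clip(table.values[:, idx], fz.attr_min, fz.attr_max)
        hit = np.zeros(table.m, dtype=bool)
        for lo, hi in _confirmed_supports(attr, scheme, verdicts, tentative_as_confirmed):
            hit |= (col >= lo) & (col <= hi)
        matrix[:, idx] = hit
    return BinaryTable(
        matrix=matrix,
        attributes=table.attributes,
        objects=table.objects,
        scheme=scheme,
        verdicts=verdicts,
    )


def _check_eps(eps: float) -> float:
    eps = float(eps)
    if not 0.0 < eps < 1.0:
        raise ValueError(f"EPS must lie strictly between 0 and 1, got {eps}")
    return eps


def threshold_ffs(eps: float, m: int) -> float:
    """Feature-selection threshold: EPS * m (m = number of objects)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return _check_eps(eps) * m


def threshold_fos(eps: float, n: int) -> float:
    """Object-selection threshold: EPS * n (n = number of attributes)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _check_eps(eps) * n


def fuzzy_feature_selection(binary: BinaryTable, eps: float) -> SelectionResult:
    """Keep attributes whose relevant-range count (column sum) strictly
    exceeds EPS * m; original column order preserved."""
    thr = threshold_ffs(eps, binary.m)
    sums = binary.column_sums()
    selected = tuple(a for a, s in zip(binary.attributes, sums) if s > thr)
    return SelectionResult(
        mode="features",
        eps=float(eps),
        threshold=thr,
        counts=dict(zip(binary.attributes, map(int, sums))),
        selected=selected,
    )


def fuzzy_object_selection(binary: BinaryTable, eps: float) -> SelectionResult:
    """Keep objects whose relevant-range count (row sum) strictly exceeds
    EPS * n; original row order preserved."""
    thr = threshold_fos(eps, binary.n)
    sums = binary.row_sums()
    selected = tuple(o for o, s in zip(binary.objects, sums) if s > thr)
    return SelectionResult(
        mode="objects",
        eps=float(eps),
        threshold=thr,
        counts=dict(zip(binary.objects, map(int, sums))),
        selected=selected,
    )


def subtable(table: DecisionTable, features=None, objects=None) -> DecisionTable:
    """Restrict a decision table to selected features and/or objects.

    ``features`` are attribute names; ``objects`` are object identifiers (as
    carried by the table). Order of the original table is preserved.
    """
    attr_keep = None
    if features is not None:
        features = set(features)
        attr_keep = [a for a in table.attributes if a in features]
    row_keep = None
    if objects is not None:
        objects = set(objects)
        row_keep = [i for i, o in enumerate(table.objects) if o in objects]
    return table.subset(objects=row_keep, attributes=attr_keep)
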