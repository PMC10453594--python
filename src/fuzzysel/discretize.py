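"""Supervised discretization by local discernibility cuts.

Each continuous attribute is partitioned into disjoint sub-intervals by cut
points chosen with a decision-tree-style local strategy: among the boundary
candidates (midpoints between adjacent distinct values whose neighbourhoods
mix classes), greedily pick the cut that discerns the most opposite-class
object pairs on the current subset, split, and recurse on each side until a
subset is class-pure, has fewer than two distinct values, or no candidate
discerns any pair. The resulting cut set is consistent with the table (every
opposite-class pair that differs on the attribute and admits a boundary cut is
separated) and locally semi-optimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._io import load_json as _load_json
from .datatable import DecisionTable

__all__ = [
    "AttributeCuts",
    "DiscretizationScheme",
    "candidate_cuts",
    "cut_quality",
    "local_cuts",
    "discretize_table",
]


@dataclass(frozen=True)
class AttributeCuts:
    """Range and interior cut points of one attribute."""

    attr_min: float
    attr_max: float
    cuts: tuple[float, ...]

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cuts)
        bnd = (self.attr_min, *cuts, self.attr_max)
        if any(b1 >= b2 for b1, b2 in zip(bnd, bnd[1:])) and len(bnd) > 1:
            if not (len(cuts) == 0 and self.attr_min == self.attr_max):
                raise ValueError(f"boundaries not strictly increasing: {bnd}")
        object.__setattr__(self, "cuts", cuts)

    @property
    def boundaries(self) -> tuple[float, ...]:
        """[attr_min, cuts..., attr_max] — the sub-interval boundary chain."""
        return (self.attr_min, *self.cuts, self.attr_max)

    @property
    def n_intervals(self) -> int:
        return len(self.cuts) + 1


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-attribute boundary chains for a fitted decision table."""

    per_attribute: dict[str, AttributeCuts]

    def __getitem__(self, attr: str) -> AttributeCuts:
        return self.per_attribute[attr]

    def __contains__(self, attr: str) -> bool:
        return attr in self.per_attribute

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.per_attribute)

    def to_json(self, path=None) -> str:
        payload = {
            a: {"min": c.attr_min, "max": c.attr_max, "cuts": list(c.cuts)}
            for a, c in self.per_attribute.items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DiscretizationScheme":
        payload = _load_json(source)
        return cls(
            {
                a: AttributeCuts(attr_min=d["min"], attr_max=d["max"], cuts=tuple(d["cuts"]))
                for a, d in payload.items()
            }
        )


def _value_groups(values, labels):
    """Sorted distinct values with per-group class-count matrix."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    classes, y = np.unique(labels, return_inverse=True)
    vals, inv = np.unique(values, return_inverse=True)
    counts = np.zeros((vals.size, classes.size), dtype=np.int64)
    np.add.at(counts, (inv, y), 1)
    return vals, counts


def candidate_cuts(values, labels) -> np.ndarray:
    """Boundary cuts: midpoints between adjacent distinct values whose two
    value-groups are not both pure with the same single class."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    vals, counts = _value_groups(values, labels)
    if vals.size < 2:
        return np.empty(0)
    keep = []
    for i in range(vals.size - 1):
        left, right = counts[i], counts[i + 1]
        lnz = np.flatnonzero(left)
        rnz = np.flatnonzero(right)
        pure_same = lnz.size == 1 and rnz.size == 1 and lnz[0] == rnz[0]
        if not pure_same:
            keep.append((vals[i] + vals[i + 1]) / 2.0)
    return np.asarray(keep)


def cut_quality(cut: float, values, labels) -> int:
    """Number of opposite-class object pairs separated by ``cut`` (one object
    strictly on each side), on the supplied subset."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not (values.min() < cut < values.max()):
        raise ValueError(f"cut {cut} outside the open value range")
    left = values < cut
    right = values > cut  # a value equal to the cut sits on neither side
    classes = np.unique(labels)
    lc = np.array([np.sum(left & (labels == c)) for c in classes], dtype=np.int64)
    rc = np.array([np.sum(right & (labels == c)) for c in classes], dtype=np.int64)
    return int(lc.sum() * rc.sum() - np.dot(lc, rc))


def local_cuts(values, labels) -> np.ndarray:
    """Greedy recursive best-cut selection (local strategy).

    Ties on quality break to the smallest cut value, which makes the result
    independent of object order.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    vals, counts = _value_groups(values, labels)
    selected: list[float] = []
    _recurse(vals, counts, selected)
    return np.asarray(sorted(selected))


def _recurse(vals, counts, selected) -> None:
    if vals.size < 2:
        return
    class_totals = counts.sum(axis=0)
    if np.count_nonzero(class_totals) < 2:  # class-pure subset
        return
    # candidate gaps and their discerned-pair counts via prefix sums
    pref = np.cumsum(counts, axis=0)
    total = class_totals.astype(np.int64)
    best_q = 0
    best_i = -1
    for i in range(vals.size - 1):
        left, right = counts[i], counts[i + 1]
        lnz = np.flatnonzero(left)
        rnz = np.flatnonzero(right)
        if lnz.size == 1 and rnz.size == 1 and lnz[0] == rnz[0]:
            continue  # not a boundary gap
        lc = pref[i]
        rc = total - lc
        q = int(lc.sum() * rc.sum() - np.dot(lc, rc))
        if q > best_q:  # strict: ties keep the earlier (smaller) cut
            best_q = q
            best_i = i
    if best_i < 0:  # no candidate discerns any pair
        return
    selected.append(float((vals[best_i] + vals[best_i + 1]) / 2.0))
    _recurse(vals[: best_i + 1], counts[: best_i + 1], selected)
    _recurse(vals[best_i + 1 :], counts[best_i + 1 :], selected)


def discretize_table(table: DecisionTable) -> DiscretizationScheme:
    """Fit local cuts for every condition attribute of ``table``."""
    table.require_supervised("discretization")
    per = {}
    for j, attr in enumerate(table.attributes):
        col = table.values[:, j]
        lo, hi = float(col.min()), float(col.max())
        if lo == hi or table.m < 2:
            cuts: tuple[float, ...] = ()
        else:
            cuts = tuple(local_cuts(col, table.decision))
        per[attr] = AttributeCuts(attr_min=lo, attr_max=hi, cuts=cuts)
    return DiscretizationScheme(per)
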