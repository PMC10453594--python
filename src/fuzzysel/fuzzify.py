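"""Triangular fuzzification of discretized attributes into linguistic variables.

Every sub-interval of a discretization scheme contributes one linguistic
variable (LV) whose membership function peaks at the sub-interval center c_j
and falls linearly to 0 at the neighbouring centers; the first and last LVs
are trapezoids, flat at 1 from the range edge to their center. For any
in-range x the memberships of an attribute's LVs form a partition of unity:
at most two LVs are non-zero and their degrees sum to 1.

The support of LV_j — the closed range over which its membership is positive —
is [attr_min, c_2] for j=1, [c_{j-1}, c_{j+1}] for interior j, and
[c_{k-1}, attr_max] for j=k. These supports are what the downstream
binarization tests raw values against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._io import load_json as _load_json
from .datatable import DecisionTable
from .discretize import DiscretizationScheme

__all__ = [
    "AttributeFuzzifier",
    "FuzzyScheme",
    "FuzzyTable",
    "interval_centers",
    "lv_support",
    "membership",
    "fuzzify_table",
    "lv_name",
]


def lv_name(attribute: str, j: int) -> str:
    """Column name of the j-th (1-based) linguistic variable of an attribute."""
    return f"{attribute}.LV{j}"


def interval_centers(boundaries) -> np.ndarray:
    """Midpoints of consecutive boundary pairs: c_j = (b_{j-1} + b_j) / 2."""
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.size < 2:
        raise ValueError("need at least 2 boundaries")
    if np.any(np.diff(boundaries) <= 0):
        if not (boundaries.size == 2 and boundaries[0] == boundaries[1]):
            raise ValueError("boundaries must be strictly increasing")
    return (boundaries[:-1] + boundaries[1:]) / 2.0


@dataclass(frozen=True)
class AttributeFuzzifier:
    """Centers, range and LV supports of a single attribute."""

    attr_min: float
    attr_max: float
    centers: tuple[float, ...]

    @classmethod
    def from_boundaries(cls, boundaries) -> "AttributeFuzzifier":
        boundaries = np.asarray(boundaries, dtype=float)
        return cls(
            attr_min=float(boundaries[0]),
            attr_max=float(boundaries[-1]),
            centers=tuple(interval_centers(boundaries)),
        )

    @property
    def k(self) -> int:
        return len(self.centers)

    def support(self, j: int) -> tuple[float, float]:
        """Closed support of LV_j (1-based)."""
        k = self.k
        if not 1 <= j <= k:
            raise IndexError(f"LV index {j} out of range 1..{k}")
        c = self.centers
        if k == 1:
            return (self.attr_min, self.attr_max)
        if j == 1:
            return (self.attr_min, c[1])
        if j == k:
            return (c[k - 2], self.attr_max)
        return (c[j - 2], c[j])

    def membership(self, x: float, j: int) -> float:
        """Degree of x in LV_j; out-of-range x is clamped to [attr_min, attr_max].

        The piecewise cases are evaluated in their printed order, first match
        wins. The edge LVs are trapezoids (flat at 1 beyond their center).
        """
        k = self.k
        if not 1 <= j <= k:
            raise IndexError(f"LV index {j} out of range 1..{k}")
        a, b = self.attr_min, self.attr_max
        x = min(max(float(x), a), b)
        if k == 1:
            return 1.0
        c = self.centers
        if j == 1:
            if a <= x <= c[0]:
                return 1.0
            if c[0] < x <= c[1]:
                return (c[1] - x) / (c[1] - c[0])
            return 0.0
        if j == k:
            if c[k - 2] <= x <= c[k - 1]:
                return (x - c[k - 2]) / (c[k - 1] - c[k - 2])
            if c[k - 1] < x <= b:
                return 1.0
            return 0.0
        if c[j - 2] <= x <= c[j - 1]:
            return (x - c[j - 2]) / (c[j - 1] - c[j - 2])
        if c[j - 1] < x <= c[j]:
            return (c[j] - x) / (c[j] - c[j - 1])
        return 0.0

    def membership_column(self, x, j: int) -> np.ndarray:
        """Vectorized :meth:`membership` over an array of raw values."""
        k = self.k
        if not 1 <= j <= k:
            raise IndexError(f"LV index {j} out of range 1..{k}")
        x = np.clip(np.asarray(x, dtype=float), self.attr_min, self.attr_max)
        if k == 1:
            return np.ones_like(x)
        c = self.centers
        out = np.zeros_like(x)
        if j == 1:
            rising = x <= c[0]
            out[rising] = 1.0
            falling = (c[0] < x) & (x <= c[1])
            out[falling] = (c[1] - x[falling]) / (c[1] - c[0])
        elif j == k:
            rising = (c[k - 2] <= x) & (x <= c[k - 1])
            out[rising] = (x[rising] - c[k - 2]) / (c[k - 1] - c[k - 2])
            out[x > c[k - 1]] = 1.0
        else:
            rising = (c[j - 2] <= x) & (x <= c[j - 1])
            out[rising] = (x[rising] - c[j - 2]) / (c[j - 1] - c[j - 2])
            falling = (c[j - 1] < x) & (x <= c[j])
            out[falling] = (c[j] - x[falling]) / (c[j] - c[j - 1])
        return out


@dataclass(frozen=True)
class FuzzyScheme:
    """Per-attribute fuzzifiers derived from a discretization scheme."""

    per_attribute: dict[str, AttributeFuzzifier]

    @classmethod
    def from_discretization(cls, disc: DiscretizationScheme) -> "FuzzyScheme":
        return cls(
            {
                attr: AttributeFuzzifier.from_boundaries(disc[attr].boundaries)
                for attr in disc.attributes
            }
        )

    def __getitem__(self, attr: str) -> AttributeFuzzifier:
        return self.per_attribute[attr]

    def __contains__(self, attr: str) -> bool:
        return attr in self.per_attribute

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.per_attribute)

    def lv_names(self, attribute: str | None = None) -> list[str]:
        attrs = [attribute] if attribute is not None else list(self.per_attribute)
        return [lv_name(a, j) for a in attrs for j in range(1, self[a].k + 1)]

    def supports(self, attribute: str) -> list[tuple[float, float]]:
        fz = self[attribute]
        return [fz.support(j) for j in range(1, fz.k + 1)]

    def to_json(self, path=None) -> str:
        payload = {
            a: {
                "min": fz.attr_min,
                "max": fz.attr_max,
                "centers": list(fz.centers),
                "supports": [list(s) for s in self.supports(a)],
            }
            for a, fz in self.per_attribute.items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FuzzyScheme":
        payload = _load_json(source)
        return cls(
            {
                a: AttributeFuzzifier(
                    attr_min=d["min"], attr_max=d["max"], centers=tuple(d["centers"])
                )
                for a, d in payload.items()
            }
        )


def lv_support(j: int, scheme: FuzzyScheme, attribute: str) -> tuple[float, float]:
    """Support pair (min, max) of LV_j of ``attribute``."""
    return scheme[attribute].support(j)


def membership(x: float, j: int, scheme: FuzzyScheme, attribute: str) -> float:
    """Membership degree of raw value ``x`` in LV_j of ``attribute``."""
    return scheme[attribute].membership(x, j)


@dataclass(frozen=True)
class FuzzyTable:
    """Membership degrees of every object in every linguistic variable."""

    degrees: pd.DataFrame  # columns = LV names, values in [0, 1]
    decision: np.ndarray
    source_attributes: tuple[str, ...]

    @property
    def lv_names(self) -> list[str]:
        return list(self.degrees.columns)

    @property
    def m(self) -> int:
        return len(self.degrees)


def fuzzify_table(table: DecisionTable, disc: DiscretizationScheme | FuzzyScheme) -> FuzzyTable:
    """Compute the fuzzified table: one membership column per LV.

    Accepts either a discretization scheme (fuzzified on the fly) or an
    already-built :class:`FuzzyScheme`.
    """
    scheme = disc if isinstance(disc, FuzzyScheme) else FuzzyScheme.from_discretization(disc)
    missing = [a for a in table.attributes if a not in scheme]
    if missing:
        raise ValueError(f"scheme lacks attributes: {missing}")
    cols = {}
    for idx, attr in enumerate(table.attributes):
        fz = scheme[attr]
        raw = table.values[:, idx]
        for j in range(1, fz.k + 1):
            cols[lv_name(attr, j)] = fz.membership_column(raw, j)
    degrees = pd.DataFrame(cols, index=list(table.objects))
    return FuzzyTable(
        degrees=degrees,
        decision=np.asarray(table.decision),
        source_attributes=table.attributes,
    )
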