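"""Seeded synthetic decision tables with known ground truth.

The generator emulates the data geometry the whole pipeline assumes: the
class signal is confined to specific, narrow value ranges of a few
informative attributes (as in diagnostic panels where only certain ranges of
a lab value indicate disease), the remaining attributes are pure noise, and a
handful of *noise objects* carry values that violate every relevant range.

Each informative feature gets one predictive interval per class. A regular
object draws, for each informative feature, a value from its own class's
interval with probability ``range_purity`` and from the other class's
interval otherwise — so the probability that an in-range value carries the
majority class is exactly the purity (at balance 1/2), and the region outside
all relevant intervals carries no class information at all. Noise features
are uniform on [0, 1] regardless of class. Values are snapped to a coarse
measurement grid (default step 0.05), mimicking limited assay resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatable import DecisionTable

__all__ = ["SynthSpec", "GroundTruth", "generate", "DEFAULT_INTERVALS"]

# one predictive interval per class, same for every informative feature
DEFAULT_INTERVALS = ((0.15, 0.40), (0.60, 0.85))

# minimum distance between a range-violating value and every relevant
# interval; violations are drawn from the extreme ends of the measurement
# range because fuzzy supports overhang their interval by half the adjacent
# sub-interval and can otherwise swallow mid-gap values
VIOLATION_MARGIN = 0.1


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic decision table."""

    m: int = 200
    n_informative: int = 5
    n_noise: int = 20
    relevant_ranges: tuple = DEFAULT_INTERVALS  # one interval per class
    class_balance: float = 0.5
    range_purity: float = 0.9
    noise_objects: int = 20
    noise_mechanism: str = "range_violation"  # or "label_flip"
    value_step: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.m < 10:
            raise ValueError("m must be >= 10")
        if not 0.5 < self.range_purity <= 1.0:
            if self.range_purity != 0.5:  # exactly 0.5 = explicit null setting
                raise ValueError("range_purity must lie in (0.5, 1] (or exactly 0.5 for a null)")
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("need at least one feature")
        ranges = tuple(tuple(map(float, r)) for r in self.relevant_ranges)
        if self.n_informative > 0:
            if len(ranges) != 2:
                raise ValueError("relevant_ranges must hold one interval per class (2)")
            for lo, hi in ranges:
                if not lo < hi:
                    raise ValueError(f"empty relevant interval ({lo}, {hi})")
            (a0, b0), (a1, b1) = ranges
            if max(a0, a1) < min(b0, b1):
                raise ValueError("per-class relevant intervals must be disjoint")
        if not 0 <= self.noise_objects < self.m:
            raise ValueError("noise_objects must be in [0, m)")
        if self.noise_mechanism not in ("range_violation", "label_flip"):
            raise ValueError("noise_mechanism must be 'range_violation' or 'label_flip'")
        object.__setattr__(self, "relevant_ranges", ranges)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator hid in the table."""

    informative_features: tuple[str, ...]
    noise_features: tuple[str, ...]
    relevant_intervals: dict  # feature -> {class label: (lo, hi)}
    noise_object_ids: tuple[int, ...]
    labels_before_noise: np.ndarray


CLASSES = ("pos", "neg")


def _grid(step: float) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.round(np.arange(0, n + 1) * step, 10)


def _grid_in(grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    pts = grid[(grid >= lo) & (grid <= hi)]
    if pts.size == 0:
        raise ValueError(f"no grid points inside ({lo}, {hi}); lower value_step")
    return pts


def generate(spec: SynthSpec):
    """Draw one decision table; fully deterministic given ``spec.seed``.

    Returns ``(table, truth)`` where ``truth`` is a :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    grid = _grid(spec.value_step)
    m = spec.m
    n_pos = int(round(m * spec.class_balance))
    labels = np.array([CLASSES[0]] * n_pos + [CLASSES[1]] * (m - n_pos), dtype=object)
    rng.shuffle(labels)

    inf_names = tuple(f"F{i + 1}" for i in range(spec.n_informative))
    noise_names = tuple(f"N{i + 1}" for i in range(spec.n_noise))
    columns = {}
    intervals = {}
    class_interval = dict(zip(CLASSES, spec.relevant_ranges))

    for name in inf_names:
        intervals[name] = dict(class_interval)
        own = rng.random(m) < spec.range_purity
        col = np.empty(m)
        for cls in CLASSES:
            own_pts = _grid_in(grid, *class_interval[cls])
            other = class_interval[CLASSES[1] if cls == CLASSES[0] else CLASSES[0]]
            other_pts = _grid_in(grid, *other)
            idx = labels == cls
            draw_own = rng.choice(own_pts, size=int(idx.sum()))
            draw_other = rng.choice(other_pts, size=int(idx.sum()))
            col[idx] = np.where(own[idx], draw_own, draw_other)
        columns[name] = col

    for name in noise_names:
        columns[name] = rng.choice(grid, size=m)

    labels_before = labels.copy()
    noise_ids: tuple[int, ...] = ()
    if spec.noise_objects > 0:
        noise_idx = np.sort(rng.choice(m, size=spec.noise_objects, replace=False))
        noise_ids = tuple(int(i) for i in noise_idx)
        if spec.noise_mechanism == "label_flip":
            flip = {CLASSES[0]: CLASSES[1], CLASSES[1]: CLASSES[0]}
            labels[noise_idx] = [flip[l] for l in labels[noise_idx]]
        else:
            # resample every informative value to the extreme ends of the range,
            # well outside all relevant intervals
            out_pts = np.array(
                [
                    p
                    for p in (grid[0], grid[-1])
                    if all(
                        p < lo - VIOLATION_MARGIN or p > hi + VIOLATION_MARGIN
                        for lo, hi in spec.relevant_ranges
                    )
                ]
            )
            if out_pts.size == 0:
                raise ValueError("relevant intervals leave no room for range violations")
            for name in inf_names:
                columns[name][noise_idx] = rng.choice(out_pts, size=noise_idx.size)

    names = inf_names + noise_names
    values = np.column_stack([columns[n] for n in names]) if names else np.empty((m, 0))
    table = DecisionTable(values=values, attributes=names, decision=labels)
    truth = GroundTruth(
        informative_features=inf_names,
        noise_features=noise_names,
        relevant_intervals=intervals,
        noise_object_ids=noise_ids,
        labels_before_noise=labels_before,
    )
    return table, truth
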