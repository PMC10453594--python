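"""Published worked-example fixtures.

The discretization boundary column of the sonar attribute V9 (22 boundary
values delimiting 21 sub-intervals) and the relevance verdicts quoted for it
serve as the canonical desk-checkable fixture: the linguistic-variable
supports, memberships and binary-table entries for V9 are all derivable from
these numbers alone.
"""

from __future__ import annotations

from .fuzzify import AttributeFuzzifier, FuzzyScheme
from .relevance import RelevanceVerdicts

__all__ = [
    "SONAR_V9_BOUNDARIES",
    "SONAR_V9_SUPPORTS",
    "sonar_v9_scheme",
    "sonar_v9_verdicts",
    "SONAR_V9_OBJECT4_VALUE",
    "SONAR_V9_OBJECT5_VALUE",
]

# Discretization boundaries of V9: range min, 20 interior cuts, range max.
SONAR_V9_BOUNDARIES = (
    0.0075,
    0.0488,
    0.0617,
    0.07535,
    0.0827,
    0.10195,
    0.1164,
    0.124,
    0.13175,
    0.1378,
    0.1494,
    0.1588,
    0.1627,
    0.1778,
    0.1795,
    0.2021,
    0.2315,
    0.2689,
    0.2899,
    0.30915,
    0.35795,
    0.6828,
)

# Published (min, max) support of each of the 21 linguistic variables of V9.
SONAR_V9_SUPPORTS = {
    "V9.LV1": (0.0075, 0.05525),
    "V9.LV2": (0.02815, 0.068525),
    "V9.LV3": (0.05525, 0.079025),
    "V9.LV4": (0.068525, 0.092325),
    "V9.LV5": (0.079025, 0.109175),
    "V9.LV6": (0.092325, 0.1202),
    "V9.LV7": (0.109175, 0.127875),
    "V9.LV8": (0.1202, 0.134775),
    "V9.LV9": (0.127875, 0.1436),
    "V9.LV10": (0.134775, 0.1541),
    "V9.LV11": (0.1436, 0.16075),
    "V9.LV12": (0.1541, 0.17025),
    "V9.LV13": (0.16075, 0.17865),
    "V9.LV14": (0.17025, 0.1908),
    "V9.LV15": (0.17865, 0.2168),
    "V9.LV16": (0.1908, 0.2502),
    "V9.LV17": (0.2168, 0.2794),
    "V9.LV18": (0.2502, 0.299525),
    "V9.LV19": (0.2794, 0.33355),
    "V9.LV20": (0.299525, 0.520375),
    "V9.LV21": (0.33355, 0.6828),
}

# Raw V9 values of the two worked-example objects.
SONAR_V9_OBJECT4_VALUE = 0.0598  # inside the confirmed LV3 support -> 1
SONAR_V9_OBJECT5_VALUE = 0.3564  # covered only by rejected LV20/LV21 -> 0


def sonar_v9_scheme() -> FuzzyScheme:
    """Fuzzy scheme for the single attribute V9, built from its boundaries."""
    return FuzzyScheme({"V9": AttributeFuzzifier.from_boundaries(SONAR_V9_BOUNDARIES)})


def sonar_v9_verdicts() -> RelevanceVerdicts:
    """The quoted verdict map: LV3 confirmed, every other LV rejected.

    Only LV3's confirmation and LV20/LV21's rejection are quoted outcomes;
    marking the remaining LVs rejected is the conservative completion needed
    to form a total verdict map for binarization.
    """
    verdicts = {name: "rejected" for name in SONAR_V9_SUPPORTS}
    verdicts["V9.LV3"] = "confirmed"
    return RelevanceVerdicts.from_map(verdicts)
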