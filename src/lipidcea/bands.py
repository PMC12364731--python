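"""Age banding shared by rate, mortality and cost tables."""

from __future__ import annotations

import bisect

# (lower inclusive, upper exclusive); the last band absorbs all older ages.
AGE_BAND_EDGES: tuple[tuple[int, int], ...] = (
    (50, 55),
    (55, 60),
    (60, 65),
    (65, 70),
    (70, 75),
    (75, 80),
    (80, 85),
    (85, 90),
    (90, 101),
)

AGE_BAND_LABELS: tuple[str, ...] = (
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85-90",
    "90+",
)

_LOWERS = [lo for lo, _ in AGE_BAND_EDGES]

N_BANDS = len(AGE_BAND_LABELS)


def band_index(age: float) -> int:
    """Index of the band containing ``age``; ages outside clamp to the ends."""
    if age < _LOWERS[0]:
        return 0
    i = bisect.bisect_right(_LOWERS, age) - 1
    return min(i, N_BANDS - 1)


def band_label(age: float) -> str:
    return AGE_BAND_LABELS[band_index(age)]
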