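"""Nocturnal sampling schedules.

Time is measured in minutes since nominal sunset at 18:00, so a full
sampling night spans the half-open interval [0, 720).  A schedule is the
union of disjoint half-open windows within that night during which nets
are notionally open.
"""

from __future__ import annotations

from dataclasses import dataclass

NIGHT_MINUTES = 720
DEFAULT_CHECK_INTERVAL = 30


@dataclass(frozen=True)
class Schedule:
    """A named union of half-open minute windows [a, b) within the night.

    Windows must be sorted, pairwise disjoint and cover a positive number
    of minutes.  Membership tests are half-open: a capture logged exactly
    at minute 360 (midnight) belongs to the second half of the night.
    """

    name: str
    windows: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("schedule needs at least one window")
        prev_end = 0
        for a, b in self.windows:
            if not (0 <= a < b <= NIGHT_MINUTES):
                raise ValueError(f"window [{a}, {b}) outside [0, {NIGHT_MINUTES}]")
            if a < prev_end:
                raise ValueError("windows must be sorted and non-overlapping")
            prev_end = b
        if self.total_minutes() == 0:
            raise ValueError("schedule covers zero minutes")

    def contains(self, time_min: float) -> bool:
        return any(a <= time_min < b for a, b in self.windows)

    def total_minutes(self) -> int:
        return sum(b - a for a, b in self.windows)

    def is_subset_of(self, other: "Schedule") -> bool:
        return all(
            any(oa <= a and b <= ob for oa, ob in other.windows)
            for a, b in self.windows
        )


#: The three canonical strategies: the full night, the first six hours,
#: and the split schedule covering the first three and last three hours.
FULL_NIGHT = Schedule("12h", ((0, 720),))
FIRST_SIX_HOURS = Schedule("6h", ((0, 360),))
SPLIT_SIX_HOURS = Schedule("6hB", ((0, 180), (540, 720)))

CANONICAL_SCHEDULES = {
    s.name: s for s in (FULL_NIGHT, FIRST_SIX_HOURS, SPLIT_SIX_HOURS)
}


def get_schedule(name: str) -> Schedule:
    try:
        return CANONICAL_SCHEDULES[name]
    except KeyError:
        raise KeyError(
            f"unknown schedule {name!r}; canonical names: "
            f"{sorted(CANONICAL_SCHEDULES)}"
        ) from None
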