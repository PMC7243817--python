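"""Standardized banding-season windows.

A season window is anchored on month-day bounds so that the number of
banding occasions ``k`` is identical in every calendar year (neither
window spans February, so leap years cannot change the day count).
Occasions are 1-based: occasion 1 is the window's start date.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

__all__ = ["SeasonWindow", "SPRING", "FALL", "season_of"]

# any non-leap year works for month-day arithmetic; windows avoid February
_REF_YEAR = 2001


@dataclass(frozen=True)
class SeasonWindow:
    """A fixed month-day window defining one banding season.

    Parameters
    ----------
    label : str
        Season name, ``"spring"`` or ``"fall"``.
    start : tuple[int, int]
        (month, day) of the first banding occasion.
    end : tuple[int, int]
        (month, day) of the last banding occasion (inclusive).
    """

    label: str
    start: tuple[int, int]
    end: tuple[int, int]

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"window {self.label!r} has non-positive length")

    @property
    def k(self) -> int:
        """Number of occasions: inclusive day count between the bounds."""
        d0 = dt.date(_REF_YEAR, *self.start)
        d1 = dt.date(_REF_YEAR, *self.end)
        return (d1 - d0).days + 1

    def start_date(self, year: int) -> dt.date:
        return dt.date(year, *self.start)

    def end_date(self, year: int) -> dt.date:
        return dt.date(year, *self.end)

    def contains(self, date: dt.date) -> bool:
        return self.start_date(date.year) <= date <= self.end_date(date.year)

    def occasion(self, date: dt.date) -> int:
        """1-based occasion index of ``date`` within its year's window."""
        if not self.contains(date):
            raise ValueError(f"{date} outside {self.label} window")
        return (date - self.start_date(date.year)).days + 1

    def date_of_occasion(self, year: int, occasion: int) -> dt.date:
        """Inverse of :meth:`occasion` for a given calendar year."""
        if not 1 <= occasion <= self.k:
            raise ValueError(f"occasion {occasion} outside 1..{self.k}")
        return self.start_date(year) + dt.timedelta(days=occasion - 1)


#: Spring banding season, 15 April to 15 June (62 occasions).
SPRING = SeasonWindow("spring", (4, 15), (6, 15))

#: Fall banding season, 15 August to 15 November (93 occasions).
FALL = SeasonWindow("fall", (8, 15), (11, 15))


def season_of(date: dt.date, windows: tuple[SeasonWindow, ...] = (SPRING, FALL)):
    """Return the window containing ``date``, or None if outside all."""
    for w in windows:
        if w.contains(date):
            return w
    return None
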