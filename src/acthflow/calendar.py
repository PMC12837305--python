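"""The 18-slot sampling calendar (June 2019 - May 2020) and its two-season split.

Blood was drawn twice monthly June through November (1st/2nd half of the
month) and once monthly December through May, giving 18 sampling events.
Events from the second half of August through the end of October form the
high-ACTH season ``mid_aug_late_oct``; the other 13 events form
``early_nov_early_aug``.
"""

from __future__ import annotations

import calendar as _stdcal
import datetime as _dt
from dataclasses import dataclass

PERIOD_MID = "mid_aug_late_oct"
PERIOD_EARLY = "early_nov_early_aug"

FIRST_HALF = "first_half"
SECOND_HALF = "second_half"
WHOLE_MONTH = "whole_month"


class CalendarError(ValueError):
    """Raised for event labels outside the 18-slot study calendar."""


@dataclass(frozen=True)
class SamplingEvent:
    label: str          # canonical ASCII form, e.g. "September_16-30"
    ordinal: int        # 1..18 in study order (June 2019 -> May 2020)
    month: int          # 1..12
    year: int           # 2019 or 2020
    batch: str          # first_half | second_half | whole_month
    period: str         # mid_aug_late_oct | early_nov_early_aug

    @property
    def month_name(self) -> str:
        return _stdcal.month_name[self.month]

    @property
    def day_bounds(self) -> tuple[int, int]:
        last = _stdcal.monthrange(self.year, self.month)[1]
        if self.batch == FIRST_HALF:
            return 1, 15
        if self.batch == SECOND_HALF:
            return 16, last
        return 1, last

    def contains(self, date: _dt.date) -> bool:
        lo, hi = self.day_bounds
        return (date.year, date.month) == (self.year, self.month) and lo <= date.day <= hi


def canonical_label(label: str) -> str:
    """Canonicalize an event label to ASCII ("September_16-30").

    The print form uses en-dashes and trailing underscores
    ("September_16–30_"); both are accepted.
    """
    s = str(label).strip().strip("_")
    for dash in ("–", "—", "−"):
        s = s.replace(dash, "-")
    s = s.replace(" ", "_")
    return s


_TWICE_MONTHLY = [(6, 2019), (7, 2019), (8, 2019), (9, 2019), (10, 2019), (11, 2019)]
_ONCE_MONTHLY = [(12, 2019), (1, 2020), (2, 2020), (3, 2020), (4, 2020), (5, 2020)]
_MID_ORDINALS = frozenset({6, 7, 8, 9, 10})  # Aug_16-31 .. Oct_16-31


def build_calendar() -> list[SamplingEvent]:
    """Return the 18 sampling events in study order."""
    events: list[SamplingEvent] = []
    ordinal = 0
    for month, year in _TWICE_MONTHLY:
        last = _stdcal.monthrange(year, month)[1]
        name = _stdcal.month_name[month]
        for batch, days in ((FIRST_HALF, "1-15"), (SECOND_HALF, f"16-{last}")):
            ordinal += 1
            events.append(SamplingEvent(
                label=f"{name}_{days}", ordinal=ordinal, month=month, year=year,
                batch=batch, period=PERIOD_MID if ordinal in _MID_ORDINALS else PERIOD_EARLY,
            ))
    for month, year in _ONCE_MONTHLY:
        last = _stdcal.monthrange(year, month)[1]
        name = _stdcal.month_name[month]
        ordinal += 1
        events.append(SamplingEvent(
            label=f"{name}_1-{last}", ordinal=ordinal, month=month, year=year,
            batch=WHOLE_MONTH, period=PERIOD_EARLY,
        ))
    return events


CALENDAR: list[SamplingEvent] = build_calendar()
EVENTS_BY_LABEL: dict[str, SamplingEvent] = {e.label: e for e in CALENDAR}
EVENT_LABELS: list[str] = [e.label for e in CALENDAR]


def get_event(label: str) -> SamplingEvent:
    key = canonical_label(label)
    try:
        return EVENTS_BY_LABEL[key]
    except KeyError:
        raise CalendarError(f"unknown sampling event label: {label!r}") from None


def assign_period(event: str | SamplingEvent) -> str:
    """Map a sampling event (or its label) to its seasonal period."""
    if isinstance(event, SamplingEvent):
        return event.period
    return get_event(event).period


def events_in_period(period: str) -> list[SamplingEvent]:
    if period not in (PERIOD_MID, PERIOD_EARLY):
        raise CalendarError(f"unknown period: {period!r}")
    return [e for e in CALENDAR if e.period == period]


def month_key(event: str | SamplingEvent) -> str:
    """Calendar-month name of an event; the month is the exclusion unit."""
    if not isinstance(event, SamplingEvent):
        event = get_event(event)
    return event.month_name
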