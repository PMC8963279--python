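"""Five-field cron schedule evaluation at minute granularity.

Dialect: the classic ``minute hour day-of-month month day-of-week`` form.
Each field accepts ``*``, a number, ``a-b`` ranges, ``*/n`` or ``a-b/n``
steps, and comma lists.  Day-of-week runs 0-7 with both 0 and 7 meaning
Sunday.  When both day-of-month and day-of-week are restricted, a date
matches if *either* does (standard cron semantics).

All evaluation is pure: :func:`fires_between` never reads the clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

from .errors import ScheduleError

_FIELD_RANGES = [
    ("minute", 0, 59),
    ("hour", 0, 23),
    ("day-of-month", 1, 31),
    ("month", 1, 12),
    ("day-of-week", 0, 7),
]


def _parse_field(text: str, name: str, lo: int, hi: int) -> tuple[frozenset[int], bool]:
    """Parse one cron field; returns (allowed values, was ``*``)."""
    values: set[int] = set()
    is_star = False
    for item in text.split(","):
        if not item:
            raise ScheduleError(f"empty item in cron field {name!r}")
        step = 1
        if "/" in item:
            item, step_text = item.split("/", 1)
            try:
                step = int(step_text)
            except ValueError:
                raise ScheduleError(f"bad step {step_text!r} in cron field {name!r}") from None
            if step < 1:
                raise ScheduleError(f"step must be >= 1 in cron field {name!r}")
        if item == "*":
            if step == 1 and text == "*":
                is_star = True
            values.update(range(lo, hi + 1, step))
            continue
        if "-" in item:
            a_text, b_text = item.split("-", 1)
            try:
                a, b = int(a_text), int(b_text)
            except ValueError:
                raise ScheduleError(f"bad range {item!r} in cron field {name!r}") from None
        else:
            try:
                a = b = int(item)
            except ValueError:
                raise ScheduleError(f"bad value {item!r} in cron field {name!r}") from None
        if not (lo <= a <= hi and lo <= b <= hi and a <= b):
            raise ScheduleError(
                f"value out of range [{lo},{hi}] in cron field {name!r}: {item!r}"
            )
        values.update(range(a, b + 1, step))
    return frozenset(values), is_star


@dataclass(frozen=True)
class CronSchedule:
    """A parsed five-field cron expression."""

    expression: str
    minutes: frozenset[int]
    hours: frozenset[int]
    days_of_month: frozenset[int]
    months: frozenset[int]
    days_of_week: frozenset[int]  # normalized to 0-6, Sunday=0
    dom_star: bool
    dow_star: bool

    def matches_date(self, dt: datetime) -> bool:
        if dt.month not in self.months:
            return False
        dom_ok = dt.day in self.days_of_month
        # datetime.weekday(): Monday=0; cron: Sunday=0
        dow_ok = (dt.weekday() + 1) % 7 in self.days_of_week
        if self.dom_star and self.dow_star:
            return True
        if self.dom_star:
            return dow_ok
        if self.dow_star:
            return dom_ok
        return dom_ok or dow_ok

    def matches(self, dt: datetime) -> bool:
        """True when the schedule fires at the minute containing ``dt``."""
        return (
            dt.minute in self.minutes
            and dt.hour in self.hours
            and self.matches_date(dt)
        )


def parse_cron(expression: str) -> CronSchedule:
    """Parse a five-field cron expression, raising :class:`ScheduleError` if malformed."""
    fields = expression.split()
    if len(fields) != 5:
        raise ScheduleError(
            f"cron expression must have 5 fields, got {len(fields)}: {expression!r}"
        )
    parsed = [
        _parse_field(text, name, lo, hi)
        for text, (name, lo, hi) in zip(fields, _FIELD_RANGES)
    ]
    dow_values = {v % 7 for v in parsed[4][0]}
    return CronSchedule(
        expression=expression,
        minutes=parsed[0][0],
        hours=parsed[1][0],
        days_of_month=parsed[2][0],
        months=parsed[3][0],
        days_of_week=frozenset(dow_values),
        dom_star=parsed[2][1],
        dow_star=parsed[4][1],
    )


def fires_between(schedule: CronSchedule, after: datetime, until: datetime) -> bool:
    """True iff at least one firing time lies in the half-open window ``(after, until]``.

    Walks candidate days and, on matching dates, the allowed hour/minute grid;
    cost is proportional to the window length in days, not minutes.
    """
    if until <= after:
        return False
    hours = sorted(schedule.hours)
    minutes = sorted(schedule.minutes)
    day = datetime(after.year, after.month, after.day)
    end_day = datetime(until.year, until.month, until.day)
    while day <= end_day:
        if schedule.matches_date(day):
            for hour in hours:
                for minute in minutes:
                    candidate = day.replace(hour=hour, minute=minute)
                    if after < candidate <= until:
                        return True
                    if candidate > until:
                        break
        day += timedelta(days=1)
    return False
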