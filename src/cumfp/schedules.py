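"""Age-indexed annual transition-probability schedules.

A schedule maps consecutive integer ages to an annual probability: either
``q(a)``, the probability of dying during the year of age ``a`` (an
all-cause life-table column), or ``i(a)``, the probability that a
neoplasia-free person develops colorectal neoplasia during that year.
Both are plain per-person-year probabilities in [0, 1].

Schedules are read from and written to two-column ``age,probability`` CSV
files, so national life tables or cohort-study incidence estimates can be
dropped in directly.  A Gompertz generator provides a realistic synthetic
stand-in for an adult life table when no external file is supplied.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Union

import numpy as np

__all__ = [
    "Schedule",
    "MortalitySchedule",
    "IncidenceSchedule",
    "make_gompertz_mortality",
    "read_schedule_csv",
    "write_schedule_csv",
]


class ScheduleError(ValueError):
    """Raised for malformed schedule data (bad ages, bad probabilities)."""


@dataclass(frozen=True)
class Schedule:
    """Annual probabilities indexed by consecutive integer ages.

    Parameters
    ----------
    start_age:
        First age covered.
    probs:
        Probability for each age ``start_age, start_age+1, ...`` in order.
    """

    start_age: int
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise ScheduleError("schedule needs a one-dimensional, non-empty probability array")
        if not np.all(np.isfinite(probs)):
            raise ScheduleError("schedule probabilities must be finite")
        if np.any(probs < 0.0) or np.any(probs > 1.0):
            bad = int(np.flatnonzero((probs < 0) | (probs > 1))[0])
            raise ScheduleError(
                f"probability {probs[bad]!r} at age {self.start_age + bad} outside [0, 1]"
            )
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "start_age", int(self.start_age))

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "Schedule":
        """Build from an ``{age: probability}`` mapping with consecutive ages."""
        ages = sorted(int(a) for a in mapping)
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ScheduleError("non-consecutive ages in schedule mapping")
        return cls(ages[0], np.array([mapping[a] for a in ages], dtype=float))

    @property
    def stop_age(self) -> int:
        """Last age covered (inclusive)."""
        return self.start_age + len(self.probs) - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.stop_age + 1)

    def at(self, age: int) -> float:
        """Annual probability at integer ``age``."""
        if not self.covers(age, age):
            raise ScheduleError(
                f"age {age} outside schedule range [{self.start_age}, {self.stop_age}]"
            )
        return float(self.probs[int(age) - self.start_age])

    def covers(self, lo: int, hi: int) -> bool:
        """Whether every integer age in ``[lo, hi]`` is defined."""
        return self.start_age <= lo and hi <= self.stop_age

    def items(self) -> Iterator[tuple[int, float]]:
        for a, p in zip(self.ages, self.probs):
            yield int(a), float(p)


class MortalitySchedule(Schedule):
    """Annual all-cause death probabilities q(a)."""


class IncidenceSchedule(Schedule):
    """Annual colorectal-neoplasia onset probabilities i(a) among the neoplasia-free."""


def make_gompertz_mortality(
    a_coeff: float, b_coeff: float, ages: range
) -> MortalitySchedule:
    """Synthetic adult life-table column q(a) = min(1, a·exp(b·age)).

    The Gompertz law of mortality is the standard parametric description of
    adult all-cause death rates; with ``a_coeff ~ 1e-5`` and
    ``b_coeff ~ 0.1 / year`` it matches Western European life tables at ages
    50-75 to well within the accuracy this model needs.

    Parameters
    ----------
    a_coeff:
        Baseline hazard scale (> 0).
    b_coeff:
        Exponential ageing rate per year (>= 0).
    ages:
        Integer ages to cover, e.g. ``range(50, 76)``.
    """
    if not a_coeff > 0:
        raise ScheduleError("Gompertz a_coeff must be positive")
    if b_coeff < 0:
        raise ScheduleError("Gompertz b_coeff must be non-negative")
    age_arr = np.array(list(ages), dtype=float)
    if age_arr.size == 0:
        raise ScheduleError("empty age range")
    q = np.minimum(1.0, a_coeff * np.exp(b_coeff * age_arr))
    return MortalitySchedule(int(age_arr[0]), q)


def read_schedule_csv(
    path: Union[str, Path], kind: type[Schedule] = Schedule
) -> Schedule:
    """Read an ``age,probability`` CSV into a schedule.

    The header row is required; ages must be integers in consecutive
    ascending order and probabilities must lie in [0, 1].  Errors name the
    offending line.
    """
    path = Path(path)
    ages: list[int] = []
    probs: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ScheduleError(f"{path}: empty file") from None
        if [h.strip().lower() for h in header[:2]] != ["age", "probability"]:
            raise ScheduleError(f"{path}: line 1: expected header 'age,probability'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ScheduleError(f"{path}: line {lineno}: expected two columns")
            try:
                age = int(row[0])
            except ValueError:
                raise ScheduleError(
                    f"{path}: line {lineno}: non-integer age {row[0]!r}"
                ) from None
            try:
                p = float(row[1])
            except ValueError:
                raise ScheduleError(
                    f"{path}: line {lineno}: non-numeric probability {row[1]!r}"
                ) from None
            if not 0.0 <= p <= 1.0:
                raise ScheduleError(
                    f"{path}: line {lineno}: probability {p} outside [0, 1]"
                )
            if ages and age != ages[-1] + 1:
                raise ScheduleError(
                    f"{path}: line {lineno}: non-consecutive ages ({ages[-1]} then {age})"
                )
            ages.append(age)
            probs.append(p)
    if not ages:
        raise ScheduleError(f"{path}: no data rows")
    return kind(ages[0], np.array(probs))


def write_schedule_csv(schedule: Schedule, path: Union[str, Path]) -> None:
    """Write a schedule as ``age,probability`` CSV (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["age", "probability"])
        for age, p in schedule.items():
            writer.writerow([age, repr(p)])
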