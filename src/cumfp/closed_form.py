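"""Closed-form cumulative false-positive rate.

Under the cohort model a person can only receive a *first* false-positive
result at screening round ``r`` if they are alive and neoplasia-free at the
round age ``a_r`` (probability ``F(a_r)``, the survivorship curve) and have
tested negative at every earlier round they were free for.  Because anyone
free at round ``r`` was necessarily free at all earlier rounds, their test
history is a sequence of independent Bernoulli trials with the per-round FP
probabilities ``p_1 .. p_{r-1}``, giving the first-FP round weights

    w_r = p_r · prod_{j<r} (1 − p_j)

and the cumulative count per 100 000 alive at 50

    cumFP(a) = 100000 · sum_{r : a_r <= a} F(a_r) · w_r.

This is exact — not an approximation — under the engine's convention that
screening happens at the exact integer age before that year's neoplasia
onset and death, so it serves as the engine's independent test oracle and
as a fast kernel for calibration and for inverting published cumFP columns
back into survivorship.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenarios import ScreeningScenario
from .schedules import IncidenceSchedule, MortalitySchedule
from .survivorship import SurvivorshipCurve

__all__ = [
    "CumFPSeries",
    "first_fp_round_weights",
    "cumfp_closed_form",
    "survivorship_from_schedules",
    "invert_column_to_survivorship",
]

PER = 100_000.0


@dataclass(frozen=True)
class CumFPSeries:
    """Cumulative first-FP count per 100 000 of a stated reference population.

    ``values[k]`` is the cumFP by age ``start_age + k`` (inclusive of any
    round at that age), per 100 000 persons under ``denominator`` — either
    everyone alive at 50 (``"all50"``) or only those neoplasia-free at 50
    (``"free50"``).
    """

    start_age: int
    values: np.ndarray = field(repr=False)
    denominator: str = "all50"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("series needs a non-empty value array")
        if np.any(np.diff(vals) < -1e-6):
            raise ValueError("cumFP must be non-decreasing in age")
        if np.any(vals < -1e-6) or np.any(vals > PER + 1e-6):
            raise ValueError("cumFP per 100 000 must lie in [0, 100000]")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "start_age", int(self.start_age))

    @property
    def stop_age(self) -> int:
        return self.start_age + len(self.values) - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.stop_age + 1)

    def at(self, age: int) -> float:
        idx = int(age) - self.start_age
        if not 0 <= idx < len(self.values):
            raise ValueError(f"age {age} outside series range")
        return float(self.values[idx])


def first_fp_round_weights(fp_probs: np.ndarray) -> np.ndarray:
    """w_r = p_r · prod_{j<r}(1 − p_j): probability that a person who is free
    at every round has their first false positive exactly at round r."""
    p = np.asarray(fp_probs, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("FP probabilities must lie in [0, 1]")
    no_fp_before = np.concatenate(([1.0], np.cumprod(1.0 - p)[:-1]))
    return p * no_fp_before


def cumfp_closed_form(
    curve: SurvivorshipCurve,
    scenario: ScreeningScenario,
    start_age: int | None = None,
) -> CumFPSeries:
    """cumFP(a) per 100 000 alive at 50, for every integer age.

    The series starts at ``start_age`` (default: the earlier of the curve
    start and the scenario start) and runs to the scenario stop age; it is a
    step function increasing only at screening ages.
    """
    ages = scenario.screening_ages
    if ages and not curve.covers(ages[0], ages[-1]):
        raise ValueError("survivorship curve does not cover all screening ages")
    w = first_fp_round_weights(scenario.fp_probabilities())
    lo = curve.start_age if start_age is None else int(start_age)
    hi = scenario.stop_age
    out = np.zeros(hi - lo + 1)
    acc = 0.0
    round_iter = iter(zip(ages, w))
    nxt = next(round_iter, None)
    for k, a in enumerate(range(lo, hi + 1)):
        while nxt is not None and nxt[0] <= a:
            acc += curve.at(nxt[0]) * nxt[1]
            nxt = next(round_iter, None)
        out[k] = PER * acc
    return CumFPSeries(lo, out)


def survivorship_from_schedules(
    mortality: MortalitySchedule,
    incidence: IncidenceSchedule,
    prevalence_at_start: float,
    start_age: int = 50,
    stop_age: int = 74,
) -> SurvivorshipCurve:
    """F implied by annual exit probabilities: F(a+1) = F(a)(1−i(a))(1−q(a)).

    ``prevalence_at_start`` is the neoplasia prevalence at ``start_age``,
    so F(start_age) = 1 − prevalence.
    """
    if not 0.0 <= prevalence_at_start < 1.0:
        raise ValueError("prevalence_at_start must lie in [0, 1)")
    if not (mortality.covers(start_age, stop_age - 1) and incidence.covers(start_age, stop_age - 1)):
        raise ValueError("schedules must cover every age in [start_age, stop_age - 1]")
    vals = np.empty(stop_age - start_age + 1)
    vals[0] = 1.0 - prevalence_at_start
    for k, a in enumerate(range(start_age, stop_age)):
        vals[k + 1] = vals[k] * (1.0 - incidence.at(a)) * (1.0 - mortality.at(a))
    return SurvivorshipCurve(start_age, vals)


def invert_column_to_survivorship(
    series: CumFPSeries, scenario: ScreeningScenario
) -> dict[int, float]:
    """Recover F at each screening age from a cumFP column.

    Each round contributes ``100000·F(a_r)·w_r`` to the column, so the
    increments of the series across rounds identify F at exactly the
    screening ages:  F(a_r) = [cumFP(a_r) − cumFP(a_{r−1})] / (100000·w_r).
    No interpolation to other ages is attempted.
    """
    ages = scenario.screening_ages
    w = first_fp_round_weights(scenario.fp_probabilities())
    out: dict[int, float] = {}
    prev = 0.0
    for a, wr in zip(ages, w):
        cur = series.at(a)
        if cur < prev - 1e-9:
            raise ValueError(f"cumFP series decreases at age {a}")
        if wr <= 0.0:
            raise ValueError(f"zero first-FP weight at round age {a}; F not identifiable")
        out[a] = (cur - prev) / (PER * wr)
        prev = cur
    return out
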