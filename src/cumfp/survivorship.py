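"""Neoplasia-free survivorship of the screening cohort.

``F(a)`` is the fraction of the cohort alive at age 50 that is still alive
and free of colorectal neoplasia (cancer or adenoma) at age ``a``.  Only
people in this pool can generate a false-positive screening result, and the
cumulative false-positive count is a survivorship-weighted sum over rounds,
so F is the sufficient statistic of the cohort for everything this package
computes: the split of the attrition between neoplasia onset and death does
not affect any output.

The default parametric form is linear between age 50 and 74.  Its two
parameters are ``f50`` — the neoplasia-free fraction at age 50 — and
``ratio_74 = F(74)/F(50)``, the fraction of the initially-free who remain
free (and alive) at 74.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .schedules import IncidenceSchedule, MortalitySchedule

__all__ = [
    "SurvivorshipCurve",
    "linear_survivorship",
    "derive_incidence_from_survivorship",
]


@dataclass(frozen=True)
class SurvivorshipCurve:
    """Fraction of the age-50 cohort alive and neoplasia-free by integer age.

    ``values[k]`` is F(start_age + k).  F must be positive at the start,
    non-increasing, and non-negative.
    """

    start_age: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("survivorship curve needs a non-empty value array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("survivorship values must be finite")
        if vals[0] <= 0.0 or vals[0] > 1.0:
            raise ValueError("F at the start age must lie in (0, 1]")
        if np.any(vals < -1e-12):
            raise ValueError("survivorship values must be non-negative")
        if np.any(np.diff(vals) > 1e-12):
            raise ValueError("survivorship must be non-increasing in age")
        object.__setattr__(self, "values", np.clip(vals, 0.0, None))
        object.__setattr__(self, "start_age", int(self.start_age))

    @property
    def stop_age(self) -> int:
        return self.start_age + len(self.values) - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.stop_age + 1)

    @property
    def f50(self) -> float:
        """F at the curve's start age (the neoplasia-free fraction at entry)."""
        return float(self.values[0])

    def at(self, age: int) -> float:
        if not self.covers(age, age):
            raise ValueError(
                f"age {age} outside curve range [{self.start_age}, {self.stop_age}]"
            )
        return float(self.values[int(age) - self.start_age])

    def covers(self, lo: int, hi: int) -> bool:
        return self.start_age <= lo and hi <= self.stop_age

    def rescaled(self, scale: float) -> "SurvivorshipCurve":
        """Same shape, F multiplied by ``scale`` everywhere."""
        if not 0.0 < scale * self.f50 <= 1.0:
            raise ValueError("rescaled F(start) must lie in (0, 1]")
        return SurvivorshipCurve(self.start_age, self.values * scale)


def linear_survivorship(
    f50: float,
    ratio_74: float,
    start_age: int = 50,
    stop_age: int = 74,
) -> SurvivorshipCurve:
    """Straight-line survivorship F(a) = f50·(1 − (1 − ratio_74)·(a−50)/24).

    Parameters
    ----------
    f50:
        Fraction of 50-year-olds who are neoplasia-free, in (0, 1].
    ratio_74:
        F(stop_age)/F(start_age), in (0, 1].
    """
    for name, val in (("f50", f50), ("ratio_74", ratio_74)):
        if not (math.isfinite(val) and 0.0 < val <= 1.0):
            raise ValueError(f"{name} must be a finite fraction in (0, 1], got {val!r}")
    span = stop_age - start_age
    if span < 1:
        raise ValueError("stop_age must exceed start_age")
    frac = np.arange(span + 1) / span
    return SurvivorshipCurve(start_age, f50 * (1.0 - (1.0 - ratio_74) * frac))


def derive_incidence_from_survivorship(
    curve: SurvivorshipCurve,
    mortality: MortalitySchedule,
    tolerance: float = 1e-9,
) -> IncidenceSchedule:
    """Incidence schedule that, combined with ``mortality``, reproduces F.

    The cohort engine drains the free pool by the factor
    ``(1 − i(a))·(1 − q(a))`` each year, so the incidence implied by a
    target survivorship curve is ``i(a) = 1 − [F(a+1)/F(a)] / (1 − q(a))``.
    Feeding the result back into the engine (with initial neoplasia
    prevalence ``1 − f50``) reproduces F exactly.

    Raises when mortality alone already exceeds the attrition the curve
    requires at some age, i.e. the implied incidence would be negative
    beyond ``tolerance`` — the curve and life table are then inconsistent.
    """
    ages = range(curve.start_age, curve.stop_age)  # i defined up to stop-1
    if not mortality.covers(curve.start_age, curve.stop_age - 1):
        raise ValueError("mortality schedule does not cover the curve's age range")
    probs = []
    for a in ages:
        fa, fa1 = curve.at(a), curve.at(a + 1)
        q = mortality.at(a)
        if fa == 0.0:
            probs.append(0.0)  # free pool already empty; incidence is moot
            continue
        if q >= 1.0:
            if fa1 > 0.0:
                raise ValueError(
                    f"age {a}: q = 1 kills the free pool but F({a + 1}) > 0"
                )
            probs.append(0.0)
            continue
        i = 1.0 - (fa1 / fa) / (1.0 - q)
        if i < -tolerance:
            raise ValueError(
                f"age {a}: mortality q = {q} already exceeds the attrition "
                f"required by F({a + 1})/F({a}) = {fa1 / fa:.6g}"
            )
        probs.append(min(1.0, max(0.0, i)))
    return IncidenceSchedule(curve.start_age, np.array(probs))
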