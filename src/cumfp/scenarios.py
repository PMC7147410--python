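"""Screening strategies and per-round false-positive probabilities.

A strategy is defined by the start age, stop age (74 throughout), the
interval between rounds, the per-test specificity ``s``, and an optional
conditional-dependence reduction ``delta``: from the second round onward
the false-positive probability among people with only prior true-negative
results drops by ``delta`` (an absolute, percentage-point reduction).
``delta = 0`` recovers conditional independence of sequential testing.

Under perfect adherence a neoplasia-free person who has never tested
false-positive and faces round ``r`` has exactly ``r - 1`` prior
true-negative results, so the dependence rule reduces to "round index
>= 2" and needs no per-person test history.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ScreeningScenario",
    "RoundPlan",
    "build_screening_ages",
    "per_round_fp_probabilities",
    "standard_catalogue",
    "DEPENDENCE_DELTA",
]

# Absolute per-round FP reduction used by the conditional-dependence
# sensitivity variant: 1 percentage point after any true-negative history.
DEPENDENCE_DELTA = 0.01


@dataclass(frozen=True)
class ScreeningScenario:
    """One screening strategy.

    Parameters
    ----------
    start_age, stop_age:
        First and last test-eligible ages (both endpoints on the grid).
    interval:
        Years between rounds (>= 1).
    specificity:
        Per-test probability ``s`` that a neoplasia-free person tests
        negative; the per-round FP probability is ``1 - s``.
    dependence_reduction:
        Absolute reduction of the FP probability from the second round
        onward (0 for conditional independence).
    label:
        Identifier used in output tables.
    """

    start_age: int
    stop_age: int
    interval: int
    specificity: float
    dependence_reduction: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_age > self.stop_age:
            raise ValueError("start_age must not exceed stop_age")
        if self.interval < 1:
            raise ValueError("interval must be >= 1 year")
        if not 0.0 < self.specificity <= 1.0:
            raise ValueError("specificity must lie in (0, 1]")
        if self.dependence_reduction < 0.0:
            raise ValueError("dependence_reduction must be >= 0")
        if 1.0 - self.specificity - self.dependence_reduction < 0.0:
            raise ValueError(
                "dependence reduction exceeds the per-round FP probability"
            )
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        lab = f"i{self.interval}_sp{round(self.specificity * 100)}"
        if self.start_age != 50:
            lab += f"_start{self.start_age}"
        if self.dependence_reduction:
            lab += f"_dep{round(self.dependence_reduction * 100)}"
        return lab

    @property
    def screening_ages(self) -> tuple[int, ...]:
        return build_screening_ages(self)

    @property
    def n_rounds(self) -> int:
        return len(self.screening_ages)

    def fp_probabilities(self) -> np.ndarray:
        """Per-round FP probabilities aligned with :attr:`screening_ages`."""
        return per_round_fp_probabilities(self, self.n_rounds)

    def with_dependence(self, delta: float = DEPENDENCE_DELTA) -> "ScreeningScenario":
        """Sensitivity twin with an absolute FP reduction after round 1."""
        return replace(self, dependence_reduction=delta, label="")

    def plan(self) -> "RoundPlan":
        return RoundPlan(self.screening_ages, tuple(self.fp_probabilities()))


@dataclass(frozen=True)
class RoundPlan:
    """Screening ages paired with per-round first-FP probabilities."""

    ages: tuple[int, ...]
    fp_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.fp_probs):
            raise ValueError("ages and fp_probs must have equal length")
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("screening ages must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in self.fp_probs):
            raise ValueError("FP probabilities must lie in [0, 1]")


def build_screening_ages(scenario: ScreeningScenario) -> tuple[int, ...]:
    """Test ages: start, start+interval, ... up to and including stop_age."""
    return tuple(
        range(scenario.start_age, scenario.stop_age + 1, scenario.interval)
    )


def per_round_fp_probabilities(
    scenario: ScreeningScenario, n_rounds: int
) -> np.ndarray:
    """FP probability per round: ``1 - s`` first, ``1 - s - delta`` after.

    The reduction applies to everyone facing a second or later round while
    still free and never false-positive, i.e. everyone with at least one
    prior true-negative result under perfect adherence.
    """
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    base = 1.0 - scenario.specificity
    later = base - scenario.dependence_reduction
    if later < 0.0:
        raise ValueError("dependence reduction exceeds the per-round FP probability")
    probs = np.full(n_rounds, later)
    if n_rounds:
        probs[0] = base
    return probs


def standard_catalogue(include_sensitivity: bool = False) -> list[ScreeningScenario]:
    """The eleven strategies studied: a 3x3 grid of interval {1,2,3} years by
    specificity {98, 95, 92}% starting at 50, plus biennial 98%-specificity
    strategies starting at 54 and 58.  With ``include_sensitivity`` each
    strategy is followed by its conditional-dependence twin (delta = 0.01).
    """
    base: list[ScreeningScenario] = []
    for interval in (1, 2, 3):
        for spec in (0.98, 0.95, 0.92):
            base.append(ScreeningScenario(50, 74, interval, spec))
    for start in (54, 58):
        base.append(ScreeningScenario(start, 74, 2, 0.98))
    if not include_sensitivity:
        return base
    out: list[ScreeningScenario] = []
    for sc in base:
        out.append(sc)
        out.append(sc.with_dependence())
    return out


def catalogue_by_label(
    include_sensitivity: bool = False,
) -> dict[str, ScreeningScenario]:
    return {sc.label: sc for sc in standard_catalogue(include_sensitivity)}
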