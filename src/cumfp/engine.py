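"""Annual-cycle state-transition cohort engine.

The cohort occupies five states: alive and neoplasia-free without / with a
prior false-positive result, alive with colorectal neoplasia without /
with a prior false positive, and dead.  Neoplasia onset and death are
absorbing with respect to false-positive eligibility: only the
free-without-FP state can generate a first false positive, and the
``cum_fp`` counter — the model's headline output — records everyone who
ever tested false positive, surviving their later neoplasia onset or death.

Each annual cycle at integer age ``a`` proceeds screening first (if ``a``
is a round age, among those alive, free, and in either FP state), then
neoplasia onset with probability ``i(a)`` (preserving the FP flag), then
death with probability ``q(a)`` from every alive state.  Occupancies are
real-valued proportions of a deterministic cohort, not a microsimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .closed_form import CumFPSeries
from .scenarios import ScreeningScenario
from .schedules import IncidenceSchedule, MortalitySchedule

__all__ = [
    "StateVector",
    "Trajectory",
    "initial_state",
    "apply_screening",
    "apply_transitions",
    "run_cohort",
    "cumfp_series",
]


@dataclass(frozen=True)
class StateVector:
    """Occupancy (persons) of the five states plus the first-FP counter."""

    free_no_fp: float
    free_fp: float = 0.0
    neo_no_fp: float = 0.0
    neo_fp: float = 0.0
    dead: float = 0.0
    cum_fp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("free_no_fp", "free_fp", "neo_no_fp", "neo_fp", "dead", "cum_fp"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"negative occupancy in {name}")

    @property
    def total(self) -> float:
        """Alive plus dead: conserved cohort mass."""
        return self.free_no_fp + self.free_fp + self.neo_no_fp + self.neo_fp + self.dead

    @property
    def alive_fp(self) -> float:
        return self.free_fp + self.neo_fp


@dataclass(frozen=True)
class Trajectory:
    """Per-age state vectors, recorded after any screening at that age and
    before that year's neoplasia onset and death."""

    start_age: int
    states: tuple[StateVector, ...]
    cohort_size: float
    initial_free: float

    @property
    def stop_age(self) -> int:
        return self.start_age + len(self.states) - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.stop_age + 1)

    def at(self, age: int) -> StateVector:
        idx = int(age) - self.start_age
        if not 0 <= idx < len(self.states):
            raise ValueError(f"age {age} outside trajectory range")
        return self.states[idx]

    def to_frame(self) -> pd.DataFrame:
        """Occupancies by age, one row per cycle."""
        return pd.DataFrame(
            {
                "age": self.ages,
                "free_no_fp": [s.free_no_fp for s in self.states],
                "free_fp": [s.free_fp for s in self.states],
                "neo_no_fp": [s.neo_no_fp for s in self.states],
                "neo_fp": [s.neo_fp for s in self.states],
                "dead": [s.dead for s in self.states],
                "cum_fp": [s.cum_fp for s in self.states],
            }
        )


def initial_state(cohort_size: float, prevalence_at_start: float) -> StateVector:
    """Cohort at entry: no screening history, prevalence split free/neoplasia."""
    if cohort_size < 0:
        raise ValueError("cohort_size must be non-negative")
    if not 0.0 <= prevalence_at_start <= 1.0:
        raise ValueError("prevalence_at_start must lie in [0, 1]")
    return StateVector(
        free_no_fp=cohort_size * (1.0 - prevalence_at_start),
        neo_no_fp=cohort_size * prevalence_at_start,
    )


def apply_screening(state: StateVector, fp_prob: float) -> StateVector:
    """One round: the free-without-FP pool tests false positive with
    probability ``fp_prob``; everyone else is unaffected and nobody is
    counted twice."""
    if not 0.0 <= fp_prob <= 1.0:
        raise ValueError("fp_prob must lie in [0, 1]")
    new_fp = state.free_no_fp * fp_prob
    return replace(
        state,
        free_no_fp=state.free_no_fp - new_fp,
        free_fp=state.free_fp + new_fp,
        cum_fp=state.cum_fp + new_fp,
    )


def apply_transitions(state: StateVector, i_a: float, q_a: float) -> StateVector:
    """One year of neoplasia onset then death.

    Onset moves each free state into the matching neoplasia state with
    probability ``i_a`` (the FP flag is preserved); death then removes the
    fraction ``q_a`` from every alive state.  ``cum_fp`` is untouched:
    first-FP events persist through onset and death.
    """
    for name, p in (("i_a", i_a), ("q_a", q_a)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    onset_no_fp = state.free_no_fp * i_a
    onset_fp = state.free_fp * i_a
    free_no_fp = state.free_no_fp - onset_no_fp
    free_fp = state.free_fp - onset_fp
    neo_no_fp = state.neo_no_fp + onset_no_fp
    neo_fp = state.neo_fp + onset_fp
    alive = free_no_fp + free_fp + neo_no_fp + neo_fp
    surv = 1.0 - q_a
    return replace(
        state,
        free_no_fp=free_no_fp * surv,
        free_fp=free_fp * surv,
        neo_no_fp=neo_no_fp * surv,
        neo_fp=neo_fp * surv,
        dead=state.dead + alive * q_a,
    )


def run_cohort(
    mortality: MortalitySchedule,
    incidence: IncidenceSchedule,
    scenario: ScreeningScenario,
    cohort_size: float = 100_000.0,
    prevalence_at_start: float = 0.0,
    start_age: int | None = None,
) -> Trajectory:
    """Evolve the cohort annually from ``start_age`` to the scenario stop age.

    ``start_age`` defaults to the scenario's first screening age but may be
    earlier (e.g. 50 for a strategy that starts testing at 58), in which
    case ``prevalence_at_start`` refers to that earlier entry age and the
    cohort ages untested until the first round.  Schedules must cover every
    age at which a transition occurs, i.e. ``[start_age, stop_age - 1]``.
    """
    a0 = scenario.start_age if start_age is None else int(start_age)
    if a0 > scenario.start_age:
        raise ValueError("run start_age must not be later than the first round")
    a1 = scenario.stop_age
    if a1 > a0 and not (
        mortality.covers(a0, a1 - 1) and incidence.covers(a0, a1 - 1)
    ):
        raise ValueError(
            f"schedules must cover every transition age in [{a0}, {a1 - 1}]"
        )
    round_prob = dict(zip(scenario.screening_ages, scenario.fp_probabilities()))
    state = initial_state(cohort_size, prevalence_at_start)
    recorded: list[StateVector] = []
    for a in range(a0, a1 + 1):
        if a in round_prob:
            state = apply_screening(state, round_prob[a])
        recorded.append(state)
        if a < a1:
            state = apply_transitions(state, incidence.at(a), mortality.at(a))
    return Trajectory(a0, tuple(recorded), cohort_size, recorded[0].free_no_fp + recorded[0].free_fp)


def cumfp_series(traj: Trajectory, denominator: str = "all50") -> CumFPSeries:
    """cumFP per 100 000 of the chosen reference population.

    ``"all50"`` divides by the full entry cohort; ``"free50"`` by the
    neoplasia-free part of it.
    """
    if denominator == "all50":
        d = traj.cohort_size
    elif denominator == "free50":
        d = traj.initial_free
    else:
        raise ValueError("denominator must be 'all50' or 'free50'")
    if d <= 0.0:
        raise ValueError("zero reference population")
    vals = np.array([s.cum_fp for s in traj.states]) * (100_000.0 / d)
    return CumFPSeries(traj.start_age, vals, denominator=denominator)
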