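"""Result tables, scenario comparisons, and the external-consistency check.

The headline deliverable is a table of cumulative false-positive counts
per 100 000 by age (rows 50-74) with one column per screening strategy,
in three flavours: the base case, the conditional-dependence sensitivity
variant (per-round FP probability reduced one percentage point after the
first round), and the base case re-expressed per 100 000 neoplasia-free
at 50.  All cells are produced by full cohort-engine runs from age 50;
the closed form is reserved for calibration and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd
import yaml

from .calibration import CalibrationAnchors, fit_scale_f50
from .closed_form import cumfp_closed_form
from .engine import cumfp_series, run_cohort
from .scenarios import (
    DEPENDENCE_DELTA,
    ScreeningScenario,
    catalogue_by_label,
    standard_catalogue,
)
from .schedules import IncidenceSchedule, MortalitySchedule, read_schedule_csv
from .survivorship import (
    SurvivorshipCurve,
    derive_incidence_from_survivorship,
    linear_survivorship,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "CohortInputs",
    "build_cohort_inputs",
    "scenario_table",
    "compare_scenarios",
    "zorzi_check",
    "run_reproduction",
    "write_table_csv",
]

DEFAULT_COMPARISON_PAIRS: tuple[tuple[str, str], ...] = (
    ("i1_sp98", "i2_sp98"),
    ("i3_sp98", "i2_sp98"),
    ("i2_sp98", "i2_sp95"),
    ("i2_sp92", "i2_sp95"),
    ("i2_sp98_start54", "i2_sp98"),
    ("i2_sp98_start58", "i2_sp98_start54"),
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a reproduction run.

    Exactly one of ``calibration`` and ``schedules`` drives the cohort:
    either the linear survivorship curve is calibrated to the anchors, or
    explicit mortality/incidence CSVs plus an entry prevalence are used.
    """

    calibration: Mapping[str, object] | None = None
    schedules: Mapping[str, object] | None = None
    scenarios: Union[str, Sequence[str]] = "all"
    sensitivity_delta: float = DEPENDENCE_DELTA
    out_dir: str = "results"
    seed: int = 0  # reserved; the cohort model is deterministic
    comparison_pairs: Sequence[tuple[str, str]] = field(
        default=DEFAULT_COMPARISON_PAIRS
    )

    def __post_init__(self) -> None:
        if (self.calibration is None) == (self.schedules is None):
            raise ValueError(
                "config needs exactly one of 'calibration' and 'schedules'"
            )

    @classmethod
    def default(cls) -> "RunConfig":
        return cls(
            calibration={
                "ratio_74": 0.54,
                "anchor_scenario": "i2_sp98",
                "anchor_value": 15_102.0,
            }
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {
            "calibration",
            "schedules",
            "scenarios",
            "sensitivity_delta",
            "out_dir",
            "seed",
            "comparison_pairs",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "comparison_pairs" in raw:
            raw["comparison_pairs"] = [tuple(p) for p in raw["comparison_pairs"]]
        return cls(**raw)

    def selected_scenarios(self) -> list[ScreeningScenario]:
        catalogue = catalogue_by_label()
        if self.scenarios == "all":
            return standard_catalogue()
        missing = [lab for lab in self.scenarios if lab not in catalogue]
        if missing:
            raise KeyError(f"unknown scenario labels: {missing}")
        return [catalogue[lab] for lab in self.scenarios]


@dataclass(frozen=True)
class CohortInputs:
    """Everything the engine needs: schedules, entry prevalence, and the
    survivorship curve they imply (kept for the external check)."""

    mortality: MortalitySchedule
    incidence: IncidenceSchedule
    prevalence_at_start: float
    curve: SurvivorshipCurve
    entry_age: int = 50


def build_cohort_inputs(config: RunConfig) -> CohortInputs:
    """Resolve a config into engine-ready schedules.

    Calibrated runs place all survivorship attrition in the incidence
    schedule (zero mortality): cumFP depends on the schedules only through
    their product, so this choice is observationally neutral.
    """
    import numpy as np

    from .closed_form import survivorship_from_schedules

    if config.calibration is not None:
        cal = dict(config.calibration)
        anchors = CalibrationAnchors(
            ratio_74=float(cal["ratio_74"]),
            anchor_scenario=catalogue_by_label()[str(cal["anchor_scenario"])],
            anchor_value=float(cal["anchor_value"]),
        )
        f50 = fit_scale_f50(anchors)
        logger.info(
            "calibrated f50 = %.6f (ratio_74 = %.4f, anchor %s = %.0f)",
            f50,
            anchors.ratio_74,
            anchors.anchor_scenario.label,
            anchors.anchor_value,
        )
        curve = linear_survivorship(f50, anchors.ratio_74)
        mortality = MortalitySchedule(50, np.zeros(25))
        incidence = derive_incidence_from_survivorship(curve, mortality)
        return CohortInputs(mortality, incidence, 1.0 - f50, curve)

    sched = dict(config.schedules)
    mortality = read_schedule_csv(sched["mortality"], MortalitySchedule)
    incidence = read_schedule_csv(sched["incidence"], IncidenceSchedule)
    prevalence = float(sched["prevalence_at_start"])
    curve = survivorship_from_schedules(mortality, incidence, prevalence)
    return CohortInputs(mortality, incidence, prevalence, curve)


def scenario_table(
    inputs: CohortInputs,
    scenarios: Sequence[ScreeningScenario],
    denominator: str = "all50",
    delta: float = 0.0,
) -> pd.DataFrame:
    """cumFP per 100 000 by age (rows) and strategy (columns).

    Every strategy is run from the common entry age so that columns share
    the age axis; strategies starting later simply contribute zeros until
    their first round.  ``delta > 0`` swaps in each strategy's
    conditional-dependence twin.
    """
    columns: dict[str, pd.Series] = {}
    for sc in scenarios:
        run_sc = sc.with_dependence(delta) if delta > 0 else sc
        traj = run_cohort(
            inputs.mortality,
            inputs.incidence,
            run_sc,
            prevalence_at_start=inputs.prevalence_at_start,
            start_age=inputs.entry_age,
        )
        series = cumfp_series(traj, denominator)
        columns[sc.label] = pd.Series(series.values, index=series.ages)
    table = pd.DataFrame(columns)
    table.index.name = "age"
    return table


def compare_scenarios(
    table: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Percent difference 100·(A − B)/B at the final age for label pairs."""
    last = table.iloc[-1]
    rows = []
    for a, b in pairs:
        if a not in table.columns or b not in table.columns:
            raise KeyError(f"comparison pair ({a}, {b}) not in table columns")
        if last[b] == 0.0:
            raise ZeroDivisionError(f"zero baseline cumFP for {b}")
        rows.append(
            {
                "scenario": a,
                "baseline": b,
                "pct_difference": 100.0 * (last[a] - last[b]) / last[b],
            }
        )
    return pd.DataFrame(rows)


def zorzi_check(
    curve: SurvivorshipCurve,
    specificity: float = 0.975,
    start_age: int = 52,
    n_rounds: int = 5,
    interval: int = 2,
) -> float:
    """Cumulative FP rate per 1000 after five biennial FIT rounds.

    Mirrors the long-running north-eastern-Italy programme: participants
    enter at the midpoint of the 50-54 recruitment ages and screen
    biennially at a specificity of 97.5%.  Returns the closed-form cumFP
    after ``n_rounds`` rounds per 1000 of the age-50 reference cohort.
    """
    stop = start_age + interval * (n_rounds - 1)
    sc = ScreeningScenario(start_age, stop, interval, specificity, label="zorzi")
    if not curve.covers(start_age, stop):
        raise ValueError("survivorship curve does not cover the screening ages")
    return cumfp_closed_form(curve, sc).at(stop) / 100.0


def write_table_csv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Serialize with cells rounded half-up to integers per 100 000."""
    import numpy as np

    rounded = table.apply(lambda col: np.floor(col + 0.5).astype(int))
    rounded.to_csv(path)


def run_reproduction(
    config: RunConfig, write: bool = True
) -> dict[str, pd.DataFrame]:
    """Produce the three cumFP tables and the comparison summary.

    Returns ``{"base", "sensitivity", "free50", "comparisons"}`` as
    unrounded DataFrames; with ``write=True`` the rounded CSVs land in
    ``config.out_dir``.
    """
    inputs = build_cohort_inputs(config)
    scenarios = config.selected_scenarios()
    base = scenario_table(inputs, scenarios, "all50")
    sens = scenario_table(inputs, scenarios, "all50", delta=config.sensitivity_delta)
    free50 = scenario_table(inputs, scenarios, "free50")
    pairs = [
        (a, b)
        for a, b in config.comparison_pairs
        if a in base.columns and b in base.columns
    ]
    comparisons = compare_scenarios(base, pairs) if pairs else pd.DataFrame()
    for label in base.columns:
        logger.info("age-74 cumFP per 100 000 [%s] = %.0f", label, base[label].iloc[-1])
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table_csv(base, out / "cumfp_base.csv")
        write_table_csv(sens, out / "cumfp_sensitivity.csv")
        write_table_csv(free50, out / "cumfp_free50.csv")
        comparisons.to_csv(out / "comparisons.csv", index=False)
    return {
        "base": base,
        "sensitivity": sens,
        "free50": free50,
        "comparisons": comparisons,
    }
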