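"""Calibration of the survivorship curve to published anchor values.

The empirical inputs behind the cohort — trial-based neoplasia incidence
and national life tables — are not distributed with the model, but the
model's outputs depend on them only through the neoplasia-free
survivorship curve F(a).  Two published summary figures pin that curve
down once a parametric shape is chosen:

* the *shape* anchor: about 54% of people neoplasia-free at 50 are still
  alive and neoplasia-free at 74, i.e. F(74)/F(50) = 0.54; and
* the *scale* anchor: biennial screening at specificity 98% from age 50
  yields a cumulative false-positive count of 15 102 per 100 000
  50-year-olds by age 74.

With a linear F the closed-form cumFP is proportional to f50 = F(50) at
fixed shape, so the scale fit is a single division: f50 equals the anchor
value divided by the unit-scale (f50 = 1) cumFP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .closed_form import cumfp_closed_form
from .scenarios import ScreeningScenario
from .survivorship import SurvivorshipCurve, linear_survivorship

__all__ = [
    "CalibrationAnchors",
    "DEFAULT_ANCHORS",
    "fit_scale_f50",
    "calibrated_linear_curve",
]


@dataclass(frozen=True)
class CalibrationAnchors:
    """Published anchors pinning down the linear survivorship curve.

    ``ratio_74`` is the shape target F(74)/F(50); ``anchor_scenario`` and
    ``anchor_value`` (age-74 cumFP per 100 000 alive at 50) set the scale.
    """

    ratio_74: float
    anchor_scenario: ScreeningScenario
    anchor_value: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ratio_74) and 0.0 < self.ratio_74 < 1.0):
            raise ValueError("ratio_74 must lie strictly in (0, 1)")
        if not (0.0 < self.anchor_value < 100_000.0):
            raise ValueError("anchor_value must lie in (0, 100000) per 100 000")
        if self.anchor_scenario.dependence_reduction != 0.0:
            raise ValueError(
                "calibration anchor must use conditional independence (delta = 0)"
            )


DEFAULT_ANCHORS = CalibrationAnchors(
    ratio_74=0.54,
    anchor_scenario=ScreeningScenario(50, 74, 2, 0.98),
    anchor_value=15_102.0,
)


def fit_scale_f50(anchors: CalibrationAnchors) -> float:
    """f50 making the closed-form age-74 cumFP hit the anchor value.

    cumFP at fixed shape is linear in f50, so
    ``f50 = (anchor_value / 100000) / U`` where U is the unit-scale
    (f50 = 1) cumFP fraction of the anchor scenario at its stop age.
    """
    sc = anchors.anchor_scenario
    unit = linear_survivorship(1.0, anchors.ratio_74, 50, sc.stop_age)
    u = cumfp_closed_form(unit, sc).at(sc.stop_age) / 100_000.0
    if u <= 0.0:
        raise ValueError("anchor scenario has no screening rounds in range")
    f50 = (anchors.anchor_value / 100_000.0) / u
    if 1.0 < f50 <= 1.0 + 1e-9:  # float noise at the no-attrition limit
        f50 = 1.0
    if not 0.0 < f50 <= 1.0:
        raise ValueError(
            f"fitted f50 = {f50:.4g} outside (0, 1]; anchors are inconsistent"
        )
    return f50


def calibrated_linear_curve(
    anchors: CalibrationAnchors = DEFAULT_ANCHORS,
) -> SurvivorshipCurve:
    """Linear survivorship curve fitted to the anchors (ages 50-74)."""
    return linear_survivorship(fit_scale_f50(anchors), anchors.ratio_74)
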