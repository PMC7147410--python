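import pytest

from cumfp import (
    DEFAULT_ANCHORS,
    RunConfig,
    build_cohort_inputs,
    calibrated_linear_curve,
    catalogue_by_label,
    fit_scale_f50,
    run_reproduction,
)


@pytest.fixture(scope="session")
def calibrated_f50():
    return fit_scale_f50(DEFAULT_ANCHORS)


@pytest.fixture(scope="session")
def calibrated_curve():
    return calibrated_linear_curve()


@pytest.fixture(scope="session")
def catalogue():
    return catalogue_by_label()


@pytest.fixture(scope="session")
def cohort_inputs():
    """Engine-ready schedules for the default calibrated run."""
    return build_cohort_inputs(RunConfig.default())


@pytest.fixture(scope="session")
def reproduction_tables():
    """Base, sensitivity, free-at-50, and comparison tables (unrounded)."""
    return run_reproduction(RunConfig.default(), write=False)
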