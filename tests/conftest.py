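import numpy as np
import pytest

from polyburst import (
    AmplitudeModel,
    RunConfig,
    ThreeStateParams,
    UnitaryIntensity,
)


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture
def exact_unitary() -> UnitaryIntensity:
    """Unitary intensity without draw-to-draw spread, for exact accounting."""
    return UnitaryIntensity(mean_au=330.0, sd_au=0.0)


@pytest.fixture
def unit_amplitude_params() -> ThreeStateParams:
    """Deterministic single-transcript production: one ON period of one
    transcript per permissive cycle, no division loss, no decay."""
    return ThreeStateParams(
        p_op=1.0,
        lambda_on=1.0,
        deterministic_on_counts=True,
        amplitude=AmplitudeModel(w_nb=0.0, pois_mean=1e-12),
        division_retention=1.0,
        half_life_h=np.inf,
        desync_max_h=0.0,
        cycle3_production=False,
    )


def make_trajectory(values, interval=4.0, corrected=True, cell="c1"):
    from polyburst import FluorescenceTrajectory

    return FluorescenceTrajectory(
        cell_id=cell,
        frame_interval_min=interval,
        intensity_au=np.asarray(values, dtype=float),
        bleach_corrected=corrected,
    )
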