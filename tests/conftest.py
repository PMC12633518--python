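import numpy as np
import pytest

from netfp.model import FrameSchedule
from netfp.registry import build_default_registry
from netfp.synthetic import (
    CohortDesign,
    GroupSpec,
    InputFunctionParams,
    simulate_cohort,
    simulate_input_function,
)


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def schedule():
    # 4x0.5, 4x1, 8x2, 6x5, 2x10 min  -> 60 min scan
    durations = [0.5] * 4 + [1.0] * 4 + [2.0] * 8 + [5.0] * 6 + [10.0] * 2
    end = np.cumsum(durations)
    return FrameSchedule(end - durations, end)


@pytest.fixture(scope="session")
def idif():
    grid = np.unique(np.concatenate([np.linspace(0, 3, 121), np.linspace(3, 95, 200)]))
    return simulate_input_function(InputFunctionParams(), grid)


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise pure-irreversible cohort with ground truth (12 scans)."""
    design = CohortDesign(
        groups=(
            GroupSpec("HC", 8, "TRACER-A", "B1"),
            GroupSpec("DIS", 4, "TRACER-A", "B1",
                      affected_rois=("lh_putamen", "rh_putamen"), k1_effect=0.2),
        ),
        noise_kappa=0.0,
        vb_scale=0.0,
        subject_k1_sd=0.05,
    )
    scans, truth = simulate_cohort(design, seed=101)
    return scans, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    design = CohortDesign(
        groups=(GroupSpec("HC", 10, "TRACER-A", "B1"),),
        noise_kappa=0.3,
        subject_k1_sd=0.05,
    )
    scans, truth = simulate_cohort(design, seed=202)
    return scans, truth
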