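import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from eggflow import CalibrationModel, SampleSet, SimConfig, simulate_sample

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the instrument's bead-fitted calibration constants (µm per TOF unit, µm)
TRUE_SLOPE = 5.94
TRUE_INTERCEPT = -491.78


@pytest.fixture(scope="session")
def true_model() -> CalibrationModel:
    return CalibrationModel(slope=TRUE_SLOPE, intercept=TRUE_INTERCEPT, n_beads=2)


@pytest.fixture(scope="session")
def standard_sample():
    """Default synthetic mixture (30% debris, 55% aligned, 15% misaligned), seed 1."""
    return simulate_sample(SimConfig(seed=1))


def make_sample(ids, tofs, exts=None, sizes=None, profiles=None) -> SampleSet:
    events = pd.DataFrame(
        {
            "object_id": list(ids),
            "tof": np.asarray(tofs, dtype=float),
            "ext": np.asarray(exts if exts is not None else np.ones(len(list(ids))), dtype=float),
        }
    )
    if sizes is not None:
        events["size_um"] = np.asarray(sizes, dtype=float)
    return SampleSet(sample_id="test", events=events, profiles=profiles)
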