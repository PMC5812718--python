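import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from multipatch import PipetteSpec, TissueModel, VirtualRig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def deterministic_tissue():
    """Noise- and randomness-free tissue: scripted encounters, certain seals."""
    return TissueModel(
        encounter_hazard_per_step=0.0,
        encounter_script=((0, 10), (1, 20), (2, 30), (3, 40)),
        dislodge_prob_per_foreign_move=0.0,
        seal_success_base=1.0,
        seal_success_decay_per_min_waiting=1.0,
        breakin_success_prob_per_pulse=1.0,
        measurement_noise_mohm=0.0,
    )


@pytest.fixture
def no_clog_spec():
    return PipetteSpec(clog_on_descent_prob=0.0)


@pytest.fixture
def deterministic_rig(deterministic_tissue, no_clog_spec):
    return VirtualRig(4, pipette_spec=no_clog_spec, tissue=deterministic_tissue, seed=0)
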