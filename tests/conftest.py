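import numpy as np
import pytest
from hypothesis import settings

from bihemi import synth
from bihemi.evoked import NakaRushtonParams

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_truth() -> synth.GroundTruth:
    return synth.GroundTruth()


@pytest.fixture(scope="session")
def quiet_truth() -> synth.GroundTruth:
    """No measurement noise or artifact: analysis sees the generative signal."""
    return synth.GroundTruth(noise_sd=0.0, artifact_gain=0.0)


@pytest.fixture(scope="session")
def small_session(default_truth) -> synth.SyntheticSession:
    return synth.generate_session(
        default_truth, n_trials=60, contrast_set=[0, 0.12, 0.25, 0.5, 1.0], seed=11
    )


def pair_truth(rho: float, noise_sd: float = 0.0, **kwargs) -> synth.GroundTruth:
    """Single-area-pair ground truth with a prescribed homotopic coupling."""
    defaults = dict(
        areas=[synth.AreaSpec("PM", 1.6, rho)],
        h_true=max(rho, 1e-6) if "h_true" not in kwargs else kwargs.pop("h_true"),
        noise_sd=noise_sd,
        artifact_gain=0.0,
        nr=NakaRushtonParams(0.0, 1.0, 0.3, 2.0),
    )
    defaults.update(kwargs)
    return synth.GroundTruth(**defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
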