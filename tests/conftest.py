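import numpy as np
import pytest

from footkin import DEFAULT_SCHEMA
from footkin.synthgen import SynthConfig


@pytest.fixture(scope="session")
def schema():
    return DEFAULT_SCHEMA


def neutral_config(**kwargs) -> SynthConfig:
    """Noise-free configuration with a neutral natural stance, so every
    prescribed angle equals the measured absolute angle exactly."""
    cfg = SynthConfig(**kwargs)
    cfg.condition_offsets["natural"] = {
        k: 0.0 for k in cfg.condition_offsets["natural"]
    }
    return cfg


@pytest.fixture
def neutral_cfg():
    return neutral_config(seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def calibrated_subject():
    """One noise-free subject processed end to end (session-cached)."""
    from footkin import pipeline, synthgen

    cfg = neutral_config(seed=1, noise_sd=0.0)
    trials, truths = synthgen.generate_subject(cfg, n_static_repeats=1)
    result = pipeline.run_subject(trials, subject="S-clean")
    return cfg, trials, truths, result


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
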