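import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rlwm_lba.synth import EEGConfig, GeneratorConfig, simulate_behavior, simulate_eeg
from rlwm_lba.task import DesignSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")

#: Reduced channel set (includes all component centers) used by EEG tests.
TEST_CHANNELS = [
    "Fz", "F3", "F4", "FCz", "FC1", "FC2", "Cz", "C3", "C4",
    "CPz", "CP1", "CP2", "Pz", "P3", "P4", "POz", "PO3", "PO4", "Oz",
]


def small_design() -> DesignSpec:
    return DesignSpec(n_blocks=4, set_size_sequence=(2, 3, 4, 5))


def make_eeg_config(**kw) -> EEGConfig:
    defaults = dict(channels=TEST_CHANNELS, sampling_rate=128.0, epoch_samples=179)
    defaults.update(kw)
    return EEGConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Six subjects on a reduced 4-block design."""
    cfg = GeneratorConfig(n_subjects=6, seed=11, design=small_design())
    return simulate_behavior(cfg)


@pytest.fixture(scope="session")
def small_eeg(small_cohort):
    cfg = GeneratorConfig(n_subjects=6, seed=11, design=small_design(), eeg=make_eeg_config())
    stim, resp = simulate_eeg(small_cohort, cfg)
    return stim, resp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
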