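"""Shared fixtures: small seeded designs, schedules, and synthetic datasets.

Expensive fixtures (wavelet power on simulated EEG) are session-scoped so the
suite computes them once.
"""

import numpy as np
import pytest

from seqdecode.decode import DecodeConfig
from seqdecode.spectral import build_wavelet_bank, tf_power
from seqdecode.synth_eeg import ALPHA, THETA, CodePatternSpec, NoiseSpec, simulate_dataset
from seqdecode.task_model import ExperimentDesign, assign_probes, build_schedule


@pytest.fixture(scope="session")
def exp1_design():
    return ExperimentDesign.from_variant("exp1")


@pytest.fixture(scope="session")
def exp3_design():
    return ExperimentDesign.from_variant("exp3")


@pytest.fixture(scope="session")
def small_design():
    """6-block exp1 design: the smallest block count that balances the six
    sequences, 324 trials."""
    return ExperimentDesign.from_variant("exp1", n_blocks=6)


@pytest.fixture(scope="session")
def small_schedule(small_design):
    return assign_probes(build_schedule(small_design, seed=11), seed=12)


@pytest.fixture(scope="session")
def small_bank():
    return build_wavelet_bank(n_freqs=8)


@pytest.fixture(scope="session")
def quick_config():
    return DecodeConfig(n_iterations=2, window_step=25, seed=5)


@pytest.fixture(scope="session")
def element_tf(small_schedule, small_bank):
    """Wavelet power of a dataset with a high-SNR alpha-band element pattern
    in the late preparation window."""
    patterns = [
        CodePatternSpec(code="element", band=ALPHA, window=(-600.0, 0.0), amplitude=8.0)
    ]
    eeg = simulate_dataset(
        small_schedule, patterns, NoiseSpec(noise_sd=10.0), seed=21,
        analysis_window=(-700.0, 400.0),
    )
    return tf_power(eeg, small_bank)


@pytest.fixture(scope="session")
def noise_tf(small_schedule, small_bank):
    """Wavelet power of pure 1/f noise (no injected label information)."""
    eeg = simulate_dataset(
        small_schedule, [], NoiseSpec(noise_sd=10.0), seed=22,
        analysis_window=(-700.0, 400.0),
    )
    return tf_power(eeg, small_bank)
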