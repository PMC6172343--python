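import numpy as np
import pytest

from lspdbn import (IncompleteSegment, MotorImageryConfig, Trial,
                    generate_dataset, simulate_two_tone)


@pytest.fixture(scope="session")
def two_tone_segment() -> IncompleteSegment:
    """The intact two-tone probe signal wrapped as a single-channel segment."""
    sig = simulate_two_tone()
    return IncompleteSegment(values=sig.values[None, :],
                             timestamps=sig.timestamps,
                             sampling_rate=sig.sampling_rate,
                             original_length=len(sig.values),
                             label=0, source_trial=0, segment_index=0)


@pytest.fixture(scope="session")
def small_mi_config() -> MotorImageryConfig:
    return MotorImageryConfig(n_channels=8, sampling_rate=250.0,
                              trial_duration=2.0)


@pytest.fixture(scope="session")
def small_dataset(small_mi_config):
    """A small but learnable synthetic dataset (8 channels, 2-s trials)."""
    return generate_dataset(small_mi_config, trials_per_class=10, seed=7)


def make_segment(values: np.ndarray, sampling_rate: float = 250.0,
                 label: int = 0) -> IncompleteSegment:
    values = np.atleast_2d(values)
    n = values.shape[1]
    return IncompleteSegment(values=values,
                             timestamps=np.arange(n) / sampling_rate,
                             sampling_rate=sampling_rate, original_length=n,
                             label=label, source_trial=0, segment_index=0)
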