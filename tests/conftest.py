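import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # bloch_oracle importable

from mrf3d import (
    SequenceConfig,
    build_dictionary,
    build_schedule,
    compress,
    default_grid,
)


@pytest.fixture(scope="session")
def schedule():
    """Full default acquisition schedule (1750 readouts)."""
    return build_schedule(SequenceConfig())


@pytest.fixture(scope="session")
def tiny_schedule():
    """Short schedule for cheap unit tests (44 readouts)."""
    cfg = SequenceConfig(
        n_exc_fisp=8,
        n_exc_flash=8,
        n_exc_per_tsl=4,
        tsl_list=(2.0, 10.0, 45.0),
        max_order=40,
    )
    return build_schedule(cfg)


@pytest.fixture(scope="session")
def midrange_dictionary(schedule):
    """~6.5k-atom dictionary at the 6% step over mid-range tissue values;
    the workhorse for matching and compression tests."""
    grid = default_grid(
        t1_range=(500.0, 1500.0),
        t2_range=(40.0, 120.0),
        t1rho_range=(50.0, 140.0),
    )
    return build_dictionary(grid, schedule)


@pytest.fixture(scope="session")
def compressed_midrange(midrange_dictionary):
    """Default matching rank (30), which retains >= 99.9% of the energy."""
    return compress(midrange_dictionary, rank=30)


def add_noise_at_snr(rng, signals, snr):
    """Complex Gaussian noise giving the requested per-sample SNR per row."""
    sig = np.atleast_2d(signals)
    sigma = np.sqrt(np.mean(np.abs(sig) ** 2, axis=1)) / snr
    noise = (
        rng.standard_normal(sig.shape) + 1j * rng.standard_normal(sig.shape)
    ) / np.sqrt(2.0)
    return sig + sigma[:, None] * noise
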