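import numpy as np
import pytest

from fpnet import (
    ResponseCollection,
    ResponseMatrix,
    SyntheticConfig,
    generate_benchmark_like,
)
from fpnet.synthetic_data import disjoint_config

MONOS = [f"S{i}" for i in range(1, 9)]


def make_collection(arrays, dt=0.01, on_window=None, class_labels=None):
    """Build a collection from {stimulus: [rate matrices]}."""
    first = next(iter(arrays.values()))[0]
    if on_window is None:
        on_window = (0.0, first.shape[1] * dt)
    trials = {
        s: [
            ResponseMatrix(s, k, rates, dt=dt, on_window=on_window)
            for k, rates in enumerate(mats)
        ]
        for s, mats in arrays.items()
    }
    return ResponseCollection(
        stimuli=list(arrays),
        trials=trials,
        class_labels=class_labels or {},
    )


@pytest.fixture(scope="session")
def noiseless_disjoint():
    """Noiseless collection with perfectly selective nodes, plus truth."""
    cfg = disjoint_config(snr=10.0, seed=3)
    return generate_benchmark_like(cfg, noiseless=True)


@pytest.fixture(scope="session")
def benchmark_snr10():
    """Benchmark-like noisy collection at SNR 10 (easy regime), plus truth."""
    return generate_benchmark_like(SyntheticConfig(snr=10.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
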