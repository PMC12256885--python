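import numpy as np
import pytest

from mregle import waveforms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_fused(X: np.ndarray, name: str = "blk", prefix: str = "S") -> waveforms.FusedTensor:
    """Wrap a plain (n, L) matrix as a single-modality fused tensor."""
    spec = waveforms.FusionSpec("concatenate", (name,), {name: 1.0})
    ids = [f"{prefix}{i}" for i in range(X.shape[0])]
    return waveforms.FusedTensor(ids, X, spec, {name: X.shape[1]})


@pytest.fixture
def linear_waveform_data(rng):
    """Rank-4 noise-free 'waveform' data split into train and validation."""
    n, L, k = 600, 120, 4
    B = rng.standard_normal((L, k))
    Z = rng.standard_normal((n, k))
    X = Z @ B.T
    return make_fused(X[:500]), make_fused(X[500:], prefix="V"), X
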