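import numpy as np
import pytest

from avafp.atm import TransitionMatrix
from avafp.avalanche import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(data, fs=4.0, **kw):
    """Recording around a small float64 matrix (fs low so 1-s check passes)."""
    data = np.asarray(data, dtype=np.float64)
    defaults = dict(
        subject_id="sub-000",
        session="test",
        group="HC",
        fs=fs,
        roi_names=[f"r{i}" for i in range(data.shape[0])],
    )
    defaults.update(kw)
    return Recording(data=data, **defaults)


def sym_tm(matrix, delta_bins=1):
    """Symmetric TransitionMatrix from a square array."""
    m = np.asarray(matrix, dtype=np.float64)
    return TransitionMatrix(
        values=(m + m.T) / 2,
        roi_names=None,
        delta_bins=delta_bins,
        n_avalanches=1,
        symmetric=True,
    )


def tm_from_edges(edges, n):
    """Symmetric TransitionMatrix whose strict upper triangle equals edges."""
    M = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    M[iu] = edges
    M[(iu[1], iu[0])] = edges
    return sym_tm(M)
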