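import numpy as np
import pytest

from ssx.statespace import make_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Noiseless 40-gene fixture with a known mixed spectrum."""
    spec = [0.9, 0.4, 0.7 * np.exp(1j * np.pi / 6), 0.7 * np.exp(-1j * np.pi / 6)]
    ds, truth = make_synthetic_dataset(
        N1=40, N2=12, M1=4, M2=3, T=14, eigen_spec=spec, noise_sd=0.0, seed=7
    )
    return ds, truth


def write_matrix_file(tmp_path, name, ids, matrix, labels=None, delimiter="\t"):
    from ssx.io_data import write_expression_matrix

    path = tmp_path / name
    write_expression_matrix(path, ids, matrix, labels, delimiter)
    return path
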