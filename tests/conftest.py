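import numpy as np
import pytest

from specseed.dataset import SpectraDataset
from specseed.grid import WavelengthGrid


@pytest.fixture
def toy_grid() -> WavelengthGrid:
    return WavelengthGrid(np.linspace(900.0, 1700.0, 10))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_dataset(X: np.ndarray, y=None) -> SpectraDataset:
    """Wrap a matrix in a SpectraDataset with an evenly spaced grid."""
    N, L = X.shape
    if y is None:
        y = np.array(["healthy"] * (N // 2) + ["defective"] * (N - N // 2))
    return SpectraDataset(X, y, WavelengthGrid(np.linspace(900.0, 1700.0, L)))


def separable_dataset(
    n_per_class: int = 20, L: int = 16, gap: float = 4.0, seed: int = 0
) -> SpectraDataset:
    """Noise-free linearly separable two-class spectra (offset at 3 bands)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, (2 * n_per_class, L))
    bands = sorted({1, L // 2, L - 2})
    X[n_per_class:, bands] += gap
    y = np.array(["healthy"] * n_per_class + ["defective"] * n_per_class)
    return SpectraDataset(X, y, WavelengthGrid(np.linspace(900.0, 1700.0, L)))
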