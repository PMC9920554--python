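import numpy as np
import pytest

from grapespec import synthetic_data
from grapespec.spectral_library import SpectralLibrary, WavelengthGrid


@pytest.fixture(scope="session")
def syrah40():
    """Small single-variety synthetic library on the canonical 10-nm grid."""
    return synthetic_data.syrah_library(n=40, seed=11)


@pytest.fixture(scope="session")
def multi_library():
    """Four-variety synthetic library, 12 samples each."""
    cfg = synthetic_data.GeneratorConfig(n_per_variety=12, master_seed=5)
    return synthetic_data.generate_library(cfg)


def make_library(X, brix, wavelengths=None, variety="Syrah"):
    """Hand-rolled library around an explicit spectra matrix."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if wavelengths is None:
        wavelengths = np.arange(350, 350 + 10 * X.shape[1], 10, dtype=float)
    return SpectralLibrary(
        grid=WavelengthGrid(wavelengths),
        sample_ids=[f"S{i:03d}" for i in range(n)],
        varieties=[variety] * n,
        years=np.full(n, 2021),
        bunch_labels=[f"B{i % 5}" for i in range(n)],
        brix=np.asarray(brix, dtype=float),
        reflectance=X,
    )


@pytest.fixture
def library_factory():
    return make_library
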