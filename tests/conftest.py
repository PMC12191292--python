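import numpy as np
import pytest

from drgpd.epg import SequenceParams
from drgpd.relaxometry import fit_volume
from drgpd.synthetic import Compartment, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def seq() -> SequenceParams:
    return SequenceParams()


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A 32x32x8 phantom with geometry scaled from the default: quick to fit
    while keeping >= 20 CSF voxels per slice and four DRG ellipsoids."""
    drg_m0 = overrides.pop("drg_M0", 0.765)
    compartments = (
        Compartment(1, (16, 7, 4), (3.6, 3.6, 14), M0=1.00, T2=2000.0, T1=4000.0),
        Compartment(10, (9, 17, 2.2), (3.4, 2.8, 1.8), M0=drg_m0, T2=95.0),
        Compartment(11, (23, 17, 2.2), (3.4, 2.8, 1.8), M0=drg_m0, T2=95.0),
        Compartment(20, (9, 24, 5.6), (3.4, 2.8, 1.8), M0=drg_m0, T2=95.0),
        Compartment(21, (23, 24, 5.6), (3.4, 2.8, 1.8), M0=drg_m0, T2=95.0),
    )
    return PhantomSpec(
        shape=(32, 32, 8),
        compartments=compartments,
        body_semi_axes=(15.0, 15.0),
        **overrides,
    )


@pytest.fixture(scope="session")
def default_phantom(seq):
    """Noiseless default-geometry phantom: (echo_data, labels, truth)."""
    return make_phantom(PhantomSpec(), seq)


@pytest.fixture(scope="session")
def fitted_default(default_phantom, seq):
    """Corrected maps of the noiseless default phantom (shared: fitting the
    full body mask is the expensive step of the suite)."""
    echo, labels, truth = default_phantom
    maps = fit_volume(echo, truth.fit_mask, seq)
    return echo, labels, truth, maps


@pytest.fixture(scope="session")
def small_phantom(seq):
    spec = small_phantom_spec()
    return spec, make_phantom(spec, seq)


def rician(rng: np.random.Generator, clean: np.ndarray, sigma: float) -> np.ndarray:
    return np.abs(
        clean + rng.normal(0, sigma, clean.shape) + 1j * rng.normal(0, sigma, clean.shape)
    )
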