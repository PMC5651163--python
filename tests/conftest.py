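"""Shared fixtures: small synthetic acquisitions and exact-kernel systems."""

import numpy as np
import pytest

import rpgrappa as rg


@pytest.fixture(scope="session")
def phantom_8ch():
    """Noiseless 8-channel 96x96 phantom acquisition with SoS reference."""
    spec = rg.PhantomSpec(image_size=(96, 96), nc=8, noise_sigma=0.0, seed=3)
    ks, ref = rg.generate_phantom_kspace(spec)
    return ks, ref


@pytest.fixture(scope="session")
def undersampled_8ch(phantom_8ch):
    """The 8-channel phantom undersampled at A_f=3 with a 32-line ACS."""
    ks, ref = phantom_8ch
    return rg.undersample(ks, 3, 32), ref


@pytest.fixture(scope="session")
def exact_fixture():
    """Small exact-kernel k-space (dy=2, dx=3, A=2, nc=2) with embedded W."""
    geom = rg.KernelGeometry(d_y=2, d_x=3, accel=2, nc=2)
    ks, W = rg.make_exact_kernel_kspace(geom, ny=32, nx=24, seed=5)
    return geom, ks, W


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_complex_system(rng, m, n, l):
    """A generic well-conditioned complex least-squares problem."""
    S = rng.normal(size=(m, n)) + 1j * rng.normal(size=(m, n))
    T = rng.normal(size=(m, l)) + 1j * rng.normal(size=(m, l))
    return S, T
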