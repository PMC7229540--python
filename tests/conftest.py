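"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's FFT paths: direct O(N^4)
double-sum DFTs, direct-sum circular correlation, and centered zero-pad
upsampling built from scratch, so that agreement is evidence and not
tautology.
"""

import numpy as np
import pytest

from subshift import ImageGrid, ShiftVector, make_phantom


# ---------------------------------------------------------------- oracles
def dft2_bruteforce(x: np.ndarray) -> np.ndarray:
    """Direct O(N^4) unnormalized forward 2-D DFT."""
    m1, m2 = x.shape
    out = np.zeros((m1, m2), dtype=complex)
    for u in range(m1):
        for v in range(m2):
            acc = 0.0 + 0.0j
            for r in range(m1):
                for c in range(m2):
                    acc += x[r, c] * np.exp(-2j * np.pi * (u * r / m1 + v * c / m2))
            out[u, v] = acc
    return out


def circular_correlation_bruteforce(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """R[dy, dx] = sum_x f1(x) * f2(x + d), periodic, direct summation."""
    m1, m2 = f1.shape
    out = np.zeros((m1, m2))
    for dy in range(m1):
        for dx in range(m2):
            acc = 0.0
            for r in range(m1):
                for c in range(m2):
                    acc += f1[r, c] * f2[(r + dy) % m1, (c + dx) % m2]
            out[dy, dx] = acc
    return out


def zeropad_upsampled_values(p: np.ndarray, factor: int) -> np.ndarray:
    """Upsampled correlation (times M1*M2) by centered spectral zero-padding.

    Output index j corresponds to lag j/factor (wrapped).  Built with
    fftshift/ifftshift-style centering, independently of the package's
    embedding helper.
    """
    m1, m2 = p.shape
    n1, n2 = factor * m1, factor * m2
    centered = np.fft.fftshift(p)
    q = np.zeros((n1, n2), dtype=complex)
    r0 = n1 // 2 - m1 // 2
    c0 = n2 // 2 - m2 // 2
    q[r0:r0 + m1, c0:c0 + m2] = centered
    return np.fft.fft2(np.fft.ifftshift(q))


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200507)


@pytest.fixture(scope="session")
def small_image(rng):
    """8x8 structured random raster for exact spectral checks."""
    return rng.standard_normal((8, 8))


@pytest.fixture(scope="session")
def phantom128():
    return make_phantom((128, 128), seed=11)


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom((64, 64), seed=7)


@pytest.fixture
def ramp_image():
    """Small deterministic non-constant image usable everywhere."""
    r = np.arange(16)[:, None] + 0.1 * np.arange(16)[None, :]
    return ImageGrid(np.sin(r) + 0.5 * np.cos(2.3 * r))


def assert_shift_close(est: ShiftVector, truth: ShiftVector, tol: float):
    assert abs(est.dy - truth.dy) <= tol, f"dy: {est.dy} vs {truth.dy}"
    assert abs(est.dx - truth.dx) <= tol, f"dx: {est.dx} vs {truth.dx}"
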