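"""Registration quality metrics: scale-minimized NRMSE and RMS gray error.

``nrmse`` is the normalized root-mean-square error minimized over a
global intensity scale ``alpha``::

    E^2 = min_alpha  sum (alpha*g - f)^2 / sum f^2
        = 1 - (sum f*g)^2 / (sum f^2 * sum g^2),   alpha* = sum f*g / sum g^2

so it is invariant to positive rescaling of the second image and lies in
[0, 1] (0 for a perfect match up to scale, 1 for orthogonal patterns).
When a shift is supplied the second image is circularly un-shifted first,
so a correct registration drives E toward 0.

``target_registration_error`` is the plain RMS gray-value difference
(smaller is better; |c| for a constant offset c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ShiftVector, as_pixels

__all__ = ["MetricReport", "nrmse", "target_registration_error"]


@dataclass(frozen=True)
class MetricReport:
    nrmse: float
    alpha: float
    the_value: float
    n_pixels: int


def target_registration_error(i1, i2) -> float:
    """RMS gray-value difference over the full image domain."""
    a = as_pixels(i1)
    b = as_pixels(i2)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def nrmse(f1, f2, shift: ShiftVector | None = None) -> MetricReport:
    """Scale-minimized NRMSE of ``f2`` against reference ``f1``.

    Parameters
    ----------
    shift
        If given, ``f2`` is circularly shifted by ``-shift`` (Fourier
        interpolation for fractional components) before comparison —
        i.e. pass the registration estimate to score the alignment.
    """
    f = as_pixels(f1)
    g = as_pixels(f2)
    if f.shape != g.shape:
        raise ValueError(f"image shapes differ: {f.shape} vs {g.shape}")
    if shift is not None:
        from .pipeline import apply_shift

        g = apply_shift(g, -shift).pixels

    sf2 = float(np.sum(f * f))
    if sf2 == 0.0:
        raise ValueError("degenerate reference image: sum of squares is zero")
    sg2 = float(np.sum(g * g))
    sfg = float(np.sum(f * g))
    if sg2 == 0.0:
        alpha, e2 = 0.0, 1.0
    else:
        alpha = sfg / sg2
        # residual at the optimal scale, computed directly: numerically
        # stable near 0, unlike the algebraically equal 1 - rho^2 form
        e2 = float(np.sum((alpha * g - f) ** 2)) / sf2
    e = math.sqrt(max(e2, 0.0))
    the = float(np.sqrt(np.mean((f - g) ** 2)))
    return MetricReport(nrmse=e, alpha=alpha, the_value=the, n_pixels=f.size)
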