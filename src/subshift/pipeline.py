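"""End-to-end translation registration: coarse stage, fine stage, combination.

Two methods share the fine stage (the matrix-product upsampled window):

* ``improved`` — decimated phase-correlation coarse stage (a 32x32-ish
  inverse transform regardless of image size, aliases resolved by direct
  correlation evaluation), then the bidirectional window search;
* ``baseline`` — the classic two-step algorithm: global factor-2
  zero-padded coarse stage, then full evaluation of the window.

The estimates combine as ``delta = (x + xbar/n, y + ybar/n)`` where
``(x, y)`` is the integer coarse center, ``(xbar, ybar)`` the window
offset in upsampled-grid units and ``n`` the upsampling factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .coarse import (
    CoarseEstimate,
    DownsampleConfig,
    coarse_shift_baseline,
    coarse_shift_decimated,
    disambiguate_candidates,
)
from .core import (
    ImageGrid,
    ShiftVector,
    as_pixels,
    cross_power_spectrum,
    forward_spectrum,
    signed_frequencies,
)
from .fine import (
    FinePeak,
    UpsampleConfig,
    bidirectional_search,
    full_window_argmax,
)

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "RegistrationError",
    "ShiftError",
    "register",
    "apply_shift",
    "shift_error",
]


class RegistrationError(RuntimeError):
    """Raised when a stage cannot produce a usable estimate."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class RegistrationConfig:
    """Pipeline settings.

    ``downsample=None`` resolves the decimation factors per image via the
    ``K = M/32`` rule at registration time.  ``normalized_spectrum``
    selects phase correlation (default) vs raw cross-correlation for the
    fine stage; the decimated coarse stage always normalizes.
    """

    upsample: UpsampleConfig = field(default_factory=lambda: UpsampleConfig(epsilon=100))
    downsample: DownsampleConfig | None = None
    method: str = "improved"
    normalized_spectrum: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("improved", "baseline"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class RegistrationResult:
    """Estimated translation plus per-stage diagnostics.

    Invariant: ``shift == coarse.shift + fine.offset_pixels`` exactly
    (componentwise), where ``coarse.shift`` is the integer center the
    fine window was placed on.
    """

    shift: ShiftVector
    coarse: CoarseEstimate
    fine: FinePeak
    method: str
    diagnostics: dict = field(default_factory=dict)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def register(reference, moving, config: RegistrationConfig | None = None) -> RegistrationResult:
    """Estimate the translation taking ``reference`` onto ``moving``.

    Returns the shift ``d`` such that (up to noise)
    ``moving(r, c) = reference((r - dy) mod M1, (c - dx) mod M2)``.
    """
    cfg = config or RegistrationConfig()
    ref = reference if isinstance(reference, ImageGrid) else ImageGrid(reference)
    mov = moving if isinstance(moving, ImageGrid) else ImageGrid(moving)
    if ref.shape != mov.shape:
        raise ValueError(f"image shapes differ: {ref.shape} vs {mov.shape}")

    s1 = forward_spectrum(ref)
    s2 = forward_spectrum(mov)
    diagnostics: dict = {"method": cfg.method}

    if cfg.method == "improved":
        ds = cfg.downsample or DownsampleConfig.auto(ref.shape)
        coarse = coarse_shift_decimated(s1, s2, ds)
        diagnostics["decimated_shape"] = coarse.surface_shape
        diagnostics["coarse_candidates"] = len(coarse.candidates)
        if coarse.ambiguous:
            coarse = disambiguate_candidates(s1, s2, coarse)
            diagnostics["disambiguation_tie"] = coarse.tie
        if not coarse.valid:
            raise RegistrationError(
                "coarse stage could not resolve a unique peak",
                diagnostics={**diagnostics, "coarse": coarse},
            )
        center = ShiftVector(float(int(coarse.shift.dy)), float(int(coarse.shift.dx)))
        coarse = replace(coarse, shift=center)
    else:
        raw = coarse_shift_baseline(s1, s2, normalized=cfg.normalized_spectrum)
        diagnostics["baseline_halfpixel"] = raw.shift.as_tuple()
        if not raw.valid:
            raise RegistrationError(
                "baseline coarse stage found no unique peak",
                diagnostics={**diagnostics, "coarse": raw},
            )
        center = ShiftVector(
            float(_round_half_up(raw.shift.dy)), float(_round_half_up(raw.shift.dx))
        )
        coarse = replace(raw, shift=center)

    p_fine = cross_power_spectrum(s1, s2, normalized=cfg.normalized_spectrum)
    if cfg.method == "improved" and cfg.upsample.search_mode == "bidirectional":
        fine = bidirectional_search(p_fine, center, cfg.upsample)
    else:
        fine = full_window_argmax(p_fine, center, cfg.upsample)

    shift = ShiftVector(
        center.dy + fine.offset_pixels[0], center.dx + fine.offset_pixels[1]
    )
    diagnostics.update(
        peak_value=fine.peak_value,
        evaluations=fine.evaluations,
        window_size=fine.window_size,
        used_fallback=fine.used_fallback,
    )
    return RegistrationResult(
        shift=shift, coarse=coarse, fine=fine, method=cfg.method, diagnostics=diagnostics
    )


def _phase_ramp_1d(extent: int, delta: float) -> np.ndarray:
    """``exp(-2j*pi*u'*delta/extent)`` with a real (cosine) Nyquist bin.

    A naive ramp assigns the unpaired Nyquist frequency of an even-length
    axis to one sign only, which makes the shifted spectrum non-Hermitian
    and leaks a genuine imaginary component for fractional shifts of
    full-band images.  Splitting the Nyquist bin symmetrically replaces
    its factor by ``cos(pi*delta)``, keeping the output exactly real
    (and identical to ``numpy.roll`` at integer shifts).
    """
    ramp = np.exp((-2j * np.pi / extent) * signed_frequencies(extent) * delta)
    if extent % 2 == 0:
        ramp[extent // 2] = np.cos(np.pi * delta)
    return ramp


def apply_shift(image, shift: ShiftVector) -> ImageGrid:
    """Translate an image by ``shift`` via the Fourier shift theorem.

    Circular (periodic) boundary semantics; at integer shifts this equals
    ``numpy.roll``.  The imaginary residue of the inverse transform is
    asserted negligible and discarded.
    """
    arr = as_pixels(image)
    spec = np.fft.fft2(arr)
    ramp = np.outer(_phase_ramp_1d(arr.shape[0], shift.dy),
                    _phase_ramp_1d(arr.shape[1], shift.dx))
    shifted = np.fft.ifft2(spec * ramp)
    scale = max(1.0, float(np.abs(shifted.real).max()))
    if float(np.abs(shifted.imag).max()) > 1e-8 * scale:
        raise ValueError("unexpected imaginary residue after Fourier shift")
    return ImageGrid(shifted.real)


@dataclass(frozen=True)
class ShiftError:
    """Per-axis absolute error and Euclidean error, in pixels."""

    dy: float
    dx: float
    euclidean: float


def shift_error(estimate: ShiftVector, truth: ShiftVector) -> ShiftError:
    ey = abs(estimate.dy - truth.dy)
    ex = abs(estimate.dx - truth.dx)
    return ShiftError(dy=ey, dx=ex, euclidean=math.hypot(ey, ex))
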