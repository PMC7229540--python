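"""Spectral primitives for translation registration by phase correlation.

The whole package rests on one set of conventions, fixed here once:

* Images are real ``M1 x M2`` rasters indexed ``(row, column)``, 0-based.
* A shift ``d = (dy, dx)`` moves content *down and right* with periodic
  (circular) boundaries::

      shifted(r, c) = reference((r - dy) mod M1, (c - dx) mod M2)

* The forward transform is the unnormalized 2-D DFT (``numpy.fft.fft2``);
  the inverse carries the ``1/(M1*M2)`` factor.  Frequencies stay in
  standard machine order (no centering shift).
* The cross-power spectrum of ``(f1, f2)`` is ``F1 * conj(F2)``.  When
  ``f2`` equals ``f1`` shifted by an integer ``d`` this is the pure phase
  ramp ``exp(+2j*pi*(u*dy/M1 + v*dx/M2))``, and the correlation surface
  has its unit peak at index ``(dy mod M1, dx mod M2)``.  Consequently the
  surface is evaluated with the ``exp(-2j*pi*...)`` kernel, i.e. as
  ``fft2(P).real / (M1*M2)``.
* Peak indices are converted to signed shifts by :func:`wrap_shift`, with
  the boundary index ``M/2`` assigned to the positive side.

Everything downstream (the decimated coarse locator, the matrix-product
upsampled window, the synthetic generator) reuses these conventions; they
are property-tested against brute-force DFT and correlation oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShiftVector",
    "ImageGrid",
    "Spectrum",
    "CrossSpectrum",
    "CorrelationSurface",
    "PeakLocation",
    "forward_spectrum",
    "cross_power_spectrum",
    "correlation_surface",
    "locate_integer_peak",
    "wrap_shift",
    "wrap_to_signed",
    "signed_frequencies",
]

#: Relative magnitude below which normalized cross-spectrum entries are
#: zeroed instead of divided (the normalization is undefined at spectral
#: zeros; band-limited images have exact zeros outside their band).
DEFAULT_FLOOR_RELATIVE = 1e-12


@dataclass(frozen=True)
class ShiftVector:
    """A translation ``(dy, dx)`` in pixels, row axis first.

    The sign sense is fixed by the package convention:
    ``shifted(r, c) = reference((r - dy) mod M1, (c - dx) mod M2)`` —
    i.e. a positive ``dy`` moves the image down, a positive ``dx`` right.
    """

    dy: float
    dx: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dy) and np.isfinite(self.dx)):
            raise ValueError(f"shift components must be finite, got ({self.dy}, {self.dx})")

    def __neg__(self) -> "ShiftVector":
        return ShiftVector(-self.dy, -self.dx)

    def __add__(self, other: "ShiftVector") -> "ShiftVector":
        return ShiftVector(self.dy + other.dy, self.dx + other.dx)

    def __sub__(self, other: "ShiftVector") -> "ShiftVector":
        return ShiftVector(self.dy - other.dy, self.dx - other.dx)

    def as_tuple(self) -> tuple[float, float]:
        return (self.dy, self.dx)


def _validated_pixels(pixels, *, require_structure: bool) -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got ndim={arr.ndim}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(arr))[0])
        raise ValueError(f"non-finite pixel value at index {idx}")
    if require_structure and arr.min() == arr.max():
        raise ValueError(
            "constant image: all pixel values are equal; a constant image "
            "has no registrable structure"
        )
    return arr


@dataclass(frozen=True, eq=False)
class ImageGrid:
    """A real-valued intensity raster (``M1`` rows x ``M2`` columns).

    Rejects constant images on construction: phase correlation of a
    structureless image is undefined (its spectrum is a lone DC spike).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = _validated_pixels(self.pixels, require_structure=True)
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(image) -> np.ndarray:
    """Coerce an :class:`ImageGrid` or array-like to a validated 2-D float array."""
    if isinstance(image, ImageGrid):
        return image.pixels
    return _validated_pixels(image, require_structure=False)


@dataclass(frozen=True, eq=False)
class Spectrum:
    """Unnormalized forward 2-D DFT of an image, frequencies in machine order."""

    coefficients: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.coefficients.shape


@dataclass(frozen=True, eq=False)
class CrossSpectrum:
    """``F1 * conj(F2)``, optionally normalized to unit magnitude per entry.

    When ``normalized`` is set, entries whose raw magnitude was at or below
    ``magnitude_floor`` are exactly 0 (the phase there is meaningless).
    """

    values: np.ndarray
    normalized: bool
    magnitude_floor: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True, eq=False)
class CorrelationSurface:
    """Real correlation surface obtained by inverting a cross spectrum."""

    values: np.ndarray
    source_shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source_shape is None:
            object.__setattr__(self, "source_shape", self.values.shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PeakLocation:
    """Located surface maximum: wrapped signed shift, value, uniqueness."""

    shift: ShiftVector
    value: float
    is_unique: bool
    index: tuple[int, int]


def forward_spectrum(image) -> Spectrum:
    """Unnormalized forward 2-D DFT of a real raster.

    The DC coefficient equals the pixel sum; a round trip through
    ``ifft2`` reproduces the pixels to machine precision.
    """
    arr = as_pixels(image)
    return Spectrum(np.fft.fft2(arr))


def cross_power_spectrum(
    s1: Spectrum,
    s2: Spectrum,
    normalized: bool = True,
    magnitude_floor: float | None = None,
) -> CrossSpectrum:
    """Entrywise ``F1 * conj(F2)``, optionally phase-normalized.

    Parameters
    ----------
    normalized
        Divide each entry by its magnitude, leaving a pure phase ramp for
        an exact circular shift.  Entries with magnitude at or below the
        floor are set to 0 instead of dividing.
    magnitude_floor
        Absolute magnitude threshold.  ``None`` resolves to
        ``1e-12 * max |F1 F2*|``.
    """
    if s1.shape != s2.shape:
        raise ValueError(f"spectrum shapes differ: {s1.shape} vs {s2.shape}")
    raw = s1.coefficients * np.conj(s2.coefficients)
    if not normalized:
        return CrossSpectrum(raw, normalized=False, magnitude_floor=0.0)
    mag = np.abs(raw)
    if magnitude_floor is None:
        magnitude_floor = DEFAULT_FLOOR_RELATIVE * float(mag.max())
    keep = mag > magnitude_floor
    out = np.zeros_like(raw)
    np.divide(raw, mag, out=out, where=keep)
    return CrossSpectrum(out, normalized=True, magnitude_floor=float(magnitude_floor))


def correlation_surface(p: CrossSpectrum) -> CorrelationSurface:
    """Invert a cross spectrum to the real circular correlation surface.

    Evaluates ``(1/(M1*M2)) * sum_uv P(u,v) exp(-2j*pi*(u*y/M1 + v*x/M2))``
    so that the phase ramp of a shift ``(dy, dx)`` produces a unit peak at
    index ``(dy mod M1, dx mod M2)``.  The imaginary residue (zero for the
    Hermitian spectra of real images) is asserted small and discarded.
    """
    vals = np.asarray(p.values)
    if not np.all(np.isfinite(vals)):
        raise ValueError("cross spectrum contains non-finite values")
    m1, m2 = vals.shape
    inv = np.fft.fft2(vals) / (m1 * m2)
    scale = max(1.0, float(np.abs(inv.real).max()))
    residue = float(np.abs(inv.imag).max())
    if residue > 1e-8 * scale:
        raise ValueError(
            f"imaginary residue {residue:.3e} exceeds 1e-8 relative; "
            "input spectrum is not Hermitian (non-real source images?)"
        )
    return CorrelationSurface(inv.real, source_shape=(m1, m2))


def wrap_shift(index: int, extent: int) -> int:
    """Convert a peak index in ``[0, extent)`` to a signed shift.

    Indices up to ``extent/2`` inclusive map to themselves (the boundary
    is assigned to the positive side); larger indices wrap negative.
    """
    index = int(index)
    if not 0 <= index < extent:
        raise ValueError(f"index {index} out of range [0, {extent})")
    return index if 2 * index <= extent else index - extent


def wrap_to_signed(value: float, extent: int) -> float:
    """Wrap any lag into the signed interval ``(-extent/2, extent/2]``."""
    w = value % extent
    return w if 2 * w <= extent else w - extent


def locate_integer_peak(surface: CorrelationSurface) -> PeakLocation:
    """Argmax of a correlation surface, as a wrapped signed shift.

    Ties are broken deterministically toward the smallest row-major index;
    ``is_unique`` reports whether the maximum was attained exactly once.
    """
    vals = np.asarray(surface.values)
    if vals.size == 0:
        raise ValueError("empty surface")
    if not np.all(np.isfinite(vals)):
        raise ValueError("surface contains non-finite values")
    flat = int(np.argmax(vals))
    r, c = np.unravel_index(flat, vals.shape)
    peak = float(vals[r, c])
    unique = int(np.count_nonzero(vals == peak)) == 1
    shift = ShiftVector(
        float(wrap_shift(int(r), vals.shape[0])),
        float(wrap_shift(int(c), vals.shape[1])),
    )
    return PeakLocation(shift=shift, value=peak, is_unique=unique, index=(int(r), int(c)))


def signed_frequencies(extent: int) -> np.ndarray:
    """Signed DFT frequency of each machine-order index (fftfreq convention).

    For even ``extent`` the Nyquist bin maps to ``-extent/2``; this is the
    convention under which the matrix-product upsampled window coincides
    exactly with the centered zero-padding oracle.
    """
    u = np.arange(extent)
    return np.where(u < (extent + 1) // 2, u, u - extent)
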