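"""Pixel-level coarse localization from the decimated cross-power spectrum.

Keeping only every ``K``-th sample of the *normalized* cross-power
spectrum and inverting the small ``(M1/K1) x (M2/K2)`` matrix yields the
sum of the ``K1*K2`` aliased periodic replicas of the full phase-correlation
surface (period ``M/K`` per axis).  Because the normalized surface is a
single narrow peak, the aliased sum still peaks at the true shift taken
modulo ``M/K`` — so a ``32 x 32`` inverse transform locates the pixel-level
shift of arbitrarily large images, at ``1/(K1*K2)`` of the full cost.

The price is ambiguity: a decimated peak at ``p`` is consistent with any
true shift ``p + j*M/K``.  The decimated surface alone cannot distinguish
the aliases (they fold onto the same sample), so every ``K > 1`` estimate
is reported ``ambiguous`` together with its wrapped alias candidates, and
:func:`disambiguate_candidates` resolves them by evaluating the
full-resolution correlation directly at each candidate lag (a handful of
single-point exponential sums — no full inverse FFT).

:func:`coarse_shift_baseline` is the classic non-decimated first stage:
the cross spectrum embedded centered in a ``2*M1 x 2*M2`` zero matrix and
inverted, giving a half-pixel-resolution global estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    CrossSpectrum,
    PeakLocation,
    ShiftVector,
    Spectrum,
    correlation_surface,
    cross_power_spectrum,
    locate_integer_peak,
    signed_frequencies,
    wrap_shift,
    wrap_to_signed,
    CorrelationSurface,
)
from .fine import upsampled_value

__all__ = [
    "DownsampleConfig",
    "CoarseEstimate",
    "decimate_cross_spectrum",
    "coarse_shift_decimated",
    "disambiguate_candidates",
    "coarse_shift_baseline",
]


def _divisors(n: int) -> list[int]:
    return [k for k in range(1, n + 1) if n % k == 0]


@dataclass(frozen=True)
class DownsampleConfig:
    """Spectral decimation factors ``(K1, K2)`` for the coarse stage."""

    k1: int
    k2: int

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1:
            raise ValueError("decimation factors must be positive integers")

    @classmethod
    def auto(cls, shape: tuple[int, int]) -> "DownsampleConfig":
        """The ``K = M/32`` rule with a deterministic fallback.

        Per axis: ``K = M // 32`` when ``M >= 64`` and ``32 | M``;
        otherwise the largest divisor of ``M`` keeping the decimated
        extent at least 32 (``K = 1`` when ``M < 32``).
        """
        factors = []
        for m in shape:
            if m >= 64 and m % 32 == 0:
                factors.append(m // 32)
            else:
                eligible = [k for k in _divisors(m) if m // k >= 32]
                factors.append(max(eligible) if eligible else 1)
        return cls(*factors)

    def validate_for(self, shape: tuple[int, int]) -> None:
        for m, k, axis in ((shape[0], self.k1, "rows"), (shape[1], self.k2, "columns")):
            if m % k != 0:
                divs = _divisors(m)
                nearest = min(divs, key=lambda d: (abs(d - k), d))
                raise ValueError(
                    f"decimation factor {k} does not divide the {axis} extent {m}; "
                    f"nearest divisor is {nearest}"
                )
            if m // k < 4:
                raise ValueError(
                    f"decimated {axis} extent {m // k} < 4 (K={k} too aggressive for M={m})"
                )


@dataclass(frozen=True)
class CoarseEstimate:
    """Pixel-level shift estimate with validity/ambiguity diagnostics.

    ``valid`` means the peak was unique and fell strictly inside the
    aliasing-safe bound ``|d| < M/(2K) - 1``; ``ambiguous`` means aliased
    alternatives exist (``candidates`` lists them, wrapped into
    ``(-M/2, M/2]``, in row-major order of their wrapped indices).
    """

    shift: ShiftVector
    valid: bool
    ambiguous: bool
    candidates: tuple[ShiftVector, ...]
    peak_value: float
    unique_peak: bool = True
    tie: bool = False
    surface_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.ambiguous and not self.candidates:
            raise ValueError("ambiguous estimate must carry candidates")
        if self.candidates and not self.ambiguous:
            raise ValueError("candidates present but estimate not marked ambiguous")


def decimate_cross_spectrum(p: CrossSpectrum, cfg: DownsampleConfig) -> CrossSpectrum:
    """Keep entries ``(K1*m, K2*n)`` of a *normalized* cross spectrum.

    Decimating an unnormalized spectrum is refused: its correlation
    surface has broad support, so the aliased replicas overlap and can
    displace the peak.  Normalization first collapses the surface to a
    near-delta, making the overlap harmless.
    """
    if not p.normalized:
        raise ValueError(
            "refusing to decimate an unnormalized cross spectrum: the aliased "
            "replicas of its broad correlation surface overlap and can move the "
            "peak; normalize the cross spectrum first"
        )
    cfg.validate_for(p.shape)
    return CrossSpectrum(
        p.values[:: cfg.k1, :: cfg.k2],
        normalized=True,
        magnitude_floor=p.magnitude_floor,
    )


def coarse_shift_decimated(
    s1: Spectrum,
    s2: Spectrum,
    cfg: DownsampleConfig,
    magnitude_floor: float | None = None,
) -> CoarseEstimate:
    """Locate the wrapped peak of the decimated phase-correlation surface.

    The returned ``shift`` lies in ``(-M/(2K), M/(2K)]`` per axis; for
    ``K > 1`` the estimate is marked ambiguous with its alias candidates
    (resolve with :func:`disambiguate_candidates`, or trust the bound if
    the physical shift is known to satisfy ``|d| < M/(2K) - 1``).
    """
    if s1.shape != s2.shape:
        raise ValueError(f"spectrum shapes differ: {s1.shape} vs {s2.shape}")
    m1, m2 = s1.shape
    cfg.validate_for((m1, m2))
    p = cross_power_spectrum(s1, s2, normalized=True, magnitude_floor=magnitude_floor)
    pd = decimate_cross_spectrum(p, cfg)
    surface = correlation_surface(pd)
    peak = locate_integer_peak(surface)

    n1, n2 = m1 // cfg.k1, m2 // cfg.k2
    dy, dx = peak.shift.dy, peak.shift.dx
    valid = (
        peak.is_unique
        and abs(dy) < m1 / (2 * cfg.k1) - 1
        and abs(dx) < m2 / (2 * cfg.k2) - 1
    )

    ambiguous = cfg.k1 * cfg.k2 > 1 or not peak.is_unique
    candidates: tuple[ShiftVector, ...] = ()
    if ambiguous:
        cands = {
            (wrap_to_signed(dy + jy * n1, m1), wrap_to_signed(dx + jx * n2, m2))
            for jy in range(cfg.k1)
            for jx in range(cfg.k2)
        }
        # deterministic row-major order of the wrapped indices
        ordered = sorted(cands, key=lambda c: (c[0] % m1, c[1] % m2))
        max_candidates = 2 * cfg.k1 * cfg.k2
        candidates = tuple(ShiftVector(*c) for c in ordered[:max_candidates])

    return CoarseEstimate(
        shift=peak.shift,
        valid=valid,
        ambiguous=ambiguous,
        candidates=candidates,
        peak_value=peak.value,
        unique_peak=peak.is_unique,
        surface_shape=surface.shape,
    )


def disambiguate_candidates(
    s1: Spectrum, s2: Spectrum, est: CoarseEstimate
) -> CoarseEstimate:
    """Pick among aliased candidates by direct full-resolution correlation.

    Evaluates the *unnormalized* circular cross-correlation at each
    candidate lag by a single-point exponential-weighted sum and keeps the
    candidate with the largest real value.  Near-ties (within 1e-9
    relative) are broken toward the smallest row-major wrapped index and
    flagged on the result.
    """
    if not est.candidates:
        raise ValueError("estimate carries no candidates to disambiguate")
    if len(est.candidates) == 1:
        only = est.candidates[0]
        return replace(
            est, shift=only, valid=True, ambiguous=False, candidates=(), tie=False
        )
    p = cross_power_spectrum(s1, s2, normalized=False)
    values = np.array(
        [upsampled_value(p, c.dy, c.dx).real for c in est.candidates]
    )
    best = int(np.argmax(values))
    tol = 1e-9 * max(1.0, float(np.abs(values).max()))
    near = np.flatnonzero(values >= values[best] - tol)
    # candidates are already in row-major order, so the first near-tie wins
    chosen = int(near[0])
    return replace(
        est,
        shift=est.candidates[chosen],
        valid=True,
        ambiguous=False,
        candidates=(),
        peak_value=float(values[chosen]),
        tie=bool(near.size > 1),
    )


def _zeropad_surface(values: np.ndarray, factor: int) -> np.ndarray:
    """Upsampled correlation surface via centered spectral zero-padding.

    Embeds each signed frequency ``(u', v')`` of the cross spectrum at the
    same signed frequency of a ``factor*M1 x factor*M2`` grid and inverts
    (unnormalized ``fft2`` kernel, scaled by ``1/(M1*M2)``); output index
    ``j`` is the lag ``j/factor`` wrapped.
    """
    m1, m2 = values.shape
    n1, n2 = factor * m1, factor * m2
    rows = signed_frequencies(m1) % n1
    cols = signed_frequencies(m2) % n2
    q = np.zeros((n1, n2), dtype=complex)
    q[np.ix_(rows, cols)] = values
    return np.fft.fft2(q).real / (m1 * m2)


def coarse_shift_baseline(
    s1: Spectrum,
    s2: Spectrum,
    normalized: bool = True,
    magnitude_floor: float | None = None,
) -> CoarseEstimate:
    """Global half-pixel first stage (upsampling factor 2 by zero-padding)."""
    if s1.shape != s2.shape:
        raise ValueError(f"spectrum shapes differ: {s1.shape} vs {s2.shape}")
    m1, m2 = s1.shape
    p = cross_power_spectrum(s1, s2, normalized=normalized, magnitude_floor=magnitude_floor)
    surface = _zeropad_surface(p.values, 2)
    peak = locate_integer_peak(CorrelationSurface(surface, source_shape=(m1, m2)))
    shift = ShiftVector(peak.shift.dy / 2.0, peak.shift.dx / 2.0)
    return CoarseEstimate(
        shift=shift,
        valid=peak.is_unique,
        ambiguous=False,
        candidates=(),
        peak_value=peak.value,
        unique_peak=peak.is_unique,
        surface_shape=surface.shape,
    )
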