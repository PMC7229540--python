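# Methods

## Model and assumptions

`subshift` estimates a single global translation between two real-valued
rasters under a *circular* (periodic) image model: the moving image is
assumed to satisfy `f₂(r, c) = f₁((r − dy) mod M₁, (c − dx) mod M₂)` up
to noise.  Everything follows from the Fourier shift theorem under that
model.  Real scanner images are not periodic; for modest shifts the
wrap-around content acts as structured noise that the normalized
cross-power spectrum suppresses well, but the method is *not* suited to
pairs with large non-overlapping regions, rotation, scaling, or strong
local deformation.  Multimodal gray-value relationships are tolerated
only insofar as phase correlation is insensitive to global intensity
scaling; genuinely nonlinear intensity mappings degrade the peak.

### Conventions (fixed once, tested everywhere)

* 0-based `(row, column)` indexing; shifts are `(dy, dx)`, rows first,
  with **moving = reference translated by +d**.
* Forward DFT unnormalized, inverse carries `1/(M₁M₂)`, machine
  frequency order.  The cross spectrum is `F₁F₂*`; its surface is
  evaluated with the `exp(−i2π·u·d/M)` kernel so an integer shift
  `(dy, dx)` peaks at index `(dy mod M₁, dx mod M₂)`.
* Peak indices wrap to signed shifts with the boundary `M/2` assigned
  positive; spectral *exponents* use the fftfreq convention (Nyquist at
  `−M/2`), which is what makes the matrix-product window agree with the
  centered zero-padding oracle to 1e−8.
* Ties in any argmax break toward the smallest row-major index.
* Inverse transforms of Hermitian spectra assert an imaginary residue
  below 1e−8 relative before discarding it.

## Coarse stage: decimated phase correlation

The inverse transform of the K-decimated normalized cross spectrum
equals the sum of the `K₁K₂` aliased replicas (period `M/K` per axis) of
the full phase-correlation surface — an identity checked against a
brute-force fold in the tests.  Since normalization collapses the
surface to a near-delta, the replicas barely interact and the decimated
peak sits at the true shift modulo `M/K`.  Decimating an *unnormalized*
spectrum is refused outright: its broad correlation surface genuinely
overlaps under aliasing and can move the peak.

A decimated peak at `p` cannot be distinguished from `p + j·M/K` using
the small surface alone, so every `K > 1` estimate carries its wrapped
alias candidates and is resolved by evaluating the full-resolution
unnormalized correlation at each candidate directly (single-point
exponential sums; `K₁K₂` of them, never a full inverse FFT).  This keeps
the stage correct for arbitrarily large shifts, not only those inside
the aliasing-safe bound `|d| < M/(2K) − 1` reported via `valid`.

Defaults: `K = M/32` per axis when `32 | M` and `M ≥ 64`, otherwise the
largest divisor keeping the decimated extent ≥ 32 — so the coarse
inverse transform is a 32×32 matrix regardless of image size whenever
the `M/32` rule applies; the decimated extent must stay ≥ 4.  The decimated surface size is recorded in the estimate and
asserted in tests — the structural counterpart of the `1/(K₁K₂)` cost
claim, deliberately not a wall-clock assertion.

The baseline coarse stage (for the reference two-step method) embeds the
cross spectrum centered in a `2M₁×2M₂` zero matrix and inverts — a
global half-pixel estimate, rounded half-up to the integer window
center.

## Fine stage: single-step DFT window

Window sample `(r, c)` evaluates lag
`(center + (r − ⌊W/2⌋)/ε, center + (c − ⌊W/2⌋)/ε)`, `W = ceil(1.5ε)`:
integer upsampled-grid offsets spanning ±0.75 px around the coarse
center, which covers the ≤ 0.5 px residual of any pixel-accurate coarse
stage with margin.  Entries are computed as `A·P·C` with the `D = P·C`
product cached, so requesting a row costs one vector–matrix product;
rows are full-width, hence the in-row column argmax is free.  Every
entry is proven (in tests, to 1e−8 relative) equal to the corresponding
sample of the `ε`-factor zero-padded inverse FFT — the two routes are
kept strictly separate: the package never computes the global zero-pad
except in the factor-2 baseline coarse stage.

The bidirectional search probes rows `⌊W/2⌋ ± kσ`, `σ = max(1,
round(0.3ε))`, outward until the row maximum (of the real part)
decreases on each side or the edge is reached, then evaluates all rows
within `±σ` of the best probe.  If the probe profile is not strictly
unimodal (including any exact tie, e.g. a degenerate flat window) the
search falls back to full evaluation and flags it.  On a unimodal
row-maximum profile the bracket provably contains the global best row,
so the result equals the full-window argmax; the fallback keeps the
equality on pathological windows at full cost.  The peak criterion is
the maximum real part (inputs are real images).

`ε` is a positive integer and the final estimate is quantized to `1/ε`
px: the expected |error| for a uniformly distributed fractional shift is
`1/(4ε)` and the worst case `1/(2ε)` — at `ε = 100` that is 0.0025 mean
/ 0.005 max, comfortably inside a 0.01 px budget.  Claims of accuracy
finer than `1/ε` at a given `ε` are not attainable on this grid and are
not made.

## Synthetic data

Phantoms are seeded Gaussian random fields hard-cut to a radial band
(`smoothness` = retained fraction of Nyquist, default 0.25) and affinely
rescaled to [0, 1].  Strict band-limitation makes the Fourier-domain
ground-truth shift *exact* (round-trip residual < 1e−8), so benchmark
errors are attributable entirely to the estimator.  What the phantoms do
not emulate: anatomical structure, cross-modality intensity mappings,
non-periodic borders, and detector noise correlations — so passing
benchmarks demonstrate estimator correctness under the circular model,
not clinical-image performance.  Additive Gaussian noise (σ as a
fraction of dynamic range) is applied to the moving image only; an
optional crop-margin mode trims borders for non-circular realism at the
cost of exact ground truth.  The Fourier warp used by the generator
symmetrizes the Nyquist bin (cosine factor) so that shifting any real
image — band-limited or not — returns an exactly real raster.

The benchmark harness draws its case list (phantom seed, shifts uniform
per axis in ±`shift_range`, noise seeds) purely from the suite seed,
independent of the registration configuration, so different methods are
compared on identical inputs; the default accuracy protocol uses one
256×256 phantom, 20 cases, shifts within ±10 px, noiseless — sizes kept
deliberately moderate so the full suite reruns in well under a minute
per method at `ε = 100`.

## Numerical choices

* Normalization floor: entries of `F₁F₂*` with magnitude ≤ 1e−12 × the
  maximum magnitude are set to 0 instead of divided (band-limited images
  have exact spectral zeros; their phase is meaningless noise).
* Disambiguation near-ties (within 1e−9 relative) resolve to the
  smallest row-major wrapped index and are flagged — relevant only for
  pathologically periodic images where the aliases are mathematically
  equivalent.
* The baseline's half-pixel coarse estimate rounds half-up
  (`⌊x + 0.5⌋`) to an integer center; the 1.5 px window absorbs the
  residual either way.
* Constant images are rejected at construction: phase correlation of a
  structureless raster is undefined.

## Known limitations

* Translation only — no rotation, scale, shear, or local deformation.
* The circular model means content shifted off one edge re-enters at the
  other; for real (non-periodic) pairs with shifts beyond a few percent
  of the frame, accuracy degrades and the crop-margin benchmark mode is
  the honest way to measure it.
* The alias disambiguation assumes the global correlation maximum is
  unique; for strictly periodic images every alias is equivalent and the
  reported (flagged) choice is a convention.
* 3-D volumes and DICOM/NIfTI I/O are out of scope; register slice-wise
  after conversion to TIFF/PNG.
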