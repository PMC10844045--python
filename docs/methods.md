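# Methods

## Model

A pixel illuminated by sinusoidally modulated excitation at frequency
*f* (angular frequency ω = 2π·*f*) and emitting with a single-exponential
decay of lifetime τ responds with

- a phase lag φ = arctan(ωτ),
- a modulation index M = 1/√(1 + (ωτ)²), measured as (b/a)/(B/A) from the
  emission (b, a) and excitation (B, A) amplitude/offset pairs.

Inverting these gives the two per-pixel lifetime estimates τ_PH = tan(φ)/ω
and τ_M = √(1/M² − 1)/ω. Both inversions are exact only for
single-exponential emitters; for mixed pixels τ_PH ≤ τ_M, which the test
suite asserts on synthetic mixtures via the summed-phasor representation.
The library works in ns throughout and stores *f* (ordinary frequency, Hz)
in configuration; ω never appears in metadata.

Non-physical pixels — φ outside [0, π/2), M outside (0, 1], zero
intensity — carry NaN as an explicit invalid sentinel. Every statistic in
the package drops NaN pixels; nothing is silently clipped.

## Classification pipeline

Given a 5-layer stack and a set of material windows:

1. **Intensity gate.** Pixels with intensity ≥ 10 % of the frame maximum
   are foreground; the boundary case (exactly 10 %) is foreground. The
   gated lifetime image is the basis for everything downstream.
2. **Window extraction.** A material window is μ ± kσ (default k = 3) from
   a single-material calibration fit; membership is tested on the closed
   interval. Windows may overlap — each material is extracted
   independently, and the result reports the count of pixels claimed by
   more than one material.
3. **Morphological cleanup.** Erosion (3 × 3 rectangle) → dilation (disk,
   r = 2) → closing (disk, r = 2) → erosion (3 × 3 rectangle). The first
   erosion removes lone false-positive pixels, dilation/closing restore
   in-body pixels whose lifetime fell outside the window (≈ 0.3 % of a
   Gaussian population lies beyond 3σ), and the final erosion smooths
   edges. Outside-image pixels are background everywhere, so objects
   shrink at the frame border. The element sizes are configurable and are
   recorded in every result; the defaults were chosen once as the smallest
   elements that remove single-pixel noise yet preserve a 25 × 35 px chip's
   bounding box.
4. **Reporting.** Relative share = cleaned-mask pixels / full frame pixel
   count × 100 (always the full frame, never the foreground count).
   Lifetime statistics are computed on the gated lifetime image under the
   cleaned mask (a pre-cleanup option exists; post-cleanup is the default
   because cleanup re-includes the tails that window extraction truncates,
   making the moment estimates unbiased for Gaussian populations).
   Particles are 8-connected components (4-connected optional); sizes are
   bounding-box extents times the projected pixel size, 5.6 µm of sensor
   pixel divided by the magnification (0.28 / 0.56 / 2.8 µm at
   20× / 10× / 2×).

"Gaussian analysis" of a lifetime population means moment estimation: the
sample mean and sample standard deviation (ddof = 1) of the valid pixels.
This is bin-width independent and coincides with a least-squares Gaussian
histogram fit for normal data; the curve-fit variant is available as
`gaussian_fit(..., method="curve_fit")` for comparison. The histogram
utility defaults to 0.05 ns bins (configurable); bins are aligned to
multiples of the bin width.

## Spectral pre-analysis

Replicate emission spectra (typically five) are background-subtracted
(clamped at zero — negative differences are measurement noise), averaged,
and resampled at 0.01 nm. Interpolation is piecewise linear by default:
it is monotone and cannot invent maxima; a cubic option exists for smooth
spectra. Peaks are local maxima with prominence ≥ 5 % of the global
maximum — enough to resolve the 691/719/741 nm chlorophyll triplet while
ignoring noise. Stokes shifts are reported against the 488 nm excitation
line; anti-Stokes emission is out of scope and rejected. Filters are ideal
boxcars (LP: transmit ≥ cut-on; BP: transmit on [cut-on, cut-off]); real
transmission curves are not modelled.

## Synthetic scenes

The generator emulates the acquisition, not the optics: per foreground
pixel τ ~ Normal(μ, σ) truncated at 0, raw φ/M layers computed exactly
from the drawn τ (so re-deriving lifetimes from the raw layers is an
identity), and multiplicative Gaussian intensity noise (CV 10 % by
default). Material defaults are the per-filter calibration values (BP:
HDPE 3.52 ± 0.21 ns, spruce 1.40 ± 0.12 ns; LP: grass 1.15 ± 0.08,
HDPE 1.68 ± 0.07, spruce 1.54 ± 0.07). Soil background is uniform
intensity in [0, 8 %] of the brightest material's mean with lifetimes
uniform on [0.2, 5] ns — a stand-in engineered so soil behaves as
sub-threshold noise; no quantitative soil statistics back it. Emission
spectra are sums of Gaussian bands (HDPE 528/594 nm, spruce 563 nm, grass
691/719/741 nm with 6 nm widths — narrow enough that overlapping bands
peak at their centres). Scene presets mirror the two multi-material
arrangements: three large abutting regions at 10×, and small chips
(including one at the 25 × 35 px detection limit) on soil at 2×.

What a green simulation test establishes: the pipeline's arithmetic,
segmentation and statistics recover known ground truth under the model's
own assumptions. What it does not establish: robustness to real-sample
effects — spatially correlated soil texture, mixed-pixel edges, biofilms,
dyes and fillers, detector nonlinearity. Accordingly the multi-material
lifetime SDs reported from real samples (≈ 0.5–0.6 ns) are far wider than
single-material calibration σ, and the generator makes no attempt to
reproduce them.

## Numerical choices and edge cases

- Lifetime round trips through φ are exact to better than 1e-9 relative
  everywhere tested; the round trip through M loses precision when
  ωτ ≲ 1e-3 (cancellation in 1/M² − 1 near M = 1), which is outside the
  regime where FD demodulation carries usable information — the property
  tests restrict to ωτ > 1e-3.
- A 35 px width at 2.8 µm/px is 98 µm exactly; instrument-report style
  rounding to 100 µm is noted in the tests but the package never rounds.
- Degenerate calibration populations (σ = 0) cannot define a window and
  are rejected rather than producing a zero-width interval.
- Stacks are written as uncompressed 5-page float32 TIFFs with a
  human-readable `key = value` sidecar declaring units (phase rad/deg,
  lifetimes ns) and layer order; round trips are byte-exact.
- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical stacks and identical classification summaries.

## Known limitations

Single modulation frequency only (no multi-frequency fitting, no phasor
plots); no camera referencing/calibration procedure; ideal filters; no
polymer-type inference beyond lifetime windows; background model is a
stand-in, labelled as such above.
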