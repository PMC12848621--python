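# Methods

## Overview

`mmpolar` implements a transmission Mueller-matrix polarimetry (MMP) analysis
chain for thin tissue sections, together with a synthetic tissue-phantom
generator that provides exact ground truth for every stage.  The chain is

1. **Reconstruction** — per-pixel 4×4 Mueller matrix from 36
   polarization-resolved intensity images,
2. **Normalization and masking** — division by the m11 (total transmittance)
   plane; region-of-interest segmentation on m11,
3. **Polar decomposition** — per-pixel diattenuation D, polarizance P,
   retardance R and depolarization power Δ,
4. **Moment statistics** — population central moments (mean, std, skewness,
   non-excess kurtosis) of parameter maps, aggregated by age group and
   fitted against age.

## Reconstruction model

The instrument model is an ideal polarization-state generator and analyzer
cycling through the six states H, V, P (+45°), M (−45°), R, L.  Detected
intensity for generator state g and analyzer state a is
`I(g,a) = ½ (1, â)·M·(1, ĝ)ᵀ` with `ĝ, â` the polarized parts of the state
Stokes vectors.  Each matrix element is a signed four-term sum of these 36
intensities (e.g. `m11 = HH+HV+VH+VV`, `m44 = RR−RL−LR+LL`); with ideal
states the sums evaluate to exactly `2·m_ij`, and the factor of two cancels
in m11 normalization.  The images are assumed co-registered (single-camera
transmission geometry); no registration stage exists.

Conventions fixed here (the field uses both): right circular polarization is
`s3 = +1`; matrix elements are addressed 1-based (`m11..m44`) in the API and
reports.  Any consistent circular-handedness convention produces identical
reconstructions, because the forward model and the element equations use the
same basis.

Pixels with `m11 ≤ floor·max(m11)` (default floor 1 %) are masked before
division — noise-dominated denominators otherwise produce unbounded
elements.  The ROI rule is deliberately explicit and configurable
(percentile of m11, default 50th, or a fixed fraction of the maximum)
because tissue-pixel selection materially affects image statistics and no
single rule is canonical.

## Polar decomposition

The canonical three-factor product `M = M_Δ·M_R·M_D` (diattenuator applied
first, depolarizer last) is used:

* `D = |(m12, m13, m14)|/m11`; `M_D` built from the diattenuation vector,
  with `m_D = √(1−D²)·I + (1−√(1−D²))·d̂d̂ᵀ`.
* `M′ = M·M_D⁻¹`; the depolarizer block is `m_Δ = ±(m′m′ᵀ)^{1/2}` via a
  symmetric eigendecomposition, the sign that of `det m′`.
* `Δ = 1 − |tr m_Δ|/3` (trace-based depolarization power, range [0, 1]).
* `m_R = m_Δ⁻¹ m′`; `R = arccos(clamp((tr m_R + 1)/2 − 1))`, reported in
  **radians**, range [0, π].
* `P = |(m21, m31, m41)|/m11`.

Numerical choices: eigenvalues of `m′m′ᵀ` are clamped at zero before square
roots (noise produces small negatives; occurrences are counted per image);
when `D ≥ 1−10⁻⁶` (polarizer-like pixel) `M_D` is inverted with the
diattenuation magnitude regularized to `1−10⁻⁶`, the pixel is flagged
`singular_diattenuator`, and the scalars are still returned — image-scale
runs must not crash on specular or polarizer-like pixels.  For mixed-sign
depolarizer diagonals the factorization is not unique (only the magnitudes
and the overall sign of `m_Δ` are determined); recovery tests therefore use
positive diagonals, and the negative-determinant branch is validated through
the reassembly residual instead.  The image path is a batched (vectorized)
implementation; a test pins it pixel-for-pixel to the single-matrix API.

Alternative decompositions (reverse-order, symmetric, differential) and
isotropic-depolarization filtering are out of scope.

## Moment statistics and trend fits

Moments are the population (1/N) forms: `μ = Σx/N`,
`σ = sqrt(Σ(x−μ)²/N)`, `skew = Σ(x−μ)³/(Nσ³)`, `kurt = Σ(x−μ)⁴/(Nσ⁴)`
(non-excess: Gaussian → 3).  They are not sample-corrected (N−1) forms —
fidelity to the printed definitions of the analysis this package
re-implements.  Skewness and kurtosis are reported as undefined (not
numbers) when σ = 0 or N < 3.

Per-sample summaries are grouped by age; group means are simple arithmetic
means across the samples of a group and the across-sample standard
deviation is the error bar.  Group means are fitted against age in days
(no centering; this affects α and the offset but not the sign of β):

* mean and std: ordinary least squares line,
* skewness and kurtosis: `y = α·exp(β·x) + c` by nonlinear least squares.

The exponential carries a third offset parameter because skewness can be
negative and a two-parameter exponential cannot cross zero.  Fits are
unweighted (error bars are reported, not used as weights, by default).
Initialization comes from log-linear regressions of the shifted series in
both orientations plus a near-linear fallback; the lowest-cost solution is
kept and the convergence flag is honest.  The *trend sign* of an
exponential fit is the sign of its derivative, `sign(α·β)` — a saturating
rising curve is legitimately represented with α < 0, β < 0, and reading β
alone would misclassify it.

## The phantom generator

The phantom is a per-pixel **effective-Mueller model**, not a photon-transport
Monte Carlo: the analysis consumes Mueller images, so an effective model
gives exact ground truth for every stage (scattering coefficients μs, μs′
and anisotropy g are consequently not simulated).  Each pixel carries

`M = diag(1, a₁, a₂, c) · M_retarder(δ, θ) · M_diattenuator(D₀)`

with three depolarization **retention channels** `(a₁, a₂, c)` acting on the
two linear and the circular Stokes components.  Scene geometry is an
elliptical tissue footprint (default 0.8 of the half-frame) on a dim
surround, with Poisson-placed plaque disks (union, overlaps allowed; radii
uniform in 1.2–2.4 px) whose expected area fraction follows the age
schedule `f(age) = κ·max(0, age − 45)` — zero before the 45-day deposition
onset, reaching 0.07 at 225 days.  The default cohort is 7 ages
(75–225 days in 25-day steps) × 3 replicates = 21 samples.

Regime encoding (defaults, 632 nm):

| region     | a₁    | a₂    | c     | consequence                         |
|------------|-------|-------|-------|-------------------------------------|
| tissue     | 0.88  | 0.84  | 0.84  | Rayleigh-like: m22 ≈ m33 > m44      |
| plaque     | 0.87  | 0.60  | 0.92  | Mie-like: m44 ≥ m22, m44 > m33      |
| surround   | 0.99  | 0.99  | 0.985 | nearly clear                        |

Plaques raise the circular retention (helicity preservation by enlarged
Mie-like scatterers), leave the first linear channel nearly unchanged (so
m22 mean and std stay flat with age), and strongly depress the second
linear channel, making plaque pixels **more** depolarizing overall
(Δ ≈ 0.19 vs. 0.13 background, both inside the 0–0.2 range typical of thin
brain sections).  A two-channel (linear, circular) parameterization cannot
express this combination — raising the circular retention alone would make
plaques *less* depolarizing — which is why the generator uses per-channel
triples.

Pixel-to-pixel variability has three seeded components:

* a **shared heavy-tailed jitter** on all three retentions (Student-t, ν=3,
  σ=0.0105, clamped at ±6σ): it produces an elevated baseline kurtosis in
  every retention-derived map.  The clamp exactly exhausts the headroom
  between the plaque circular retention and the 0.995 factor ceiling, so
  clipping can never act on one channel alone and the per-pixel m22/m44
  orderings hold at every generated pixel by construction;
* small independent per-channel Gaussian jitters (σ=0.003, clamped ±3σ);
* a **diffuse heterogeneity term** on the second linear channel only:
  Gaussian with variance proportional to the plaque-load schedule, std
  0.03 at 225 days.  It emulates plaque-associated microstructural
  disorder beyond the discrete deposits, broadening the depolarization
  distribution with age without touching the m22 or m44 channels.

Retardance (0.20 rad, axis π/8), diattenuation (0.05 along horizontal) and
transmittance (0.70 tissue / 0.15 surround) carry small Gaussian jitters.
Wavelength enters only as a multiplicative retention scale
(445 nm: 0.94, 532 nm: 0.97, 632 nm: 1.0 — shorter wavelengths scatter
more); cohort geometry is reused across wavelengths by seeding placement
independently of wavelength.  The 36-state measurement is simulated with an
ideal analyzer model, an exposure scale, and seeded additive Gaussian noise
of per-pixel standard deviation signal/SNR (default SNR 50), clipped at
zero.  Shot noise is off by default: the emulated regime is a bright laser
source on a camera, where a single controllable SNR is the useful knob.

### What the generator injects, and why

The statistics layer is meant to recover an age trend structure, so the
generator encodes one explicitly:

* **skewness of Δ and m44 rises with age** — the growing plaque-pixel
  fraction forms a two-component location mixture whose third moment grows
  with the mixing fraction (separations ≈ 2.5–5.5 background σ are inside
  the regime where mixture skewness increases with the fraction);
* **kurtosis of Δ falls with age** — two cooperating mechanisms: the
  growing mixture variance deflates the heavy-tailed baseline kurtosis, and
  the diffuse heterogeneity term Gaussianizes the Δ distribution as it
  broadens;
* **mean and std of m22 stay flat** — plaques barely touch the first linear
  channel (offset 0.01, small against the ≈0.011 map σ).

Component separations, jitter scales and the clamp were chosen by
closed-form mixture-moment analysis and a design-stage Monte Carlo so that
the injected signs are statistically detectable at 64×64 px with 21
samples; they are configurable, and none of them is claimed to be a
measured tissue property.  Problem sizes used by the shipped checks —
256×256 px for the single full cohort, 64×64 px for the 20-repetition
sign-stability check, 128×128 px for ordering fractions — are the
package's default verification sizes.

### What passing tests do and do not show

The phantom shares with real polarimetric data the measurement operator,
the noise entry point, the mixture character of plaque-bearing maps and the
orderings of the diagonal elements; it does **not** model photon transport,
speckle, instrument miscalibration, registration error, paraffin optics
(a global retention scale is the only hook), or realistic plaque
morphology.  Passing the trend-recovery checks therefore shows that the
*pipeline* recovers structure faithfully from images with known structure —
it is not evidence about real tissue, and no numeric claim from measured
brain data is reproduced here (those raw images are not public).

## Known limitations

* The polar decomposition is order-dependent; only the canonical
  depolarizer-retarder-diattenuator order is implemented.
* Retardance is a scalar (no linear/circular split, no orientation map).
* The 16-measurement reduced scheme is not implemented — only the fully
  determined 36-state scheme.
* Exponential trend fits on 7 group means are weakly identified; β point
  estimates carry large variance (the bootstrap helper quantifies this) and
  only trend signs should be interpreted at that sample size.
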