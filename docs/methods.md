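# Methods

`musfa` quantifies the organisation of muscle tissue in longitudinal B-mode
ultrasound through spatial frequency analysis (SFA) of the speckle/striation
texture, and implements the within-image statistical design used to compare
injured against adjacent healthy muscle after hamstring strain injury. This
note documents the model, the numerical choices, and what the synthetic
study conditions do and do not emulate.

## Spectral pipeline

For a calibrated, isotropically resampled image and a polygonal ROI, the
pipeline:

1. converts the physical kernel size (default **6.5 mm**) to pixels,
   `k = round(kernel_mm / pixel_mm)`;
2. enumerates **every** kernel placement (stride 1 by default, configurable)
   whose `k x k` pixel centers all lie inside the polygon — full containment,
   so tissue outside the drawn region never contaminates a spectrum;
3. zero-pads each kernel into a `pad_n x pad_n` array (default **128**) and
   takes the 2-D FFT magnitude. Frequency resolution is
   `1/(pad_n * pixel_mm)` cycles/mm (0.078125 at 0.1 mm pixels);
4. applies a radially symmetric Butterworth high-pass
   `H(f) = 1/sqrt(1 + (f_c/f)^(2m))` with `H(f_c) = 1/sqrt(2)` (−3 dB)
   exactly and `H(0) = 0` (defaults `f_c = 0.25` cycles/mm, order `m = 2`);
5. locates the maximum filtered magnitude over the non-redundant half-plane
   (positive axial frequencies plus the positive-lateral half of the
   zero-axial row). **PSFR** is the radial distance of that bin from the
   origin in cycles/mm; **Mmax%** is `100 * peak / DC` where DC is the
   unfiltered overall brightness (the plain intensity sum of the kernel);
6. averages PSFR and Mmax% over all kernels with a valid peak.

### Numerical choices

- **Mean subtraction before padding.** Each kernel's mean is removed before
  zero-padding (`subtract_mean=True`). Without it, the rectangular window
  convolves the (huge) DC term into a Dirichlet sidelobe skirt decaying
  roughly as 1/f, which on log-compressed images (mean ≈ 150–190 of 255)
  exceeds realistic band peaks all the way up to ~0.8 cycles/mm; no radial
  high-pass can remove it without also destroying genuine low-frequency
  peaks in disorganised tissue. The DC bin of the returned spectrum still
  carries the true overall brightness, so Mmax% retains its definition and
  its invariance to uniform gain. The flag is exposed for users who want
  the raw convention.
- **No windowing.** Only zero-padding is applied; the high-pass handles
  residual low-frequency leakage of the band component itself.
- **Peak search domain.** Restricted to the half-plane (conjugate symmetry
  would otherwise produce systematic ties) and to radial frequencies at or
  below the Nyquist frequency `1/(2*pixel_mm)`: corner bins of the square
  FFT grid reach `sqrt(2)` times Nyquist but are not physically resolvable
  as a radial frequency. Ties break toward the lower radius, then row-major
  order; an optional `axial_sector_deg` restricts the search to near-axial
  orientations (bands in longitudinal muscle images are near-horizontal).
- **"No peak" kernels** (filtered spectrum identically zero, e.g. constant
  blocks) are excluded from ROI means rather than counted as zero, which
  would bias means toward an arbitrary value; a result with more than 50%
  such kernels is flagged unreliable.
- **Isotropy.** Anisotropic pixels are bilinearly resampled to
  `min(spacing_axial, spacing_lateral)` so a mm-defined kernel is a square
  pixel block and the radial frequency is geometrically meaningful.
- The batched implementation uses a real-input FFT with conjugate-symmetric
  index remapping; it is bit-equivalent to the reference `fft2` path, which
  the tests verify against a direct double-loop DFT oracle.

## Synthetic study conditions

Clinical images are not redistributable, so the generator emulates the
statistical structure the analysis needs:

- **Speckle**: a complex circular-Gaussian scatterer field convolved with a
  separable PSF (Gaussian-modulated cosine axially, Gaussian laterally;
  σ = 0.08 / 0.12 mm, a high-resolution linear array with near-pixel
  speckle cells). The envelope is exactly Rayleigh (fully developed
  speckle), verified by KS tests. Display mapping is
  `255 * (20*log10(env/RMS) + 35) / 60` clipped to [0, 255]; RMS
  normalisation keeps brightness stable across image sizes. A Gaussian
  display-smoothing blur (**0.10 mm**) emulates scan-conversion
  post-processing; it suppresses the high-frequency speckle/noise spectrum
  far above the perimysial band and sets the Mmax% noise floor (~1%).
- **Perimysial banding**: a multiplicative raised-cosine grating,
  `I * (1 + A * g)`, `g in [0, 1]` at frequency `1/band_spacing_mm` —
  hyperechoic bands brighten, never darken. Healthy spacing defaults to
  ~1.1–1.3 mm (PSFR 0.8–0.9 cycles/mm).
- **Focal injury** inside an edema polygon: band amplitude multiplied by an
  attenuation factor, band spacing replaced by a wider one (edema pushing
  fascicle bundles apart — this is how the generator realises a lower
  injured-region PSFR; a single global grating cannot carry two spacings),
  and additive broadband noise (σ = 12 display units by default) emulating
  the elevated noise floor of fluid-filled tissue.
- **Cohorts**: per athlete, true (PSFR, Mmax%) values for the injured and
  adjacent regions are drawn from a bivariate normal around configurable
  group means/SDs (defaults: injured 0.77 (0.24) / adjacent 0.89 (0.25)
  cycles/mm; 1.41 (0.43) / 2.28 (0.50) %; within-athlete correlation
  ρ = 0.5, chosen so the paired-difference spread matches the reported
  confidence intervals rather than the wider independent-draw value). The
  contralateral image has uniform healthy texture with mirrored ROIs — a
  true null. A separate return-to-sport group has its injured-region
  parameters moved toward the adjacent ones by `healed_fraction`
  (default 1.0) with edema noise shrunk proportionally.
- **Calibration**: a cached pilot grid maps band amplitude to measured
  Mmax% (two seeds, 8 amplitudes, per noise condition and per band-spacing
  bin, since the noise power under the peak varies with frequency) and is
  inverted by linear interpolation. Drawing means for Mmax% are
  floor-compensated: the generator cannot realise values below the speckle
  noise floor, so the drawing mean is shifted down until
  `E[max(draw, floor)]` equals the requested group mean. Calibration
  promises approximate group means (±10%), not exact moments.

### What the generator does not emulate

Beamforming, depth-dependent attenuation and focal zones, vendor-specific
post-processing, hematoma geometry, or any distributional features of the
clinical images beyond the published group means/SDs. Passing tests show
the *pipeline* recovers known texture parameters and that the *statistics*
behave correctly under the published effect sizes — not that the phantoms
look like real muscle.

## Statistics

- **Within-image difference**: Healthy − Injured; positive means the
  adjacent tissue has the larger value. The within-image design controls
  for machine-setting differences between acquisitions.
- **Paired t-test** (time-of-injury region comparison, per limb): classical
  two-sided paired t with a 95% CI; Anderson–Darling normality of the
  differences is reported alongside as a warning, never as a gate.
  Zero-variance differences yield a degenerate-flagged result. Athletes
  missing a pair member are excluded listwise per limb and logged.
- **Anderson–Darling**: composite normality (estimated mean/SD) with the
  small-sample correction `A*² = A²(1 + 0.75/n + 2.25/n²)` and the standard
  piecewise-exponential p-value approximation.
- **Wilcoxon rank-sum** (within-image differences, time of injury vs return
  to sport; unpaired — different athlete groups): Mann–Whitney convention
  `W = #{(i,j): x_i > y_j} + ties/2`, range `0..n_x*n_y`. P-values are
  exact via full enumeration of the null distribution (subset-sum dynamic
  programme over ranks) for tie-free samples with `n_x + n_y <= 20`, else
  normal approximation with tie and continuity corrections. The
  **Hodges–Lehmann** shift estimate is the median of all pairwise
  differences; its 95% CI takes the ordered pairwise differences at the
  exact critical index `k = max{k : P(U <= k) <= 0.025}` (normal
  approximation of `k` beyond `n_x*n_y > 400`).
- **Quantiles**: medians [IQR] use linear interpolation (type 7).
- **Minimum detectable change**: `MDC = z * sqrt(2) * SEM` with
  `SEM = SD * sqrt(1 - ICC)`, z = 1.96. Because the underlying reliability
  data live in a separate study, the published thresholds
  (0.19 cycles/mm for PSFR, 0.60% for Mmax%) are also available directly as
  constants for the healed-vs-threshold comparison at return to sport.

The type-I-error property of the paired test is verified on 5,000 null
replicates drawn at the parameter level from the same per-athlete sampler
the image generator consumes — the calibration of a t-test depends on the
distribution of the region values, not on the image renderer — while the
power property (detection of the injured-limb Mmax% deficit in ≥80% of
replicate cohorts) runs through full image rendering and spectral analysis.

## Problem sizes and determinism

Tests and the acceptance script run phantoms of 16 x 16–24 mm at 0.1 mm
pixels with kernel stride 4, and the one-command demo study renders
40 x 56 mm frames (400 x 560 pixels) at stride 2 — sizes chosen so a full
synthetic study completes in about a minute on one CPU while each ROI still
averages tens to thousands of kernels. All randomness flows from explicit
seeds through `numpy.random.default_rng`; identical seeds reproduce
byte-identical images, manifests and reports (CSV floats are written with a
fixed format for this reason).

## Known limitations

- The high-pass cutoff frequency and filter family are configuration
  choices (0.25 cycles/mm, Butterworth order 2); results at very low PSFR
  are sensitive to them, and every report embeds the configuration used.
- Measured Mmax% has a speckle-dependent noise floor; group targets near or
  below it are realised only approximately (see floor compensation above).
- When banding is weak (deep injury, strong edema), the per-kernel peak is
  frequently noise-driven and per-athlete PSFR only partially tracks the
  generator's nominal band spacing; group means remain within the ±10%
  calibration band but per-image PSFR in that regime should be read with
  care — a faithful reflection of the method's behaviour on disorganised
  tissue.
- The cross-sectional design (different groups at the two timepoints) is
  mirrored as-is; no longitudinal modelling is attempted.
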