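# Methods

## nMDP colocalization

Each channel is normalized within the whole-cell ROI by its deviation from
the ROI mean, two-sidedly rescaled so that mean → 0, brightest ROI pixel → 1
and dimmest → −1 (`(I−m)/(M−m)` above the mean, `(I−m)/(m−L)` below). The
nMDP image is the pixelwise product of the two normalized channels over the
ROI; outside-ROI pixels carry no weight in the mean/min/max or any score.

Choices worth making explicit:

- **Scalar score = arithmetic mean of the product over ROI pixels.** A
  per-image reduction is needed to compare cells of different sizes; the mean
  over all ROI pixels is the only reduction consistent with a single score
  per cell that is bounded in [−1, 1], symmetric, and invariant to positive
  affine rescaling of either channel. An alternative (averaging only
  above-threshold pixels) would entangle the score with the masking
  parameters, so it is not offered.
- **Two-sided vs one-sided denominators.** Part of the nMDP literature uses
  the single `M−m` denominator for both branches, in which case the dimmest
  pixel does not generally map to −1. The two-sided form is the default here
  because it realizes the stated landmark mapping exactly; the one-sided
  variant is available via `normalize_channel(..., one_sided=True)` for
  comparison.
- **Degenerate input.** A channel constant on the ROI maps to all zeros
  (score contribution 0, the no-information value) rather than raising.
- **Display convention.** Product +1 → gold RGB (255, 215, 0), −1 → pure
  green (0, 255, 0), 0 → black, linear ramps, rounded to uint8. Pixels
  negative in *both* channels are blacked out for clarity — after the score
  is computed, so rendering never changes the number.

## À-trous wavelet compartment masking

The undecimated à-trous transform smooths repeatedly with the separable
B3-spline kernel (1/16, 1/4, 3/8, 1/4, 1/16), taps dilated by 2^(j−1) at
scale j; detail plane W_j = A_{j−1} − A_j, and the input reconstructs exactly
as ΣW_j + A_J. Boundary handling is mirror reflection by default; a periodic
mode exists and is exactly shift-equivariant.

Masking parameters (all recorded in each `CompartmentMask`):

- **Scales {2, 3}** enter the multiscale product: scale 1 is noise-dominated
  and puncta of σ ≈ 1.5 px concentrate energy at scales 2–3.
- **Hard threshold k = 3** robust sigmas per plane, σ_j = MAD(W_j)/0.67449
  estimated over the ROI when one is supplied (an all-zero plane has σ = 0
  and passes through unchanged).
- **Positive coefficients only.** A pixel joins the mask when its thresholded
  detail coefficient is positive at every selected scale. Bright puncta
  produce positive coefficients; admitting mutually-negative coefficients
  (whose signed product is also positive) would add the dim diffraction ring
  around each spot to the mask — in measurements here that inflated mask area
  roughly 3.6-fold with below-average pixels and biased compartment
  intensities toward the cell mean.
- **ROI edge handling.** Before decomposition, pixels outside the ROI are
  filled with the ROI median. The intensity step at the cell boundary
  otherwise dominates W_2/W_3 and rings the ROI edge with spurious objects
  (object-level F1 at peak SNR 5 was ~0.8 with the raw step and ~1.0 with the
  fill).
- **Cleanup:** objects smaller than 4 px are removed (single-pixel and
  pair survivors of correlated noise).
- Masks are rebuilt independently per frame from that frame's marker image,
  so they track morphology changes (e.g. vacuole swelling); no object
  tracking across frames is attempted.

## Normalized compartment intensity

Each probe frame is divided by its whole-cell ROI mean, recomputed every
frame so bleaching and focal drift cancel; the ROI mean of the normalized
image is exactly 1. The per-frame compartment value is the arithmetic mean
of normalized intensity over mask∩ROI. An empty mask at a frame yields a
missing value (NaN) with a logged warning rather than an exception; cohort
aggregates (mean ± s.e.m., s.e.m. = sd/√n) use only non-missing cells and
report n per point. The 95% CI used for nMDP cohort summaries is the normal
approximation mean ± 1.96·s.e.m.

Percent-change summaries use the mean of all pre-event frames as baseline
and the mean of the last three frames as plateau; the per-frame traces are
the primary output and are never rescaled to the t = 0 value.

Representative-cell selection returns the cell nearest the cohort median of
the chosen metric (ties broken toward the smallest cell id); such a cell
always lies within the 25th–75th percentile band, which the function asserts.

## Cohort statistics

Classical fixed-effects one-way ANOVA (F = MS_between/MS_within, p from the
F upper tail) followed by all-pairs Tukey HSD in the Tukey–Kramer form
(q = |Δmean|/√(MS_w/2·(1/n_i+1/n_j))), adjusted p from the studentized range
distribution with (k, N−k) parameters; with two groups this reduces exactly
to the pooled-variance t-test. The all-identical-values degenerate case
defines F = 0, p = 1. Significance is decided against the cached critical
value of the studentized range (equivalent to p < α); a `p_values=False`
fast path skips the expensive tail integrals in large simulation screens.
Stars: *** p < 0.0001, ** p < 0.01, * p < 0.05.

## Synthetic data generator

The generator emulates a single confocal optical section of one transfected
cell:

- **Cell ROI**: a filled random low-order Fourier blob occupying 20–60% of
  the frame (target fraction 0.35, frame 256×256 by default).
- **Puncta**: isotropic 2-D Gaussians, σ = 1.5 px (diffraction-limited
  endosomes at ~0.1 µm/px), subpixel centers uniform inside the ROI (3σ
  margin from the edge), optional minimum separation for clean object-level
  oracles. Integrated amplitude defaults to 5000 photons with ±30% uniform
  jitter over a 20 photon/px cytosolic background — sparse bright puncta,
  ~18× background at the peak for unit enrichment, 15 puncta per cell by
  default.
- **Channel sharing**: of N spots, round(f·N) carry amplitude in both
  channels of the (0, 1) pair; the rest alternate between the two. Channels
  beyond the pair label every punctum (marker channels).
- **Kinetics**: per-channel enrichment multipliers over frames — constant,
  exponential relaxation after an event frame (the dissociation program,
  default 3.0 → 1.0 with τ = 2.5 frames), or linear drift (the persistence
  program, +5% across the series). Frame-to-minutes mapping is metadata.
- **Noise**: Poisson shot noise on photons, then linear gain, offset
  (100 counts) and Gaussian read noise (2 counts) — the standard PMT
  approximation. Unless set explicitly, gain is chosen so the brightest
  expected pixel sits near ¼ of the uint16 range.

What the generator deliberately does *not* model: realistic PSF shapes and
z-sectioning, vesicle motility, photobleaching, stage drift, cytosolic
texture, and cell-to-cell morphology covariance. Tests passing on this
generator therefore demonstrate the correctness and calibration of the
*analysis* — not that any particular biological dataset would yield a given
cohort mean.

### Scenario calibration

With the default photon budget, the dissociation program (3.0 → 1.0) reads
out as a ≥ 50% drop in normalized compartment intensity and the persistence
program (+5% drift) as a small positive change. The measurable drop depends
on the puncta/background contrast: the compartment mean includes the
cytosolic floor under each punctum, and the whole-cell mean includes the
puncta, both of which compress the dynamic range — hence the bright-sparse
default regime. Traces in the demo config (10 frames) stop before the
exponential has fully relaxed, giving ~40% drops; the calibration scenarios
use 16 frames.

## Problem sizes

Simulation-backed tests use 128–256 px frames, 10–50 puncta, 10–20 seeds
and 2000-replicate null calibrations; these sizes give stable Monte-Carlo
estimates (binomial s.e. ≈ 0.005 on the family-wise error rate) while the
full suite runs in well under a minute per module.

## Known limitations

- nMDP scores depend on the ROI: including more dark background raises the
  score of any bright-bright pair. The ROI is therefore an explicit input
  (an Otsu-based convenience guesser exists in `intensity` workflows but is
  never used by the tests or pipeline defaults — drawing the ROI is the
  analyst's decision).
- The wavelet threshold assumes approximately stationary noise within the
  ROI; strong intensity-dependent (photon-limited) noise inside very bright
  structures is not modeled in σ_j.
- The studentized range tail is evaluated by scipy's numerical integration,
  accurate to well below 1e-4 absolute over the tested range; extreme
  q values are clipped to [0, 1] in p.
- 2-D only; no 3-D decomposition, no per-vesicle tracking.
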