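# Methods

This note documents the models, conventions and numerical choices behind
`placidollt`, and what the synthetic validation does and does not show.

## Scene and measurement model

A Placido-disk topographer projects concentric illuminated rings onto the
cornea; the tear film specularly reflects them. The working hypothesis is
that a thicker, lipid-rich layer reflects more light, so the grey-level
statistics of the reflected ring pattern track lipid layer thickness (LLT).
Analysis is restricted to the pupil region because the iris adds diffuse
texture unrelated to the tear film; all metrics are normalised by the pixel
count *n* precisely so that the (subject-dependent) pupil size does not
matter.

## Processing chain

Stages run in this order, each with an 8-bit contract (round to integer,
clip to [0, 255]) unless `bit_exact=False`:

1. **Grey conversion** — BT.601 luminance (0.299 R + 0.587 G + 0.114 B),
   rounded. The conversion formula is a package choice; any fixed luminance
   weighting works equally, since all downstream statistics are relative.
2. **Centre crop** — a (2h+1)×(2h+1) window (default h = 120, i.e.
   241 × 241 px) around the examiner-annotated ring centre. The window must
   fit inside the frame; the error message reports the feasible centre
   range.
3. **Band-pass** — difference of Gaussians, σ_low = 2 px and σ_high = 20 px
   by default, reflective boundaries. The DoG transfer
   exp(−2π²σ_low²f²) − exp(−2π²σ_high²f²) passes typical Keratograph ring
   periods (~8–16 px: ≥ 0.58 at period 12 px) and suppresses slow
   illumination gradients (≤ 0.05 at period 400 px). The response is
   **half-wave rectified** by default (`bandpass_offset = 0`): the flat
   background maps to 0 and only the positive ring humps survive. A
   mid-grey re-centring (`bandpass_offset = 128`) is available for
   inspecting the signed response, but it is unusable ahead of the gain-3
   contrast step — 128 × 3 saturates every pixel at 255 and deeper ring
   troughs then *lower* the mean, inverting the intended
   brightness-vs-reflectivity response. The rectified default keeps all
   brightness metrics strictly increasing in ring amplitude.
4. **Smoothing** — Gaussian, σ = 4 px, reflective boundaries.
5. **Pupil mask** — pixels whose centres fall strictly inside the annotated
   circle, or inside the polygon by the even–odd rule. Coordinates are
   0-based (column, row) with the origin at the top-left pixel centre,
   everywhere in the package.
6. **Contrast enhancement** — v ↦ clip(round(v·255/85), 0, 255), i.e. gain
   3 with saturation; monotone non-decreasing, so it never reorders pixel
   intensities.

Every `ProcessedROI` carries a provenance record (stages + parameters);
identical inputs and provenance give bit-identical outputs.

## Metric definitions and conventions

With *p* a pixel value of the processed ROI, *n* the pixel count, *p*max
the ROI maximum and *x̄* the mean:

* energy = Σp²/n; relative energy = Σ(p/pmax)²/n = energy/pmax²;
  SD irregularity = Σ((p−x̄)/pmax)²/n = var(p)/pmax². *p*max is the
  **per-ROI** maximum by default (`pmax_mode="full"` switches to 255).
* **entropy** = Shannon entropy of the grey-level relative-frequency
  distribution (natural log; empty bins contribute 0), divided by *n*. The
  per-pixel-value reading −Σp·log(p)/n exists as `entropy_mode="pixel"`,
  but only the frequency reading yields the tiny per-n magnitudes
  (~10⁻⁴ on a ~3·10⁴-pixel ROI) that make entropy comparable across ROI
  sizes; the log base is configurable because no convention is canonical.
* total area = composite 2-D trapezoidal integral of the intensity surface
  over the mask's bounding grid (unit pixel spacing, out-of-mask cells
  zero-imputed), divided by *n*; undefined below 4 pixels or on degenerate
  1-D grids. By default it integrates the post-enhancement surface
  (`area_stage="pre"` integrates before the contrast stretch).
* basic statistics: population SD; median = lower central order statistic
  for even *n* (deterministic and integer-valued); mode = smallest grey
  level attaining the maximal count; skewness g1 = m₃/m₂^1.5 and
  non-excess kurtosis g2 = m₄/m₂² (both undefined, reported NaN, at zero
  variance). Undefined metrics propagate as NaN and become missing grades,
  never zeros.

## Grading

Grades are 1, 2 and 3+ (wave and colour-fringe merged — separating them
needs colour information, out of scope for grey-level analysis). For
higher-is-thicker metrics: value < cut(1|2) → 1, < cut(2|3) → 2, else 3+;
kurtosis and skewness reverse the direction. Ties at a boundary take the
thicker grade, and a value exactly at the screening cut-off is called
normal (tie upward in both cases; the convention matters only for exact
equality on discretised metrics).

Calibration runs three ROC analyses per metric (1 vs ≥ 2, 1 vs 2, 2 vs 3+)
on per-subject values (replicate means when replicates exist) and stores
the Youden-optimal thresholds; the direction is inferred from which side of
the screening contrast the thin group's mean falls. A fitted table whose
boundaries come out of order (possible for a non-monotone metric on a noisy
cohort) is rejected, or dropped with a warning under `strict=False`.

## Statistical machinery

* **AUC** — Mann–Whitney concordance via midranks (tied pairs credited
  0.5). Candidate cut-offs are midpoints of consecutive sorted unique
  values; the Youden-maximal one is reported, ties broken toward higher
  specificity (fewer false alarms in screening), then toward the lower
  threshold. 95% CI by stratified percentile bootstrap (B = 2000 by
  default, seeded); a contrast whose CI still covers 0.5 is flagged
  non-discriminative.
* **Discriminant power** = (√3/π)(logit Se + logit Sp); ±∞ (not an
  exception) at Se/Sp ∈ {0, 1}.
* **Repeatability** — Sw = √(mean within-subject sample variance, ddof 1);
  CoR = 2.77·Sw (1.96·√2, the Bland–Altman convention); CoV = 100·Sw /
  |grand mean|. Subjects with < 2 replicates are excluded with a warning.
* **Agreement** — accuracy, Cohen's κ, quadratic-weighted κ
  (w_ij = 1 − (i−j)²/(G−1)²) and F1. The headline F1 collapses to binary
  altered (grade 1) vs normal (≥ 2) with *normal* as the positive class;
  because that convention is not universal, the macro-averaged F1 over all
  grades is reported alongside. These standard statistics are delegated to
  scikit-learn behind the module's interface; the ROC/Youden machinery is
  implemented here because its tie and threshold conventions are part of
  the method.

## Phantom generator

The phantom renders what the instrument sees: inside the pupil disk, rings
I(r) = B + A·profile(2πr/λ) over a dark gap level B (profile ∈ [0, 1],
sinusoid or square — rings are *brighter* than the gaps, and A is the LLT
surrogate); a ring-free textured iris annulus around it; seeded Gaussian
sensor noise everywhere; clipping to [0, 255]. The unipolar profile keeps
the full default amplitude range (A up to 135 over B = 40) inside 8 bits.
Defaults: 512 × 680 px, λ = 16 px, pupil radius 100 px, noise SD 8. After an
optional break-up time, seeded elliptical dark patches with
Gaussian-feathered edges grow in number and area, a minimal stand-in for
local pattern degradation of a destabilising tear film.

Cohorts map grade g to mean amplitude A = 30g + 15 (45/75/105/135) with
between-subject jitter SD 6 — mild group overlap, so ROC curves are
non-degenerate — and render 3 replicates per subject at the requested
post-blink timepoints. All randomness flows from explicit integer seeds
through numpy's PCG64 generator, so frames are bit-identical across runs
and platforms.

**What the phantom does not emulate:** real tear-film optics (no ray
tracing), corneal curvature distortion of ring spacing, eye movements,
specular highlights, illumination drift, or colour interference fringes.
Passing the end-to-end phantom study therefore demonstrates that the
pipeline is correct and that the grading machinery recovers a known
monotone reflectivity→grade relationship; it does **not** reproduce the
clinical performance figures (AUC ≈ 0.89–0.91, accuracy ≈ 0.76–0.77,
weighted κ ≈ 0.77, the repeatability magnitudes, or the r ≈ 0.655–0.674
correlations), which depend on 94 clinical recordings that are not
deposited. Those numbers ship only as flagged reference metadata
(`placidollt.reference`).

## Problem sizes and validation design

The validation suite uses: 100 random ROIs (mixed sizes up to 241 × 241)
against double-loop brute-force oracles at 10⁻⁹; 50 seeded datasets for the
AUC-vs-concordance identity (exact); 100 random G×G confusion tables
(G ≤ 5) for the weighted-kappa oracle; 200 subjects × 3 replicates for Sw
recovery (σ = 1, within 10%); and a 4-grade × 10-subject × 3-replicate
phantom cohort at noise SD 8 for the end-to-end study — sizes chosen so the
whole suite completes in well under a minute per component while keeping
sampling error far from the asserted margins.

## Known limitations

* The published kurtosis (~0.015) and skewness (~0.14) reference magnitudes
  are inconsistent with the standard moment-ratio definitions used here
  (kurtosis of any distribution is ≥ 1); their shipped cut-offs are
  therefore unusable with this pipeline and those metrics must be
  recalibrated on cohort data.
* Video containers need an ffmpeg-backed imageio plugin; the supported
  bit-exact input is a lossless PNG/TIFF frame stack.
* Pattern centre and pupil come from manual annotation (as in clinical use
  of the method); blink detection is advisory only.
* Single-metric grading only: no multi-metric or learned combination.
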