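# Methods

## Parametric mapping

**ADC.** Each pixel of a multi-b-value diffusion series is fitted with the
mono-exponential decay `S(b) = S0·exp(−b·ADC·10⁻⁶)`, with b in s/mm² and ADC
stored in 10⁻⁶ mm²/s so the map values are directly comparable to the renal
literature (cortical values ~1600–2800, medullary ~1700–2600 at 3T). Two
criteria are offered: *loglinear* (default) minimises least squares of
ln S on b and flags any pixel with a non-positive sample as invalid;
*nonlinear* minimises least squares on the signal itself, initialised from
the log-linear solution. The nonlinear solver is a vectorised
Levenberg-damped Gauss–Newton over all pixels simultaneously (2×2 normal
equations in closed form, per-pixel damping, 200 iterations max,
relative-improvement tolerance 10⁻¹⁴); on benign noiseless data it converges
to the generating parameters to better than 10⁻⁹ relative error, and on
noisy single pixels it agrees with a dense (S0, ADC) grid search within one
grid step. Unweighted least squares is used throughout; no Rician-bias
correction is applied, so at low SNR the fitted ADC is biased low — a known
limitation, acceptable at the SNR of cortical/medullary ROIs.

**T1.** Inversion-recovery magnitude data are fitted with
`|S(TI)| = |A − B·exp(−TI/T1*)|`. Polarity is restored exhaustively: for TI-
sorted samples every possible sign-flip point k (first k samples negated,
k = 0..n) is tried, which covers all physically realisable sign patterns of
a monotone recovery at ≤ n+1 candidates. For each candidate the problem is
solved by variable projection — (A, B) are linear given T1*, so the search
is one-dimensional: a 160-point log-spaced T1* grid (20–8000 ms) followed by
golden-section refinement of the projected SSE inside the best bracket. The
apparent T1* is corrected with the Look-Locker relation `T1 = T1*(B/A − 1)`.
Pixels with A ≤ 0 or a degenerate design are invalid; pixels with B/A ≤ 1
(correction non-physical, which noise can produce) report T1* and carry a
per-pixel quality flag rather than failing. Any ≥3 distinct TIs are
accepted; the synthetic generator emits 6 (the protocol's printed 161, 241,
321 ms plus 800, 1600, 3200 ms) so the 3-parameter fit is over-determined
without simulating cardiac gating.

## ROI aggregation and Δ indices

Compartment statistics pool **pixels** across all ROIs of a compartment
(areas therefore weight ROIs), with a mean-of-ROI-means mode available as a
sensitivity check; the SD is the pixel SD. Invalid map pixels are silently
excluded with a warning above 20% exclusion. The indices are plain
differences, ΔADC = cortex − medulla mean (likewise ΔT1); their sign is
meaningful and preserved. Synthetic ROI sampling mimics manual placement:
~11 cortical and ~19 medullary ROIs per subject.

## Sirius-red quantification

Sections are unmixed by optical-density colour deconvolution with a fixed
stain matrix (published hematoxylin vector; a fast-red-like vector for the
Sirius-red marker; orthogonal residual third channel). The matrix is
configurable because the commercial package used for the original
measurements keeps its channel definitions proprietary — thresholds are
comparable in spirit, not bit-identical. Concentrations are divided by the
8-bit maximum optical density (log10 255 ≈ 2.41) and clipped to [0, 1], so
the shipped threshold presets (human 0.15 hematoxylin / 0.11 red, rat
0.07 / 0.45, both with a 10 µm² minimum area) apply to a fixed scale.
Marker pixels are those inside the ROI polygon (even-odd rule on pixel
centres) whose marker channel is ≥ its threshold and hematoxylin channel
below its threshold; a brown-channel exclusion exists but is off by default
since how the original software combined brown with red on Sirius-red
slides is not documented. Components are 8-connected; the area filter is
physical (pixel count × calibration², so 186 px at 0.232 µm/px). Percent
area = 100 × kept marker area / ROI area.

## Statistics

Implemented from their defining formulas, with scipy supplying reference
distributions only. All p-values are two-sided.

- *Pearson*: sample correlation, p from the t-transform with n−2 df.
- *Fisher z*: `z = (atanh r1 − atanh r2)/√(1/(n1−3)+1/(n2−3))`, normal p.
  The two samples are treated as independent — the convention of the
  standard online calculators — even when, as in the motivating analysis,
  the correlations share subjects; this reproduces the reported behaviour
  and is documented rather than "corrected".
- *Rank-sum* ("Wilcoxon" comparing two groups): exact mode enumerates all
  C(n, n_a) assignments of the observed midranks (ties handled by
  enumeration), counting assignments whose rank-sum deviates from the
  permutation mean at least as much as observed; used automatically at
  n ≤ 12. Otherwise a tie-corrected normal approximation with 0.5
  continuity correction, which stays within 0.02 of the exact p in the
  8–12 range and holds the type-I error within [0.03, 0.07] at α = 0.05.
- *ICC(1,1)*: one-way random-effects single-measure,
  `(MSB − MSW)/(MSB + (k−1)MSW)`, with the F-based 95% CI.
- *ANOVA + Bonferroni*: classical one-way decomposition; pairwise t tests
  use the pooled within-group mean square, p multiplied by the number of
  comparisons and capped at 1.

## Classification pipeline

The IF grid (10–70% step 10) binarises subjects at each cut-off t into
High (IF > t, consistent with "more than t%") vs Low; the rank-sum p of
ΔADC between the groups is recorded, degenerate (empty-group) thresholds
are flagged and excluded, and the minimum-p threshold is selected. When
several grid thresholds fall inside the same gap of the empirical IF
distribution they induce the identical split and exactly tie; the tie is
broken toward the threshold closest to the centre of its gap, the most
representative cut of an interval the data cannot distinguish. A cohort
with constant ΔADC yields all p = 1 and an explicit *uninformative* flag.

The discriminant is the 1-D two-class Gaussian LDA with pooled within-class
variance; with class priors π the boundary solves the equality of linear
discriminant scores: `x* = (µ_H + µ_L)/2 + σ²·ln(π_L/π_H)/(µ_H − µ_L)`.
Priors default to class frequencies (the common statistical-package
default); equal priors are a flag. Sensitivity and specificity are
resubstitution recalls on the High- and Low-IF classes — optimistic by
construction, matching how a small single-cohort study reports them. The
bootstrap resamples subjects with replacement, refits the LDA per replicate
and records its resubstitution accuracy; replicates missing a class (or
with zero pooled variance) are redrawn so the replicate count stays fixed,
with an error once redraws exceed 50%. The CI is the 2.5/97.5 percentile
interval. One `numpy.random.default_rng` generator per operation, seed
surfaced in every output.

## Synthetic data

The generators define the study conditions and are deterministic in
(spec, seed).

- **Phantoms**: a medullary ellipse inside a cortical ring on a 64×64 grid
  (100×100 for noise studies); defaults ADC 1800/2000 ×10⁻⁶ mm²/s and T1
  1350/1450 ms (cortex/medulla), mid-range of the values observed in
  allografts; S0 ≈ 100 with Rician σ = 2 (i.e. 2% of S0). Noise is Rician —
  magnitude of a complex signal with iid Gaussian noise — because both DWI
  and IR inputs are magnitude images; at S = 0 this reduces to a Rayleigh
  law with mode σ, which the tests verify against the closed form. The IR
  generator uses B = 2A, making the Look-Locker correction the identity, so
  phantom truth tables remain exact for both apparent and corrected T1.
- **Histology**: stain-composed RGB via Beer–Lambert with the same default
  stain matrix the quantifier inverts. Collagen disks (radius 8–18 px,
  wholly inside the frame so no clipped fragment falls under the minimum
  area) are painted to just below the requested fraction, then the painted
  region grows outward pixel-by-pixel in distance order to the exact pixel
  count — growth never fragments a component, so the painted truth is
  reachable to ≪0.1% and the min-area filter sees only full-size blobs.
- **Cohorts** (default n = 29, the size of the analysed allograft subset):
  IF is a mixture of a low-fibrosis majority (U(2, 35), weight 0.55) and a
  high tail (U(35, 80)); ΔADC = 220 − 5.5·IF + N(0, 92²), whose noiseless
  zero-crossing sits at 40% IF and whose noise level puts the median
  ΔADC–IF R² near 0.64 (verified ∈ [0.5, 0.8] over 500 seeds). The ΔT1
  link (10 − 2·IF + N(0, 70²)) targets R² ≈ 0.29; its printed range and
  that R² are mutually tight for a linear-Gaussian link, so the R² was
  prioritised and the range is approximate. A Sirius-red column adds
  N(0, 20²) noise to IF (R² ≈ 0.56 with the primary column). Banff ci
  follows the standard bands (0: ≤5%, 1: 6–25%, 2: 26–50%, 3: >50%), ct is
  ci ± 1, inflammation scores are drawn independently (no inflammation–MRI
  correlation is emulated), and eGFR is loosely linked to IF. Compartment
  means are medullary draws inside the observed ranges plus the Δ, keeping
  the table internally consistent.
- **Planted cohorts** for threshold-recovery studies: ΔADC ~ N(150, 40²)
  for IF ∈ (5, 35) and N(−100, 40²) for IF ∈ (45, 80), n = 29.

What the generators do **not** emulate: anatomy, partial-volume mixing at
compartment borders, motion/distortion, B1/B0 inhomogeneity, staining
variability between labs, and any joint ΔT1–ΔADC correlation structure.
Passing tests therefore demonstrate correctness of the estimators and the
analysis logic under the stated noise models, not clinical performance on
patient data.

## Problem sizes and numerical choices

Default suite sizes: 64×64 phantoms (≈1.8k fitted pixels), 10k-pixel noise
studies, 200 planted cohorts for threshold recovery, 50 histology seeds,
10k null simulations for the rank-sum size check, 500 seeds for the
R²-calibration check — each chosen as the smallest size at which the checked
quantity is stable. Ties in ranks use midranks; exact-test comparisons use
a 10⁻⁹ slack so floating-point midrank sums do not miscount boundary
assignments; the ADC solver clamps Levenberg damping to [10⁻¹², 10¹²];
golden-section T1* refinement runs 90 iterations, well past machine
precision of the bracket. Degenerate inputs (empty compartments, all-zero
series, constant vectors, single-class labels) raise typed errors or flag
pixels instead of propagating NaNs; the CLI maps configuration errors and
statistical degeneracy to distinct exit codes (2 and 3).

## Known limitations

Rician bias is uncorrected; the stain matrix is a published approximation,
not the proprietary channels of the original software; resubstitution
performance is optimistic and no cross-validation is offered (the reported
analysis used none); the Fisher-z comparison assumes independent samples;
IVIM/kurtosis diffusion models and automatic cortex/medulla segmentation
are out of scope.
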