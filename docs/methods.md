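# Methods

`pdff-texture` quantifies the *pattern* of fatty infiltration in paraspinal
muscle from quantitative water–fat MRI, and relates it to isometric muscle
strength. This note documents the models, the numerical choices, and what
the synthetic data do and do not establish.

## Input model

The pipeline operates on proton-density fat-fraction (PDFF) maps: 3D
volumes on the percent scale, PDFF = 100·F/(F+W) with F and W the fat and
water signal magnitudes. Voxels with F+W = 0 (air) are defined as 0 % and
tallied rather than rejected, because masks are expected to exclude them
and the tally exposes mask leakage. Maps carry anisotropic spacing; the
reference acquisition uses 3.2 × 2.0 × 4.0 mm³ voxels. Masks must live on
the same grid as the map — no registration or reorientation is performed.
Four muscle ROIs are analyzed: right/left erector spinae (ES) and psoas
(PS).

## First-order (histogram) features

Variance, skewness and kurtosis of the in-ROI intensity histogram,
computed from bin centers weighted by bin probabilities. Kurtosis is
non-excess (a normal distribution scores 3). The bin count is the median
of three classical rules — Sturges ⌈log₂n⌉+1, Scott (width 3.49·s·n^(−1/3),
sample SD with n−1 denominator), and Freedman–Diaconis (width
2·IQR·n^(−1/3), interpolated quartiles) — which is robust to any single
rule misbehaving on skewed ROI distributions. Degenerate conventions:
zero range → 1 bin; zero IQR → Sturges count; zero-variance histogram →
skewness and kurtosis reported as 0 with a degeneracy flag. First-order
features are computed from the original-resolution voxels, before any
resampling.

## Second-order (co-occurrence) features

Eight features of the 3D gray-level co-occurrence matrix (GLCM): energy,
entropy (base-2 by default; configurable), contrast, homogeneity,
correlation, variance, sum-average, and dissimilarity, with marginal
statistics taken from the symmetrized matrix. Correlation of a
zero-variance marginal is defined as 0 and flagged.

Preprocessing: the ROI is cropped to its bounding box (+1 voxel), the
volume and mask are resampled to cubic voxels at the minimum input edge
(2.0 mm for the reference spacing) — trilinear intensities, mask density
thresholded at 0.5 — and the in-mask intensities are quantized to 200
uniform levels between the in-mask extrema (fixed 0–100 % bounds are
available via configuration). Before interpolation, out-of-mask voxels
are replaced by their nearest in-mask value, so boundary voxels never mix
muscle with background air; a constant ROI therefore stays constant under
resampling.

Co-occurrences are accumulated over all in-mask voxel pairs for each of
the 13 canonical offsets of the 26-neighborhood (one per ± pair),
symmetrized, and normalized. Because the grid is isotropic at this point,
all 13 unit-voxel offsets span comparable physical lengths; no
per-direction distance weighting is applied. Features are averaged
unweighted over the directions with at least one valid pair, which makes
the result exactly invariant under the 48 axis permutation/reflection
symmetries of the grid (verified by test). Directions without pairs are
skipped and counted.

Per muscle this yields 11 texture features (3 histogram + 8 GLCM) plus
mean PDFF and physical volume. Right and left muscles are combined by
volume-weighted averaging, f = (f_R·V_R + f_L·V_L)/(V_R+V_L), using
physical mm³ volumes so the weighting is resolution independent.

## Cohort statistics

The cohort table holds one row per subject with 26 candidate predictors
(age, BMI, bilateral mean PDFF of ES and PS, and the 22 bilateral texture
features) plus extension and flexion torque (Nm) and sex.

* Normality: one-sample Kolmogorov–Smirnov against a normal with
  sample-estimated mean/SD. With estimated parameters the plain test is
  anticonservative; the Lilliefors-corrected variant is available.
* Sex comparisons: two-sided Student pooled-variance t-tests (a Welch
  variant is available).
* Correlation screen: Pearson r per variable with two-sided p, flagged at
  the Bonferroni level α/m (α = 0.05, m = 24 for the strength screen:
  2 mean PDFF + 22 texture features; m is an explicit argument because
  the appropriate family size differs between analyses). α/24 ≈ 0.0021
  at two significant figures.
* Stepwise regression (`StepwiseOLS` → `StepwiseOLSResults`): classic
  bidirectional selection — the excluded candidate with the smallest
  partial-F p enters if p < 0.05, then the included predictor with the
  largest p leaves if p > 0.10, until no change. For a single regressor
  the partial F equals the squared coefficient t, so coefficient p-values
  are used. Ties break toward the smaller p, then alphabetically; a
  visited-state set guards against entry/removal cycles; candidates that
  are collinear with the included set (undefined p) are skipped.
  Reported: coefficients, p-values, R², adjusted
  R² = 1 − (1−R²)(n−1)/(n−k−1), and the full step trace.

A known property of this selector, relevant to interpreting its output:
with ~24 null candidates at p_enter = 0.05, the probability that *some*
spurious variable joins a final model is large (≈1 − 0.95²⁴ ≈ 0.7 per
scan round), so small-p spurious entries are expected in a substantial
fraction of fits. This is intrinsic to stepwise selection at these
conventional thresholds, not an implementation artifact; the step trace
makes such entries auditable.

## Synthetic phantoms and cohorts

No real cohort is distributable, so a generator emulates the study
conditions end to end.

**Phantom.** Each muscle is an elliptic cylinder filled with a truncated
normal base PDFF field; fatty streaks are axis-aligned prolate ellipsoids
(elongated cranio-caudally) centered at random in-mask voxels, filled
with a truncated normal at the streak level. The default grid is
64 × 44 × 20 voxels at 3.2 × 2.0 × 4.0 mm (ES ≈ 3000, PS ≈ 1250 voxels
per side); Monte-Carlo work uses a reduced 36 × 26 × 10 layout with
proportionally smaller muscles, chosen so repeated cohort generation
stays fast while every pipeline stage is still exercised. Streak
geometry is validated against muscle size; a fixed seed reproduces a
phantom bit for bit. Phantoms can be emitted as consistent fat/water
signal pairs (F = PDFF, W = 100 − PDFF) that round-trip through the PDFF
computation exactly.

**Mean/pattern decoupling.** A subject's muscle-mean PDFF target is drawn
per sex (ES 8.93 % male / 11.65 % female; PS pooled at 4.83 %, since only
the ES sex difference is treated as established), and the base level is
then solved from
target = (1−f)·base + f·streak_level, with f the *lattice* streak volume
fraction. Realized mean fat content therefore tracks the target
independently of how streaky the muscle is — the same contrast the study
illustrates with subjects of comparable mean PDFF but very different
texture. If a lean muscle cannot host the drawn contamination, the
streak count is reduced to the feasible maximum; budgets are sized so
this almost never binds. The base location is corrected for the 0 %
truncation (root-finding on the truncated-normal mean) so the
decomposition holds in expectation for lean muscles too.

**Heterogeneity.** Streak count (ES 0–5, PS 0–3) and per-muscle streak
level (ES 25–70 %, PS 12–32 %) are drawn independently per subject, so
contamination fraction and intensity vary separately; this keeps
histogram variance (≈ p·d²) and skewness (≈ p·d³/σ³) from collapsing
onto one axis. Psoas contamination is kept mild relative to its base
noise (σ ≈ 1.2 %): when base variance is negligible against
contamination energy, skewness and kurtosis of the mixture become
deterministically linked (for a two-point mixture kurt = 1 + skew²) and
no selector could tell them apart. PS streak levels are far milder than
the ES ones; the generator's PS variance magnitudes are consequently
smaller than those seen in real psoas data — a deliberate trade for
identifiable planted effects.

**Outcomes.** Torques are linear in measured features plus Gaussian
noise:

    MVIC_ext  = 10  + 1.5·Kurtosis(global)_ES + 6.0·BMI      + ε,  σ = 8 Nm
    MVIC_flex = 100 + 3.0·Variance(global)_PS + 12·Skewness(global)_PS + ε

The coefficient structure mirrors the predictors the study reports for
each outcome; the values are chosen so generated torques span roughly
100–340 Nm, and σ = 8 Nm reflects isokinetic dynamometry test–retest
repeatability (a few percent of typical MVIC). The declared coefficients
and every subject's generating parameters are returned as ground truth
for recovery testing.

**Calibration.** At n = 100 with default settings the realized cohort
means land at ≈10.7 % (ES) and ≈4.85 % (PS), within one SD of the 10.50
± 2.90 / 4.83 ± 1.82 calibration targets, with females higher than males
in ES.

**What the synthetic data do not show.** Phantoms are cylinders with
ellipsoidal streaks — no anatomy, no partial-volume mixture at muscle
boundaries beyond interpolation, no MR physics (echoes, field maps,
T1/T2* bias), no left/right asymmetry, and psoas heterogeneity milder
than in vivo. Passing tests demonstrate correctness of the computational
pipeline and recoverability of planted effects under these idealized
conditions, not clinical validity on real maps.

## Problem sizes used by tests and the acceptance script

GLCM oracle equivalence runs 200 random masked grids (≤8³, ≤6 levels, all
13 directions) against an explicit pair-enumeration oracle at 1e-12.
Mean-matched heterogeneity pairs use 20 seeds on the full-size ES
phantom. Planted-model recovery uses 50 cohorts of n = 100 on the
reduced layout. The null calibration of the correlation screen uses
2000 synthetic null cohorts of n = 26 with 24 noise predictors (500 in
the acceptance script). The script derives every stream from `--seed`
via `SeedSequence`.

## Known limitations

* The stepwise exclusion property is limited by the selector's intrinsic
  null-entry rate (see above): in roughly 10–20 % of synthetic cohorts a
  spurious predictor — occasionally a mean-PDFF column — joins a final
  model with p just under 0.05, even though its partial correlation with
  the outcome is exactly null by construction.
* The plain KS normality p-value with estimated parameters is
  approximate; use the Lilliefors variant when it matters.
* Variance(global) is reported on the percent² scale of the PDFF axis;
  an analysis quantizing intensities first would report it on the
  level² scale instead.
* Whether the reference analysis quantized between ROI extrema or fixed
  0–100 % bounds is ambiguous; both are supported (`intensity_bounds`),
  ROI extrema by default.
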