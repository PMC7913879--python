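# pdff-texture

Texture analysis of proton-density fat-fraction (PDFF) maps of paraspinal
muscles, for researchers studying muscle composition and function with
chemical-shift-encoding water–fat MRI.

Mean PDFF — the voxel-average fat fraction of a muscle — ignores *how*
fat is distributed. Two muscles with identical mean fat content can look
entirely different: one uniformly infiltrated, the other streaked with
focal fatty replacements. This package quantifies that pattern and tests
whether it predicts muscle function:

* **First-order features** of the in-ROI intensity histogram: variance,
  skewness, and (non-excess) kurtosis, with the bin count chosen as the
  median of the Sturges, Scott and Freedman–Diaconis rules.
* **Second-order features** of the 3D gray-level co-occurrence matrix
  (GLCM) after isotropic resampling and 200-level uniform quantization:
  energy, entropy, contrast, homogeneity, correlation, variance,
  sum-average and dissimilarity, accumulated over all in-mask voxel
  pairs in the 13 directions of the 26-neighborhood and averaged across
  directions for rotation invariance.
* **Bilateral aggregation**: right/left features combined by
  volume-weighted means, f = (f_R·V_R + f_L·V_L)/(V_R + V_L).
* **Cohort statistics**: KS normality screening, pooled t-tests by sex,
  a Bonferroni-corrected Pearson screen (α/24 ≈ 0.0021), and stepwise
  multivariate linear regression (entry p < 0.05, removal p > 0.10,
  partial F-tests) reporting coefficients, R² and adjusted
  R² = 1 − (1−R²)(n−1)/(n−k−1) via a statsmodels-style
  `StepwiseOLS` / `StepwiseOLSResults` pair.
* **A synthetic cohort generator**: phantom muscles (elliptic cylinders
  with high-PDFF fatty streaks) and full cohorts with strength outcomes
  planted on texture features, with ground truth returned for recovery
  testing — so the entire pipeline is testable without access to
  patient data.

Volumes and masks are NIfTI (`nibabel`); tables are pandas DataFrames;
statistics run on scipy/statsmodels.

## Worked example

Simulate a 26-subject cohort and fit the extension-strength model:

```bash
pdff-texture simulate --n-subjects 26 --seed 7 --out-dir demo
pdff-texture analyze --cohort demo/cohort.csv --outcome mvic_ext --out demo/report.json
```

prints

```
Stepwise OLS: mvic_ext ~ kurtosis_global_es + bmi + variance_ps
n = 26, R^2 = 0.9595, adj. R^2 = 0.9540

Steps:
  add    kurtosis_global_es       p = 7.739e-08
  add    bmi                      p = 4.824e-10
  add    variance_ps              p = 0.01686

Coefficients:
  const                          29.277   se      12.14   p 0.02467
  kurtosis_global_es             1.6211   se    0.08253   p 1.943e-15
  bmi                            5.0375   se     0.4534   p 1.719e-10
```

The selector recovers the two planted predictors of extension strength —
erector-spinae histogram kurtosis (true coefficient 1.5) and BMI (true
coefficient 6.0) — with estimates 1.62 and 5.04; mean PDFF does not
enter. The third line is a spurious entry (`variance_ps`, p = 0.017):
with 24 null candidates tested at the 0.05 entry level, occasional
extras are expected, and the printed trace makes them auditable. The
high adjusted R² (0.95) reflects the low simulated torque noise, not a
claim about real cohorts.

Feature extraction from existing maps works the same way:

```bash
pdff-texture extract --pdff pdff.nii.gz --masks masks.nii.gz --out features.csv
```

where the mask file labels muscles 1: ES-right, 2: ES-left, 3: PS-right,
4: PS-left; the CSV holds one row per muscle with mean PDFF, physical
volume and the 11 texture features.

The same operations are available as a library:

```python
from pdff_texture import (CohortConfig, generate_cohort_table,
                          StepwiseOLS, predictor_columns)

table, truth = generate_cohort_table(CohortConfig(n_subjects=26, seed=7))
res = StepwiseOLS.from_dataframe(table, "mvic_ext",
                                 predictor_columns()).fit()
print(res.summary())
```

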