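# pkdrad

CT radiomics of polycystic kidneys: can the *texture* of kidney parenchyma
on non-contrast CT — not just kidney volume — tell apart patients with
impaired baseline kidney function, and patients whose function is declining
fast?

In autosomal dominant polycystic kidney disease (ADPKD), fluid-filled cysts
progressively replace working parenchyma; height-adjusted total kidney
volume (ht-TKV) is the established imaging biomarker of progression, but
the tissue's textural heterogeneity plausibly carries complementary
information about the fibro-inflammatory background. `pkdrad` implements
the full analysis pipeline for testing that idea, for imaging scientists
and biostatisticians working with small clinical cohorts:

- **Imaging**: NIfTI CT volumes + per-kidney masks → merged parenchyma ROI.
- **Texture**: grey-level co-occurrence (GLCM) features — correlation
  `F_cm.corr`, cluster tendency `F_cm_merged.clust.tend` and the rest of
  the IBSI-style suite — under four 2D/2.5D aggregation schemes, plus
  first-order intensity statistics and morphology; cohort z-scoring.
- **Endpoints**: CKD-EPI eGFR from serum creatinine, baseline class (late
  CKD: eGFR < 60 mL/min/1.73 m²), per-patient eGFR slope by OLS, and
  rapid-progressor labels (decline > 3 mL/min/1.73 m²/year).
- **Selection**: Wilcoxon–Mann–Whitney screening, Benjamini–Hochberg at
  α = .05, and Pearson decorrelation down to a single modelling feature,
  guarded by the one-to-ten events-per-variable rule.
- **Models & validation**: IRLS logistic regression with a small-sample
  battery — recalibration likelihood-ratio test, Mann–Whitney AUC with
  stratified percentile-bootstrap 95% CIs (B = 2000), paired DeLong
  comparisons, Youden-index thresholds, Jeffreys intervals for the
  classification metrics, repeated stratified 3-fold CV, and a
  1000-replicate bootstrap "average model" for internal validation.
- **Phantoms**: a synthetic cystic-kidney cohort generator that plants a
  latent severity driving kidney volume, eGFR, its slope and parenchymal
  texture, so the whole pipeline is testable end to end without any
  patient data.

The two key texture statistics, for a normalized symmetric co-occurrence
matrix p(i,j) with marginal mean μ and variance σ²:

    correlation       = Σᵢⱼ (i−μ)(j−μ) p(i,j) / σ²
    cluster tendency  = Σᵢⱼ (i+j−2μ)² p(i,j)

Heterogeneous cystic tissue shows *higher* co-occurrence correlation
(coherent structures make neighbouring intensities co-vary) and *lower*
merged cluster tendency than homogeneous parenchyma; the phantom generator
reproduces exactly this direction and the tests assert it.

## Worked example

Simulate a 58-patient cohort in which 7 patients lack the three creatinine
values needed for slope estimation, extract features from every phantom and
run the progression analysis:

```python
import warnings
from pkdrad.phantom import PhantomParams, CohortParams, generate_cohort
from pkdrad.pipeline import PipelineConfig, cohort_feature_table, run_progression_analysis

params = CohortParams(n=58, seed=1, n_visit_deficient=7,
                      beta_texture=2.5, sd_texture=1.2,
                      beta_slope=5.0, sd_slope=0.4, sd_measurement=1.0)
cohort = generate_cohort(params, PhantomParams())
config = PipelineConfig(seed=2)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    features = cohort_feature_table(cohort, config)
    report = run_progression_analysis(features, cohort.visits, config)

print(f"analyzed {report['n_analyzed']} of {report['n_patients_total']} patients "
      f"({report['n_rapid']} rapid, {report['n_non_rapid']} non-rapid)")
print("selected feature:", report["selection"]["selected"])
for name, m in report["models"].items():
    lo, hi = m["auc_ci"]
    print(f"{name:>9}: AUC {m['auc']:.2f} (95% CI {lo:.2f}-{hi:.2f}), "
          f"sens {m['metrics']['sensitivity']:.2f}, spec {m['metrics']['specificity']:.2f}")
```

This prints:

```
analyzed 51 of 58 patients (35 rapid, 16 non-rapid)
selected feature: F_cm_merged.clust.tend
 radiomic: AUC 0.90 (95% CI 0.77-0.99), sens 0.94, spec 0.81
   ht-TKV: AUC 0.68 (95% CI 0.49-0.85), sens 0.83, spec 0.56
```

Seven visit-deficient patients were excluded (each listed with its reason
in `report["excluded"]`), the screening cascade selected a co-occurrence
feature, and the texture-based logistic model clearly out-discriminates
the volume-based one — the planted association is recovered. Sensitivity
refers to rapid progressors, specificity to non-rapid; both carry Jeffreys
95% CIs in `report["models"][...]["metrics"]`.

The same machinery runs from the shell:

```
pkdrad simulate --n 58 --seed 1 --out cohort/
pkdrad extract --images cohort/images --out features.csv
pkdrad endpoints --clinical cohort/clinical.csv --out endpoints.csv
pkdrad run-progression --features features.csv --clinical cohort/clinical.csv --out run/
pkdrad run-baseline    --features features.csv --clinical cohort/clinical.csv --out run/
```

`run-baseline` fits the three baseline models (ht-TKV + age, radiomic
feature + age, radiomic feature + ht-TKV) and writes a consolidated JSON
report, ROC coordinates and figures under the run directory.

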