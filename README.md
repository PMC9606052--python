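# petrad — multi-lesion FDG-PET radiomics

`petrad` is a toolkit for the central methodological question of PET
radiomics in multifocal disease (e.g. diffuse large B-cell lymphoma): when a
patient has many lesions, **which lesions and which features should feed an
outcome model** — the largest lesion, the hottest (highest SUVmax), all
lesions merged into one patient-level VOI, per-lesion features aggregated by
maximum or median, or simple patient-level *dissemination* metrics such as
Dmax<sub>bulk</sub>, the maximum distance from the largest lesion to any
other lesion?

It provides, end to end:

* a **synthetic phantom cohort generator**: multi-lesion SUV images with
  known ground truth and a binary progression-like outcome drawn from a
  logistic link on standardized (log MTV, SUV<sub>peak</sub>,
  Dmax<sub>bulk</sub>), intercept-calibrated to a target prevalence
  (default 52/296 ≈ 17.6%);
* **lesion delineation** by the SUV ≥ 4.0 / volume ≥ 3 mL rule
  (26-connected components), with scripted mask editing and scan QC;
* an **IBSI-aligned radiomics engine**: 5 conventional PET features on the
  original grid plus 22 morphology, 50 intensity and 408 texture features
  (GLCM, GLRLM, GLSZM, GLDZM, NGTDM, NGLDM with 2D/2.5D/3D aggregations) on
  the image resampled to 2 mm and discretized at 0.25 SUV — 485 features per
  lesion or patient VOI;
* **18 dissemination features** (lesion count, four inter-lesion distance
  features, intensity and volume spread across lesions);
* **twelve lesion/feature-selection model variants** and a repeated
  stratified cross-validation harness (5 folds × 50 repeats) with skew-gated
  log transform, SMOTE oversampling, six feature-reduction methods,
  ridge-logistic classification, fold-wise DeLong model comparison with
  median p, and random-forest feature importance;
* a YAML-configured **experiment driver** and CLI (`petrad simulate`,
  `segment`, `extract`, `disseminate`, `build-table`, `compare`,
  `run-experiment`).

See `docs/methods.md` for the model, feature definitions, numerical choices
and limitations.

## Worked example

```python
import numpy as np
from petrad import (PhantomConfig, CohortConfig, generate_cohort,
                    extract_cohort_features, build_feature_table, ModelSpec,
                    run_repeated_cv, lesion_concordance)

phantom = PhantomConfig(grid_shape=(48, 48, 64), n_lesions_range=(1, 4),
                        lesion_radius_range_mm=(9.0, 16.0),
                        lesion_suv_range=(4.5, 25.0))
cohort = CohortConfig(n_patients=120, seed=7)
patients = generate_cohort(cohort, phantom)

feats = extract_cohort_features(patients, approaches=["reference", "dissemination"])
print(f"patients: {len(feats)}, prevalence: {np.mean([p.outcome for p in feats]):.3f}")

frac, _ = lesion_concordance([p.lesions for p in feats])
print(f"largest == hottest lesion in {100 * frac:.0f}% of patients")

table = build_feature_table(feats, ModelSpec("reference"))
print(f"reference table: {table.X.shape[0]} x {table.n_features}")

result = run_repeated_cv(table, ModelSpec("reference", oversampling="interpolate"),
                         n_folds=5, n_repeats=10, seed=7)
print(f"reference model CV-AUC: {result.mean_auc:.3f} +/- {result.sd_auc:.3f}")
```

Output:

```
patients: 120, prevalence: 0.175
largest == hottest lesion in 54% of patients
reference table: 120 x 3
reference model CV-AUC: 0.757 +/- 0.112
```

Reading the numbers: the cohort's empirical event rate (0.175) matches the
calibrated prevalence target; in roughly half of these synthetic patients
the largest lesion is not the hottest (peak SUVs are drawn independently of
size); the reference model — just MTV, SUV<sub>peak</sub> and
Dmax<sub>bulk</sub> — recovers the outcome signal planted by the generating
link, with the ± value being the SD over the 50 fold AUCs.

The same grid can be driven from a config file:

```bash
petrad run-experiment --config experiment.yaml --out results/ --seed 1
```

which writes `grid.csv` (every approach × oversampling × reduction cell),
`best_models.csv`, per-fold AUCs, DeLong comparisons against the reference
model, feature-importance tables and full provenance.

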