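# comorbmtl

Multitask-learning signatures of the comorbidity between pain and
affective symptoms (depression, anxiety) in multi-center cohort data.

Pain and affective symptom severity are weakly correlated outcomes
measured on the same subjects.  To find the *shared* component — the
features that carry information about both conditions at once —
`comorbmtl` fits the two outcomes jointly with a density-weighted,
L2,1-regularized multitask regression:

```
min_W  Σᵢ (1/nᵢ) Σⱼ Rᵢⱼ (xᵢⱼ·Wᵢ − yᵢⱼ)²  +  λ‖W‖₂,₁ ,
‖W‖₂,₁ = Σ_g ‖W[g,·]‖₂ ,    R_j = C_jˣ · n/Σ C_jˣ ,  C_j = 1 − f_j
```

where `W` (features × tasks) is shrunk row-wise — a feature is selected
for both outcomes or for neither — and the density weights `R_j`
up-weight subjects with rare outcome values `f_j` (symptom scores are
heavily right-skewed; `x = 1` by default, `x = 0` disables weighting).

Around this estimator the package implements the full multi-center
workflow:

- **Leakage-free preprocessing** — standardization and (for voxelwise
  neural data) PCA fitted on training centers only;
- **Leave-one-center-out cross-validation (LOCOCV)** for the penalty λ,
  requiring at least one selected feature;
- **Hold-out permutation inference** — the frozen model is tested per
  hold-out center with one-sided permutation tests of the MAE;
- **Penalty-path robustness** — λ is raised in steps of 0.01 up to
  0.99; features robustly selected with the *same* weight sign for both
  outcomes are comorbidity markers, those with *opposing* signs are
  discriminators;
- **Signature reconstruction** — PC-space weights are projected back to
  voxel space (NIfTI export through a binary mask);
- **Stacked ensembling** — a second-level multitask model over
  first-level model estimates, with a paired Wilcoxon test of whether
  extra signatures improve per-subject absolute errors;
- **A synthetic multi-center generator** with planted ground truth,
  calibrated so the simulated ordinal outcomes reproduce weak
  cross-outcome Spearman correlations (ρ ≈ 0.28 pain–depression,
  ρ ≈ 0.34 pain–anxiety at n = 689).

## Worked example

```python
import numpy as np
from comorbmtl import (SimConfig, generate_dataset, split_centers, loco_cv,
                       refit_development, holdout_evaluation, robustness_path,
                       robust_support)

data, truth = generate_dataset(SimConfig(n_subjects=800, effect_size=0.5, seed=7))
dev_labels, hold_labels = split_centers(data.tasks[0].centers, seed=7)
dev, hold = data.subset_centers(dev_labels), data.subset_centers(hold_labels)

cv = loco_cv(dev)                     # LOCOCV over lambda = 0.01 ... 0.99
model = refit_development(dev, cv.selected_lambda)
perms = holdout_evaluation(model, hold, B=999, seed=7)
profile = robustness_path(dev, cv.selected_lambda)

print("selected lambda:", cv.selected_lambda)
for r in perms[:4]:
    print(f"center {r.center} {r.task}: MAE={r.observed_mae:.3f} p={r.p_value:.4g}")
print("robust support:", robust_support(profile).tolist())
print("planted support:", sorted(truth.support.tolist()))
```

prints

```
selected lambda: 0.19
center c1 pain: MAE=0.640 p=0.001
center c1 depression: MAE=0.586 p=0.001
center c3 pain: MAE=0.657 p=0.001
center c3 depression: MAE=0.704 p=0.001
robust support: [25, 37, 48, 60, 70, 84, 95]
planted support: [25, 37, 48, 60, 70, 84, 95]
```

The selected penalty keeps a small joint support; each hold-out center's
MAE (in standardized outcome units) beats its permutation null
(p = 0.001 is the smallest value attainable with B = 999), and the
penalty-path robust support exactly recovers the seven planted features.

The same workflow is scriptable from the shell:

```sh
comorbmtl simulate --n-subjects 800 --seed 7 --out sim/
comorbmtl cv --features sim/features.tsv --outcomes sim/outcomes.tsv \
             --centers sim/centers.tsv --out cv.tsv
comorbmtl run --config pipeline.yaml     # full end-to-end run
```

## Layout

| module            | contents                                              |
|-------------------|-------------------------------------------------------|
| `weighting`       | density-based sample weights R_j                      |
| `mtl_core`        | L2,1 multitask estimator (objective, prox, solver)    |
| `preprocessing`   | standardizer, PCA, signature back-projection, NIfTI   |
| `model_selection` | LOCOCV, model ranking, λ-path robustness, markers     |
| `inference`       | permutation tests, paired Wilcoxon                    |
| `ensemble`        | stacked second-level model, with/without comparison   |
| `synthetic`       | multi-center generator with planted ground truth      |
| `pipeline` / `cli`| I/O, center splits, gated hold-out access, runner     |

See `docs/methods.md` for the statistical details and design choices.
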