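"""Stacked ensemble of first-level neural and psychosocial models.

A second-level multitask model is trained whose features are the
first-level models' predictions: for task ``i`` (say, pain), feature
column ``m`` holds model ``m``'s estimate of task ``i`` for each
subject.  The first-level models stay frozen — they were fit on the
development centers — and the second level is trained on the hold-out
sample with leave-one-center-out cross-validation inside it, using the
same density-weighted L2,1 machinery as the first level.  Because the
hold-out sample doubles as the ensemble's training universe, ensemble
errors are cross-validated rather than tested on fresh centers.

Whether an extra signature (e.g., the neural ones) earns its place is
decided by a paired Wilcoxon test on per-subject absolute errors from
matched cross-validation folds, with and without the extra columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import (DEFAULT_B, PairedComparison, PermutationResult,
                        permutation_test, wilcoxon_paired)
from .model_selection import (CvResult, FittedPipeline, cv_subject_errors,
                              loco_cv, refit_development)
from .mtl_core import SolverOptions, TaskCollection, TaskData

__all__ = ["StackedDesign", "EnsembleResult", "build_stacked_design",
           "fit_stacked_ensemble", "compare_with_without"]


@dataclass
class StackedDesign:
    """Second-level design: per-task feature columns are first-level estimates."""

    first_level_labels: list[str]
    collection: TaskCollection

    @property
    def n_models(self) -> int:
        return len(self.first_level_labels)

    def drop_models(self, labels: list[str]) -> "StackedDesign":
        """A reduced design without the named first-level columns."""
        keep = [m for m, name in enumerate(self.first_level_labels) if name not in labels]
        if len(keep) == len(self.first_level_labels):
            raise ValueError(f"none of {labels} are in the design")
        tasks = [TaskData(t.features[:, keep], t.outcomes, t.task_id, t.centers)
                 for t in self.collection.tasks]
        names = [self.collection.feature_names[m] for m in keep]
        return StackedDesign([self.first_level_labels[m] for m in keep],
                             TaskCollection(tasks, names))


def build_stacked_design(first_level_models: dict[str, FittedPipeline],
                         data: TaskCollection) -> StackedDesign:
    """Assemble the second-level design from frozen first-level models.

    ``data`` holds the raw features and outcomes of the subjects the
    ensemble is trained on (the hold-out sample); each first-level model
    predicts both tasks for those subjects from its own feature space —
    all models here share ``data``'s feature tables.
    """
    labels = list(first_level_models)
    if not labels:
        raise ValueError("need at least one first-level model")
    per_task_cols: list[list[np.ndarray]] = [[] for _ in data.tasks]
    for name, model in first_level_models.items():
        if model.model.t != data.t:
            raise ValueError(
                f"first-level model {name!r} predicts {model.model.t} tasks, "
                f"data has {data.t}")
        preds = model.predict_standardized([t.features for t in data.tasks])
        for i in range(data.t):
            per_task_cols[i].append(preds[i])
    tasks = [TaskData(np.column_stack(per_task_cols[i]), task.outcomes,
                      task.task_id, task.centers)
             for i, task in enumerate(data.tasks)]
    return StackedDesign(labels, TaskCollection(tasks, labels))


@dataclass
class EnsembleResult:
    cv: CvResult
    model: FittedPipeline
    mae: dict[str, float]                 # per task, pooled over CV test folds
    permutation: list[PermutationResult]  # per task, on pooled CV predictions


def fit_stacked_ensemble(design: StackedDesign,
                         lambda_grid: np.ndarray | None = None,
                         weighting_exponent: float = 1.0,
                         B: int = DEFAULT_B, seed: int = 0,
                         options: SolverOptions | None = None) -> EnsembleResult:
    """Fit the second-level model with LOCOCV across the design's centers.

    Selects the penalty by mean cross-validated MSE (as at the first
    level), reports the per-task MAE pooled over test folds, and attaches
    a permutation test of that pooled MAE.
    """
    data = design.collection
    if data.center_labels().size < 2:
        raise ValueError("stacked ensemble needs at least 2 centers")
    cv = loco_cv(data, lambda_grid, weighting_exponent, use_pca=False,
                 options=options, label="stacked_ensemble")
    model = refit_development(data, cv.selected_lambda, weighting_exponent,
                              use_pca=False, options=options)
    errors = cv_subject_errors(data, cv.selected_lambda, weighting_exponent,
                               options=options)
    mae = {t.task_id: float(errors[i].mean()) for i, t in enumerate(data.tasks)}

    # permutation significance of the pooled cross-validated errors:
    # shuffle outcomes against the cross-validated predictions per task
    rng = np.random.default_rng(seed)
    perms = []
    for i, task in enumerate(data.tasks):
        # recover pooled predictions from |error| is lossy; recompute directly
        preds, ys = _pooled_cv_predictions(design, cv.selected_lambda,
                                           weighting_exponent, i, options)
        perms.append(permutation_test(ys, preds, B=B,
                                      seed=int(rng.integers(2**31 - 1)),
                                      task=task.task_id))
    return EnsembleResult(cv, model, mae, perms)


def _pooled_cv_predictions(design: StackedDesign, lam: float, exponent: float,
                           task_index: int,
                           options: SolverOptions | None) -> tuple[np.ndarray, np.ndarray]:
    from .model_selection import (_fit_transforms, _fold_weights,
                                  _transformed_collection)
    from .mtl_core import fit_mtl_path

    data = design.collection
    labels = data.center_labels()
    preds, ys = [], []
    for c in labels:
        train = data.subset_centers([x for x in labels if x != c])
        tf = _fit_transforms(train, False, "max", fold=str(c))
        train_std = _transformed_collection(train, tf)
        weights = _fold_weights(train_std, exponent)
        fit = fit_mtl_path(train_std, [lam], weights, options)[float(lam)]
        task = data.subset_centers([c]).tasks[task_index]
        X = tf.transform_features(task.features)
        preds.append(X @ fit.values[:, task_index])
        ys.append(tf.transform_outcomes(task_index, task.outcomes))
    return np.concatenate(preds), np.concatenate(ys)


def compare_with_without(design_full: StackedDesign, design_reduced: StackedDesign,
                         lambda_grid: np.ndarray | None = None,
                         weighting_exponent: float = 1.0,
                         options: SolverOptions | None = None) -> list[PairedComparison]:
    """Paired comparison of the full vs reduced stacked designs.

    Both designs are cross-validated with identical center folds on the
    same subjects; per task, per-subject absolute errors at each design's
    own selected penalty are compared with the Wilcoxon signed-rank test.
    ``delta_mae = MAE_full - MAE_reduced`` (negative favors the full design).
    """
    full, red = design_full.collection, design_reduced.collection
    if set(design_reduced.first_level_labels) - set(design_full.first_level_labels):
        raise ValueError("reduced design must be a subset of the full design")
    for tf_, tr_ in zip(full.tasks, red.tasks):
        if tf_.n != tr_.n or not np.array_equal(tf_.centers, tr_.centers):
            raise ValueError("designs must share subjects and fold structure")

    out = []
    errs = {}
    for name, design in (("full", design_full), ("reduced", design_reduced)):
        cv = loco_cv(design.collection, lambda_grid, weighting_exponent,
                     options=options, label=name)
        errs[name] = cv_subject_errors(design.collection, cv.selected_lambda,
                                       weighting_exponent, options=options)
    for i, task in enumerate(full.tasks):
        out.append(wilcoxon_paired(errs["full"][i], errs["reduced"][i],
                                   task=task.task_id))
    return out
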