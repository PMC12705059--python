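"""Leave-one-center-out model selection and lambda-path robustness.

Model selection respects the multi-center structure of the data:
each cross-validation fold holds out every subject from one acquisition
center, transforms (standardization, PCA) and density weights are
re-estimated on the training centers only, and the penalty ``lambda`` is
chosen to minimize the mean test MSE (mean over folds, then over tasks)
among *admissible* penalties — those whose refit on the full development
set selects at least one feature.  Ties go to the larger penalty
(the sparser model).

The robustness procedure then increases the penalty in steps of 0.01
from the selected value up to 0.99, refitting on the full development
set at each step, and counts how often each feature survives.  A feature
that is robustly selected with the *same* weight sign for both outcomes
is a comorbidity marker; one with *opposing* signs discriminates between
the two conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mtl_core import (CoefficientMatrix, SolverOptions, TaskCollection,
                       TaskData, fit_mtl_path, selected_features)
from .preprocessing import (PcaTransform, Standardizer, apply_pca,
                            apply_standardizer, fit_pca, fit_standardizer)
from .weighting import DensityWeights, compute_density_weights

__all__ = [
    "default_lambda_grid", "FoldTransforms", "FittedPipeline", "CvResult",
    "RobustnessProfile", "loco_cv", "refit_development", "cv_subject_errors",
    "rank_models", "robustness_path", "classify_markers", "display_filter",
]


def default_lambda_grid() -> np.ndarray:
    """The 0.01-step grid {0.01, ..., 0.99} used for LOCOCV."""
    return np.round(np.arange(0.01, 1.0, 0.01), 2)


# ---------------------------------------------------------------------------
# fold transforms
# ---------------------------------------------------------------------------

@dataclass
class FoldTransforms:
    """Training-set transforms for one fold: feature and outcome scaling, PCA.

    Feature parameters are fitted on the stacked training rows of all
    tasks (tasks share one feature space); outcome scaling is per task.
    Applying these to held-out rows uses training parameters only.
    """

    feature_std: Standardizer
    outcome_std: list[Standardizer]
    pca: PcaTransform | None = None

    def transform_features(self, X: np.ndarray) -> np.ndarray:
        Z = apply_standardizer(self.feature_std, X)
        if self.pca is not None:
            Z = apply_pca(self.pca, Z)
        return Z

    def transform_outcomes(self, task_index: int, y: np.ndarray) -> np.ndarray:
        s = self.outcome_std[task_index]
        return ((np.asarray(y, dtype=float) - s.means[0]) / s.sds[0])


def _fit_transforms(train: TaskCollection, use_pca: bool,
                    pca_k: int | str, fold: str = "") -> FoldTransforms:
    X_all = np.vstack([task.features for task in train.tasks])
    fstd = fit_standardizer(X_all, fold=fold)
    pca = fit_pca(apply_standardizer(fstd, X_all), pca_k) if use_pca else None
    ostd = [fit_standardizer(task.outcomes[:, None], fold=fold) for task in train.tasks]
    return FoldTransforms(fstd, ostd, pca)


def _transformed_collection(data: TaskCollection, tf: FoldTransforms) -> TaskCollection:
    tasks = []
    for i, task in enumerate(data.tasks):
        tasks.append(TaskData(tf.transform_features(task.features),
                              tf.transform_outcomes(i, task.outcomes),
                              task.task_id, task.centers))
    names = (list(data.feature_names) if tf.pca is None
             else [f"PC{j + 1}" for j in range(tf.pca.k)])
    return TaskCollection(tasks, names)


def _fold_weights(train_std: TaskCollection, exponent: float) -> list[DensityWeights]:
    return [compute_density_weights(task.outcomes, exponent) for task in train_std.tasks]


@dataclass
class FittedPipeline:
    """A model refit on the full development set, with its transforms.

    Bundles everything needed to score raw held-out subjects: the
    development-set standardizers (features and outcomes), the optional
    PCA, the density-weight exponent, and the coefficient matrix at the
    selected penalty.
    """

    transforms: FoldTransforms
    model: CoefficientMatrix
    weighting_exponent: float
    task_ids: list[str]

    def predict_standardized(self, features: list[np.ndarray]) -> list[np.ndarray]:
        """Per-task predictions in development-standardized outcome units."""
        if len(features) != self.model.t:
            raise ValueError("one raw feature matrix per task required")
        return [self.transforms.transform_features(X) @ self.model.values[:, i]
                for i, X in enumerate(features)]


def refit_development(data: TaskCollection, lam: float,
                      weighting_exponent: float = 1.0, use_pca: bool = False,
                      pca_k: int | str = "max",
                      options: SolverOptions | None = None) -> FittedPipeline:
    """Refit at one penalty on the full development set."""
    tf = _fit_transforms(data, use_pca, pca_k, fold="development")
    std = _transformed_collection(data, tf)
    weights = _fold_weights(std, weighting_exponent)
    fits = fit_mtl_path(std, [lam], weights, options)
    return FittedPipeline(tf, fits[float(lam)], weighting_exponent, data.task_ids)


# ---------------------------------------------------------------------------
# LOCOCV
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-lambda LOCOCV errors and the selected penalty."""

    lambda_grid: np.ndarray               # ascending
    fold_errors: np.ndarray               # (n_lambda, n_folds, t) unweighted MSE
    mean_mse: np.ndarray                  # (n_lambda,) mean over folds then tasks
    admissible: np.ndarray                # (n_lambda,) bool, >=1 feature on dev refit
    n_selected: np.ndarray                # (n_lambda,) dev-refit support size
    selected_lambda: float
    fold_centers: list
    task_ids: list[str]
    label: str = ""

    @property
    def selected_mse(self) -> float:
        idx = int(np.flatnonzero(np.isclose(self.lambda_grid, self.selected_lambda))[0])
        return float(self.mean_mse[idx])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "lambda": self.lambda_grid,
            "mean_mse": self.mean_mse,
            "admissible": self.admissible,
            "n_selected": self.n_selected,
            **{f"mse_fold_{c}_{t}": self.fold_errors[:, f, i]
               for f, c in enumerate(self.fold_centers)
               for i, t in enumerate(self.task_ids)},
        })


def _check_centers(data: TaskCollection) -> np.ndarray:
    labels = data.center_labels()
    if labels.size < 2:
        raise ValueError("LOCOCV needs at least 2 centers")
    for task in data.tasks:
        counts = {c: int((task.centers == c).sum()) for c in labels}
        small = [c for c, k in counts.items() if k < 2]
        if small:
            raise ValueError(f"centers with fewer than 2 subjects: {small}")
    return labels


def loco_cv(data: TaskCollection, lambda_grid: np.ndarray | None = None,
            weighting_exponent: float = 1.0, use_pca: bool = False,
            pca_k: int | str = "max", options: SolverOptions | None = None,
            label: str = "") -> CvResult:
    """Leave-one-center-out cross-validation over a lambda grid.

    Each fold holds out one entire center; transforms and density weights
    come from the training centers only; test MSE is unweighted.  The
    selected lambda minimizes the mean MSE among admissible penalties
    (at least one feature selected in the full-development refit), ties
    broken toward the larger (sparser) penalty.
    """
    labels = _check_centers(data)
    grid = np.sort(np.asarray(default_lambda_grid() if lambda_grid is None
                              else lambda_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty lambda grid")

    fold_errors = np.empty((grid.size, labels.size, data.t))
    for f, c in enumerate(labels):
        train = data.subset_centers([x for x in labels if x != c])
        test = data.subset_centers([c])
        tf = _fit_transforms(train, use_pca, pca_k, fold=str(c))
        train_std = _transformed_collection(train, tf)
        weights = _fold_weights(train_std, weighting_exponent)
        fits = fit_mtl_path(train_std, grid, weights, options)
        W_path = np.stack([fits[lam].values for lam in grid])  # (n_lambda, p, t)
        for i, task in enumerate(test.tasks):
            X = tf.transform_features(task.features)
            y = tf.transform_outcomes(i, task.outcomes)
            resid = X @ W_path[:, :, i].T - y[:, None]        # (n_test, n_lambda)
            fold_errors[:, f, i] = np.mean(resid**2, axis=0)

    # admissibility from the full-development refit at each lambda
    tf_dev = _fit_transforms(data, use_pca, pca_k, fold="development")
    dev_std = _transformed_collection(data, tf_dev)
    dev_weights = _fold_weights(dev_std, weighting_exponent)
    dev_fits = fit_mtl_path(dev_std, grid, dev_weights, options)
    tol = (options or SolverOptions()).selection_tolerance
    n_selected = np.array([selected_features(dev_fits[lam], tol).size for lam in grid])
    admissible = n_selected >= 1

    mean_mse = fold_errors.mean(axis=1).mean(axis=1)
    if not admissible.any():
        raise ValueError(
            "no admissible lambda: every penalty on the grid selects zero "
            f"features (grid [{grid[0]:g}, {grid[-1]:g}]); extend the grid "
            "toward smaller values")
    best = np.min(mean_mse[admissible])
    candidates = np.flatnonzero(admissible & (mean_mse == best))
    selected = float(grid[candidates[-1]])  # ties -> larger lambda

    return CvResult(grid, fold_errors, mean_mse, admissible, n_selected,
                    selected, list(labels), data.task_ids, label)


def cv_subject_errors(data: TaskCollection, lam: float,
                      weighting_exponent: float = 1.0, use_pca: bool = False,
                      pca_k: int | str = "max",
                      options: SolverOptions | None = None) -> np.ndarray:
    """Per-subject absolute test errors at one penalty, across LOCOCV folds.

    Returns an array of shape (t, n) aligned with each task's original row
    order (every subject appears in exactly one test fold), in the training
    fold's standardized outcome units.  Used for paired model comparisons.
    """
    labels = _check_centers(data)
    n = data.tasks[0].n
    out = np.full((data.t, n), np.nan)
    for c in labels:
        train = data.subset_centers([x for x in labels if x != c])
        tf = _fit_transforms(train, use_pca, pca_k, fold=str(c))
        train_std = _transformed_collection(train, tf)
        weights = _fold_weights(train_std, weighting_exponent)
        fits = fit_mtl_path(train_std, [lam], weights, options)
        W = fits[float(lam)].values
        for i, task in enumerate(data.tasks):
            mask = task.centers == c
            X = tf.transform_features(task.features[mask])
            y = tf.transform_outcomes(i, task.outcomes[mask])
            out[i, mask] = np.abs(X @ W[:, i] - y)
    if np.isnan(out).any():
        raise RuntimeError("fold partition did not cover every subject")
    return out


def rank_models(results: list[CvResult], top_k: int = 3) -> list[CvResult]:
    """Order candidate models by their selected-lambda mean MSE; keep top_k.

    Ties are broken by model label, deterministically.
    """
    if top_k > len(results):
        warnings.warn(f"top_k={top_k} exceeds the {len(results)} candidates; "
                      "returning all", RuntimeWarning)
        top_k = len(results)
    ranked = sorted(results, key=lambda r: (r.selected_mse, r.label))
    return ranked[:top_k]


# ---------------------------------------------------------------------------
# lambda-path robustness
# ---------------------------------------------------------------------------

TAG_MARKER = "comorbidity_marker"
TAG_DISCRIMINATOR = "discriminator"
TAG_UNSTABLE = "unstable"
TAG_NEVER = "never_selected"


@dataclass
class RobustnessProfile:
    """Selection counts and weight signs along the increasing-penalty path."""

    lambda_path: np.ndarray               # ascending, step 0.01 by default
    selected: np.ndarray                  # (n_lambda, p) bool
    signs: np.ndarray                     # (n_lambda, p, t) int8; 0 where unselected
    start_weights: np.ndarray             # (p, t) fitted W at the path start
    feature_names: list[str]
    task_ids: list[str]
    classification: list[str] = field(default_factory=list)

    @property
    def selection_counts(self) -> np.ndarray:
        return self.selected.sum(axis=0)

    @property
    def robustness_fraction(self) -> np.ndarray:
        counts = self.selection_counts
        m = counts.max(initial=0)
        return counts / m if m > 0 else counts.astype(float)

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame({
            "feature": self.feature_names,
            "count": self.selection_counts,
            "robustness": self.robustness_fraction,
            "tag": self.classification,
        })
        for i, t in enumerate(self.task_ids):
            df[f"weight_{t}"] = self.start_weights[:, i]
        return df


def robustness_path(data: TaskCollection, start_lambda: float,
                    step: float = 0.01, end_lambda: float = 0.99,
                    weighting_exponent: float = 1.0, use_pca: bool = False,
                    pca_k: int | str = "max",
                    options: SolverOptions | None = None) -> RobustnessProfile:
    """Refit along an increasing penalty path and record selections and signs.

    Fits use the full development set (transforms and density weights
    recomputed on it); the path runs from ``start_lambda`` (normally the
    LOCOCV-selected penalty) to ``end_lambda`` in ``step`` increments.
    """
    if not 0 < start_lambda <= end_lambda <= 0.99 + 1e-12:
        raise ValueError("need 0 < start_lambda <= end_lambda <= 0.99")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(np.floor((end_lambda - start_lambda) / step + 1e-9)) + 1
    path = np.round(start_lambda + step * np.arange(n_steps), 10)

    tf = _fit_transforms(data, use_pca, pca_k, fold="development")
    std = _transformed_collection(data, tf)
    weights = _fold_weights(std, weighting_exponent)
    fits = fit_mtl_path(std, path, weights, options)
    tol = (options or SolverOptions()).selection_tolerance

    p, t = std.p, std.t
    selected = np.zeros((path.size, p), dtype=bool)
    signs = np.zeros((path.size, p, t), dtype=np.int8)
    for g, lam in enumerate(path):
        W = fits[lam].values
        sel = selected_features(fits[lam], tol)
        selected[g, sel] = True
        signs[g, sel, :] = np.sign(W[sel, :]).astype(np.int8)

    profile = RobustnessProfile(path, selected, signs,
                                fits[path[0]].values.copy(),
                                list(std.feature_names), data.task_ids)
    profile.classification = classify_markers(profile)
    return profile


def classify_markers(profile: RobustnessProfile) -> list[str]:
    """Tag each feature from its sign record along the penalty path.

    comorbidity_marker: selected at least once, and with the same nonzero
    weight sign for both tasks at *every* penalty where it is selected;
    discriminator: opposing nonzero signs at every selected penalty;
    unstable: any mixed or degenerate (exactly-zero) sign pattern;
    never_selected otherwise.
    """
    tags = []
    n_lambda, p = profile.selected.shape
    for j in range(p):
        rows = np.flatnonzero(profile.selected[:, j])
        if rows.size == 0:
            tags.append(TAG_NEVER)
            continue
        s = profile.signs[rows, j, :]  # (k, t)
        nonzero = np.all(s != 0, axis=1)
        same = nonzero & np.all(s == s[:, :1], axis=1)
        opposing = nonzero & ~np.all(s == s[:, :1], axis=1)
        if same.all():
            tags.append(TAG_MARKER)
        elif opposing.all():
            tags.append(TAG_DISCRIMINATOR)
        else:
            tags.append(TAG_UNSTABLE)
    return tags


def robust_support(profile: RobustnessProfile,
                   min_fraction: float = 0.5) -> np.ndarray:
    """The pipeline's support estimate: features surviving most of the path.

    A single prediction-optimal penalty routinely admits weakly
    correlated null features alongside the true ones; the robustness
    path is the designed remedy.  A feature belongs to the robust
    support when it is selected in at least ``min_fraction`` of the
    path fits, relative to the most robust feature (majority rule by
    default).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    return np.flatnonzero(profile.robustness_fraction >= min_fraction)


def display_filter(profile: RobustnessProfile,
                   weights_at_start: np.ndarray | None = None) -> np.ndarray:
    """Feature subset worth displaying, per the dual 10% rule.

    Keeps features selected at least 10% as often as the most robust
    feature AND whose largest per-task |weight| at the path start is at
    least 10% of the overall largest |weight|.
    """
    W = profile.start_weights if weights_at_start is None else np.asarray(weights_at_start)
    frac = profile.robustness_fraction
    max_abs = np.abs(W).max(axis=1)
    global_max = np.abs(W).max(initial=0.0)
    keep = (frac >= 0.10) & (max_abs >= 0.10 * global_max)
    return np.flatnonzero(keep)
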