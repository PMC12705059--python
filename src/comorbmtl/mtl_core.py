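"""Weighted multitask least squares with L2,1 (joint-sparsity) regularization.

The estimator couples ``t`` regression tasks (here: two symptom-severity
outcomes measured on the same subjects) through row sparsity of the
coefficient matrix ``W`` (features x tasks):

    min_W  sum_i (1/n_i) sum_j R_ij (x_ij . W_i - y_ij)^2  +  lambda * ||W||_{2,1}

where ``||W||_{2,1} = sum_g ||W[g, :]||_2`` sums the Euclidean norms of the
feature rows, ``R_ij`` are density-based training weights
(:mod:`comorbmtl.weighting`) that sum to ``n_i`` within each task, and
``lambda >= 0`` controls how many feature rows survive.  Because a whole
row is shrunk or zeroed at once, a feature is selected for all tasks or
for none — the knowledge transfer acts through *which* features are
kept, not through the per-task weight values.

The objective is convex; it is minimized by a monotone accelerated
proximal-gradient method (FISTA with a backtracking line search and the
monotone safeguard of Beck & Teboulle).  The data term is quadratic, so
Gram matrices ``X_i' R X_i`` are precomputed once per (data, weights)
pair and every iteration costs ``O(p^2 t)`` regardless of the number of
subjects; fitting a whole lambda path with warm starts is then cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .weighting import DensityWeights

__all__ = [
    "TaskData",
    "TaskCollection",
    "CoefficientMatrix",
    "SolverOptions",
    "l21_norm",
    "prox_l21",
    "objective",
    "lambda_max",
    "fit_mtl",
    "fit_mtl_path",
    "predict",
    "selected_features",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TaskData:
    """One regression task: features, outcomes and (optional) center labels."""

    features: np.ndarray
    outcomes: np.ndarray
    task_id: str = ""
    centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.outcomes = np.asarray(self.outcomes, dtype=float).ravel()
        if self.features.shape[0] != self.outcomes.size:
            raise ValueError(
                f"task {self.task_id!r}: {self.features.shape[0]} feature rows "
                f"vs {self.outcomes.size} outcomes")
        if not np.all(np.isfinite(self.features)) or not np.all(np.isfinite(self.outcomes)):
            raise ValueError(f"task {self.task_id!r}: non-finite values in inputs")
        if self.centers is not None:
            self.centers = np.asarray(self.centers)
            if self.centers.size != self.outcomes.size:
                raise ValueError(f"task {self.task_id!r}: center labels misaligned")

    @property
    def n(self) -> int:
        return self.outcomes.size

    @property
    def p(self) -> int:
        return self.features.shape[1]


@dataclass
class TaskCollection:
    """An ordered set of tasks sharing one feature space."""

    tasks: list[TaskData]
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("a TaskCollection needs at least one task")
        p = self.tasks[0].p
        for task in self.tasks:
            if task.p != p:
                raise ValueError("all tasks must share the same feature count")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal the feature count")

    @property
    def t(self) -> int:
        return len(self.tasks)

    @property
    def p(self) -> int:
        return self.tasks[0].p

    @property
    def task_ids(self) -> list[str]:
        return [task.task_id for task in self.tasks]

    def center_labels(self) -> np.ndarray:
        """Sorted unique center labels across all tasks."""
        labels: list = []
        for task in self.tasks:
            if task.centers is None:
                raise ValueError("tasks carry no center labels")
            labels.append(np.unique(task.centers))
        return np.unique(np.concatenate(labels))

    def subset_centers(self, keep: Sequence) -> "TaskCollection":
        """Restrict every task to subjects whose center is in ``keep``."""
        keep_set = set(np.asarray(keep).tolist())
        tasks = []
        for task in self.tasks:
            if task.centers is None:
                raise ValueError("tasks carry no center labels")
            mask = np.array([c in keep_set for c in task.centers])
            tasks.append(TaskData(task.features[mask], task.outcomes[mask],
                                  task.task_id, task.centers[mask]))
        return TaskCollection(tasks, list(self.feature_names))


@dataclass
class SolverOptions:
    max_iterations: int = 5000
    rel_tolerance: float = 1e-8
    selection_tolerance: float = 1e-10
    backtrack_factor: float = 0.5
    keep_trace: bool = True

    def __post_init__(self) -> None:
        if (self.max_iterations <= 0 or self.rel_tolerance <= 0
                or self.selection_tolerance < 0
                or not 0 < self.backtrack_factor < 1):
            raise ValueError("invalid solver options")


@dataclass
class CoefficientMatrix:
    """Fitted coefficients W (p x t) plus solver diagnostics."""

    values: np.ndarray
    lam: float
    converged: bool = True
    n_iterations: int = 0
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# norm / prox / objective
# ---------------------------------------------------------------------------

def l21_norm(W: np.ndarray) -> float:
    """Sum over feature rows of the Euclidean norm across tasks."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    return float(np.linalg.norm(W, axis=1).sum())


def prox_l21(W: np.ndarray, threshold: float) -> np.ndarray:
    """Row-wise group soft-thresholding: the proximal map of ``threshold * ||.||_{2,1}``."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    norms = np.linalg.norm(W, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > threshold, 1.0 - threshold / norms, 0.0)
    return W * scale[:, None]


def _weight_arrays(data: TaskCollection,
                   weights: Sequence[DensityWeights | np.ndarray] | None) -> list[np.ndarray]:
    if weights is None:
        return [np.ones(task.n) for task in data.tasks]
    if len(weights) != data.t:
        raise ValueError("one weight vector per task required")
    out = []
    for task, w in zip(data.tasks, weights):
        arr = w.weights if isinstance(w, DensityWeights) else np.asarray(w, dtype=float)
        if arr.size != task.n:
            raise ValueError(f"weights misaligned for task {task.task_id!r}")
        out.append(arr)
    return out


def objective(W: np.ndarray, data: TaskCollection,
              weights: Sequence[DensityWeights | np.ndarray] | None,
              lam: float) -> float:
    """Weighted multitask objective, evaluated directly from residuals."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape != (data.p, data.t):
        raise ValueError(f"W has shape {W.shape}, expected {(data.p, data.t)}")
    R = _weight_arrays(data, weights)
    total = 0.0
    for i, task in enumerate(data.tasks):
        resid = task.features @ W[:, i] - task.outcomes
        total += float((R[i] * resid**2).sum()) / task.n
    return total + lam * l21_norm(W)


# ---------------------------------------------------------------------------
# quadratic form (Gram precomputation)
# ---------------------------------------------------------------------------

class _QuadLoss:
    """The smooth data term as per-task quadratics 0.5 w'Aw - b'w + c."""

    def __init__(self, data: TaskCollection,
                 weights: Sequence[DensityWeights | np.ndarray] | None):
        R = _weight_arrays(data, weights)
        A_list, b_list = [], []
        self.c = 0.0
        for task, r in zip(data.tasks, R):
            Xw = task.features * r[:, None]
            A_list.append((2.0 / task.n) * (task.features.T @ Xw))
            b_list.append((2.0 / task.n) * (Xw.T @ task.outcomes))
            self.c += float((r * task.outcomes**2).sum()) / task.n
        self.A = np.stack(A_list)          # (t, p, p)
        self.b = np.stack(b_list).T        # (p, t)
        self.t, self.p = self.A.shape[0], self.A.shape[1]
        # gradient Lipschitz constant: largest eigenvalue over tasks
        self.lipschitz = max(
            (float(np.linalg.eigvalsh(A)[-1]) if A.size else 0.0) for A in A_list)

    def value(self, W: np.ndarray) -> float:
        AW = self._AW(W)
        return self.c + 0.5 * float((W * AW).sum()) - float((self.b * W).sum())

    def _AW(self, W: np.ndarray) -> np.ndarray:
        # (t,p,p) @ (t,p,1) -> (p,t) in one matmul call
        return np.matmul(self.A, W.T[:, :, None])[:, :, 0].T

    def grad(self, W: np.ndarray) -> np.ndarray:
        return self._AW(W) - self.b

    def grad_at_zero_rownorms(self) -> np.ndarray:
        return np.linalg.norm(self.b, axis=1)


def lambda_max(data: TaskCollection,
               weights: Sequence[DensityWeights | np.ndarray] | None = None) -> float:
    """Smallest penalty at which the all-zero coefficient matrix is optimal.

    From the stationarity condition at ``W = 0``: the zero matrix solves the
    problem iff every row of the gradient of the data term at the origin has
    Euclidean norm at most ``lambda``.
    """
    return float(_QuadLoss(data, weights).grad_at_zero_rownorms().max(initial=0.0))


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _prox_rows(W: np.ndarray, threshold: float) -> tuple[np.ndarray, float]:
    """Group soft-threshold rows; also return the result's L2,1 norm."""
    norms = np.sqrt(np.einsum("ij,ij->i", W, W))
    np.maximum(norms, 1e-300, out=norms)
    scale = np.maximum(0.0, 1.0 - threshold / norms)
    out = W * scale[:, None]
    return out, float((norms * scale).sum())


def _fista(quad: _QuadLoss, lam: float, options: SolverOptions,
           W0: np.ndarray | None) -> CoefficientMatrix:
    p, t = quad.p, quad.t
    W = np.zeros((p, t)) if W0 is None else np.array(W0, dtype=float)
    Z = W.copy()
    tk = 1.0
    L = max(quad.lipschitz, 1e-12)
    step = 1.0 / L
    F_W = quad.value(W) + lam * l21_norm(W)
    trace = [F_W]
    F_cand_prev = np.inf
    V_prev: np.ndarray | None = None
    converged = False
    n_iter = 0

    for n_iter in range(1, options.max_iterations + 1):
        G = quad.grad(Z)
        fZ = quad.value(Z)
        # backtracking on the quadratic majorization (with an exact quadratic
        # loss and step = 1/L this accepts immediately; kept as a safeguard)
        while True:
            V, V_norm = _prox_rows(Z - step * G, step * lam)
            D = V - Z
            fV = quad.value(V)
            if fV <= fZ + float((G * D).sum()) + float((D * D).sum()) / (2 * step) + 1e-12:
                break
            step *= options.backtrack_factor
        F_V = fV + lam * V_norm

        # monotone safeguard: the accepted iterate never increases the objective
        if F_V <= F_W:
            W_new = V
            F_new = F_V
        else:
            W_new = W
            F_new = F_W
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        Z = W_new + (tk / tk_new) * (V - W_new) + ((tk - 1.0) / tk_new) * (W_new - W)
        W, F_W, tk = W_new, F_new, tk_new
        if options.keep_trace:
            trace.append(F_W)

        # converge on both the objective and the iterate: the objective can
        # flatten out well before the coefficients settle
        obj_ok = abs(F_V - F_cand_prev) <= options.rel_tolerance * max(1.0, abs(F_V))
        par_ok = (V_prev is not None and
                  float(np.abs(V - V_prev).max()) <=
                  options.rel_tolerance * max(1.0, float(np.abs(V).max())))
        if obj_ok and par_ok:
            converged = True
            break
        F_cand_prev = F_V
        V_prev = V

    if not converged:
        warnings.warn(
            f"MTL solver did not converge in {options.max_iterations} iterations "
            f"(lambda={lam:g})", RuntimeWarning)
    return CoefficientMatrix(W, lam, converged, n_iter, np.asarray(trace))


def fit_mtl(data: TaskCollection, lam: float,
            weights: Sequence[DensityWeights | np.ndarray] | None = None,
            options: SolverOptions | None = None,
            warm_start: np.ndarray | None = None) -> CoefficientMatrix:
    """Fit the weighted L2,1-regularized multitask regression at one ``lambda``.

    Features and outcomes are expected standardized (no intercept is fit;
    centering upstream absorbs it).  Initialization is ``W = 0`` unless a
    ``warm_start`` matrix is given.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    options = options or SolverOptions()
    quad = _QuadLoss(data, weights)
    return _fista(quad, lam, options, warm_start)


def fit_mtl_path(data: TaskCollection, lambdas: Sequence[float],
                 weights: Sequence[DensityWeights | np.ndarray] | None = None,
                 options: SolverOptions | None = None) -> dict[float, CoefficientMatrix]:
    """Fit a whole lambda path with shared Gram matrices and warm starts.

    The path is solved from the largest penalty downward (sparse solutions
    first), each fit warm-started from its predecessor; results are keyed
    by the requested lambda values.
    """
    options = options or SolverOptions()
    quad = _QuadLoss(data, weights)
    out: dict[float, CoefficientMatrix] = {}
    W_prev: np.ndarray | None = None
    for lam in sorted(set(float(l) for l in lambdas), reverse=True):
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        fit = _fista(quad, lam, options, W_prev)
        out[lam] = fit
        W_prev = fit.values
    return out


def predict(model: CoefficientMatrix,
            features: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Per-task linear predictions ``X_i W_i`` (no intercept)."""
    if len(features) != model.t:
        raise ValueError("one feature matrix per task required")
    preds = []
    for i, X in enumerate(features):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != model.p:
            raise ValueError(f"task {i}: {X.shape[1]} features, model has {model.p}")
        preds.append(X @ model.values[:, i])
    return preds


def selected_features(model: CoefficientMatrix, tolerance: float = 1e-10) -> np.ndarray:
    """Indices of feature rows with Euclidean norm above ``tolerance``.

    Selection is joint across tasks: a feature either contributes to every
    task's signature or to none.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    return np.flatnonzero(np.linalg.norm(model.values, axis=1) > tolerance)
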