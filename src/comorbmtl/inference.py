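"""Hold-out inference: one-sided permutation tests and paired Wilcoxon.

The generalization test never fits anything on hold-out centers: a model
frozen on the development set predicts each hold-out center's subjects,
and the mean absolute error (MAE) is compared with a permutation null
obtained by shuffling the observed outcomes within the center while
keeping the predictions fixed.  The one-sided p-value

    p = (1 + #{null MAE <= observed MAE}) / (1 + B)

is small when the predictions align with the outcomes better than
chance; the +1 smoothing keeps p strictly positive at finite B.

The paired Wilcoxon signed-rank test compares two models' per-subject
absolute errors on the same subjects (zero differences dropped, ties
mid-ranked; exact null for up to 25 informative pairs, normal
approximation with continuity correction beyond).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mtl_core import TaskCollection
from .model_selection import FittedPipeline

__all__ = ["PermutationResult", "PairedComparison", "permutation_test",
           "holdout_evaluation", "wilcoxon_paired"]

#: permutation count used in the headline analyses
DEFAULT_B = 10_000
ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class PermutationResult:
    """One-sided permutation test of a prediction's MAE on held-out subjects."""

    observed_mae: float
    null_maes: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    center: str = ""
    task: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class PairedComparison:
    """Wilcoxon signed-rank comparison of two models' absolute errors."""

    delta_mae: float
    statistic: float          # V: sum of ranks of positive differences
    p_value: float
    n_pairs: int              # informative (nonzero-difference) pairs
    zeros_dropped: int
    degenerate: bool = False
    task: str = ""


def permutation_test(y_true: np.ndarray, y_pred: np.ndarray, B: int = DEFAULT_B,
                     seed: int = 0, center: str = "", task: str = "") -> PermutationResult:
    """Permutation null for the MAE: shuffle outcomes, keep predictions fixed."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 subjects")
    if B < 1:
        raise ValueError("B must be at least 1")

    observed = float(np.mean(np.abs(y_pred - y_true)))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(y_true, (B, y_true.size)), axis=1)
    null = np.mean(np.abs(perms - y_pred), axis=1)
    p = (1 + int(np.sum(null <= observed + 1e-12))) / (1 + B)
    return PermutationResult(observed, null, p, B, seed, center, task)


def holdout_evaluation(final_model: FittedPipeline, holdout: TaskCollection,
                       B: int = DEFAULT_B, seed: int = 0) -> list[PermutationResult]:
    """Evaluate a frozen development model per hold-out center and task.

    Hold-out features and outcomes are transformed with the development
    standardizers; the permutation is performed within each center
    separately (matching the per-center reporting of hold-out results).
    """
    labels = holdout.center_labels()
    results = []
    rng = np.random.default_rng(seed)
    for c in labels:
        sub = holdout.subset_centers([c])
        preds = final_model.predict_standardized([t.features for t in sub.tasks])
        for i, task in enumerate(sub.tasks):
            y_std = final_model.transforms.transform_outcomes(i, task.outcomes)
            results.append(permutation_test(
                y_std, preds[i], B=B, seed=int(rng.integers(2**31 - 1)),
                center=str(c), task=task.task_id))
    return results


def _exact_signed_rank_p(ranks: np.ndarray, v_plus: float) -> float:
    """Exact two-sided signed-rank p with mid-ranks, by convolution.

    Mid-ranks are multiples of 1/2, so doubling them gives integers and
    the null distribution of 2*V+ over all sign assignments is a simple
    polynomial product, computed by dynamic programming.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        new = dist.copy()
        new[r:] += dist[:total + 1 - r]
        dist = new
    dist /= dist.sum()
    v2 = int(round(2 * v_plus))
    p_low = float(dist[:v2 + 1].sum())
    p_high = float(dist[v2:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_paired(errors_a: np.ndarray, errors_b: np.ndarray,
                    task: str = "") -> PairedComparison:
    """Paired Wilcoxon signed-rank test on per-subject error differences.

    ``delta_mae`` is mean(errors_a) - mean(errors_b) over all pairs
    (negative when model a has the smaller errors).  The statistic V is
    the sum of the mid-ranks of the positive differences among the
    informative pairs.
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired error vectors must have equal length")
    if a.size == 0:
        raise ValueError("empty error vectors")
    d = a - b
    delta = float(np.mean(d))
    nonzero = d != 0
    zeros = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        return PairedComparison(delta, 0.0, 1.0, 0, zeros, degenerate=True, task=task)

    ranks = stats.rankdata(np.abs(d))
    v_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, v_plus)
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided", method="approx")
        p = float(res.pvalue)
    return PairedComparison(delta, v_plus, p, n, zeros, task=task)
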