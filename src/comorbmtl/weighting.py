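"""Density-based sample weights for imbalanced outcomes.

Skewed ordinal outcomes (most subjects reporting little or no pain,
depression or anxiety) leave a squared-error fit dominated by the common
low scores.  Density-based weighting counteracts this by up-weighting
subjects whose outcome value is rare in the training set:

    R_j = C_j^x * n / sum_j C_j^x,      C_j = 1 - f_j,

where ``f_j`` is the relative frequency of subject ``j``'s outcome value
among the ``n`` training subjects and ``x >= 0`` tunes the strength of
the reweighting (``x = 0`` disables it).  The weights always sum to
``n``, so a weighted mean squared error stays on the same scale as the
unweighted one and the regularization strength remains comparable
across folds of different size.

Weights are a training-time device only: they are recomputed per task
and per training fold, and evaluation metrics are always unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DensityWeights", "compute_density_weights"]

#: decimal places used when matching outcome values to count frequencies;
#: outcomes here are (standardized) ordinal scores, so exact matching after
#: mild rounding is the intended behaviour.
FREQUENCY_DECIMALS = 10


@dataclass(frozen=True)
class DensityWeights:
    """Per-subject training weights derived from outcome frequency.

    Attributes
    ----------
    weights:
        Nonnegative weights ``R_j``; sum to ``n``.
    exponent:
        The reweighting exponent ``x``.
    frequencies:
        Relative frequency ``f_j`` of each subject's outcome value.
    complements:
        ``C_j = 1 - f_j``.
    n:
        Number of training subjects.
    fallback:
        True when all outcomes were identical and ``x > 0``; in that
        degenerate case uniform unit weights are returned.
    """

    weights: np.ndarray
    exponent: float
    frequencies: np.ndarray
    complements: np.ndarray
    n: int
    fallback: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.fallback and abs(self.weights.sum() - self.n) > 1e-9 * max(self.n, 1):
            raise ValueError("density weights must sum to the number of subjects")


def compute_density_weights(y: np.ndarray, exponent: float = 1.0,
                            n_bins: int | None = None) -> DensityWeights:
    """Compute density-based weights ``R_j`` from an outcome vector.

    Parameters
    ----------
    y:
        Training outcome vector (any real values; frequencies are counted
        on values rounded to 10 decimals, appropriate for ordinal scores
        that may have been standardized).
    exponent:
        Nonnegative reweighting strength ``x``; ``0`` yields unit weights.
    n_bins:
        Optional histogram binning for genuinely continuous outcomes;
        when given, frequencies are counted per equal-width bin instead
        of per exact value.  Off by default.

    Returns
    -------
    DensityWeights
        With ``weights`` summing to ``len(y)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("outcome vector must be non-empty")
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome vector contains non-finite values")
    if exponent < 0:
        raise ValueError(f"exponent must be nonnegative, got {exponent}")

    n = y.size
    if n_bins is None:
        keys = np.round(y, FREQUENCY_DECIMALS)
        _, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
        freq = counts[inverse] / n
    else:
        if n_bins < 1:
            raise ValueError("n_bins must be positive")
        edges = np.histogram_bin_edges(y, bins=n_bins)
        idx = np.clip(np.digitize(y, edges[1:-1]), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        freq = counts[idx] / n

    comp = 1.0 - freq
    if exponent == 0.0:
        # 0^0 = 1 convention: no reweighting at all.
        weights = np.ones(n)
        return DensityWeights(weights, exponent, freq, comp, n)

    powered = comp**exponent
    total = powered.sum()
    if total <= 0.0:
        # every subject shares one outcome value: reweighting is undefined,
        # fall back to uniform unit weights.
        return DensityWeights(np.ones(n), exponent, freq, comp, n, fallback=True)
    weights = powered * (n / total)
    return DensityWeights(weights, exponent, freq, comp, n)
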