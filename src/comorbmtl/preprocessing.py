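"""Leakage-free standardization, PCA, and voxel-space signature reconstruction.

All transform parameters (per-feature means and standard deviations,
PCA loadings) are estimated on training subjects only and then applied
unchanged to held-out subjects — the standard guard against information
leaking across acquisition sites in multi-center prediction.

For the neural arm, voxelwise contrast values are reduced to principal
component scores before model fitting; a fitted model's PC-space weights
can afterwards be projected back through the loadings to a voxel-space
weight map (the "neural signature"), one map per task.  When the model
selects exactly one component, the per-task signatures are scalar
multiples of one single spatial pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mtl_core import CoefficientMatrix

__all__ = [
    "Standardizer", "fit_standardizer", "apply_standardizer",
    "PcaTransform", "fit_pca", "apply_pca",
    "NeuralSignature", "reconstruct_signature",
    "signature_to_nifti", "signature_to_table",
]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardizer:
    """Per-feature centering/scaling parameters estimated on training rows."""

    means: np.ndarray
    sds: np.ndarray
    n_fit: int
    fold: str = ""


def fit_standardizer(train_features: np.ndarray, fold: str = "") -> Standardizer:
    """Estimate means and sample standard deviations (ddof=1) per column.

    Raises if any column has zero variance — constant features must be
    removed upstream (see :func:`comorbmtl.pipeline.read_dataset`).
    """
    X = np.atleast_2d(np.asarray(train_features, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = np.flatnonzero(sds <= 0)
        raise ValueError(
            f"zero-variance columns {bad.tolist()}: remove constant features "
            "before standardization")
    return Standardizer(means, sds, X.shape[0], fold)


def apply_standardizer(s: Standardizer, features: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != s.means.size:
        raise ValueError(f"{X.shape[1]} columns, standardizer fitted on {s.means.size}")
    return (X - s.means) / s.sds


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaTransform:
    """Principal-component map fitted on (already standardized) training rows.

    ``loadings`` holds one orthonormal column per retained component,
    ordered by decreasing explained variance; component signs follow the
    largest-|loading|-positive convention so that signature signs are
    reproducible across runs.
    """

    loadings: np.ndarray
    component_means: np.ndarray
    k: int
    explained_variance: np.ndarray


def fit_pca(train_std: np.ndarray, k: int | str = "max") -> PcaTransform:
    X = np.atleast_2d(np.asarray(train_std, dtype=float))
    n, p = X.shape
    k_max = min(n - 1, p)
    if k == "max":
        k_eff = k_max
    else:
        k_eff = int(k)
        if not 1 <= k_eff <= k_max:
            raise ValueError(f"k must be in [1, {k_max}], got {k_eff}")
    means = X.mean(axis=0)
    _, svals, Vt = np.linalg.svd(X - means, full_matrices=False)
    loadings = Vt[:k_eff].T.copy()
    # sign convention: make the largest-|loading| entry of each component positive
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(k_eff)])
    signs[signs == 0] = 1.0
    loadings *= signs
    explained = (svals[:k_eff] ** 2) / max(n - 1, 1)
    return PcaTransform(loadings, means, k_eff, explained)


def apply_pca(t: PcaTransform, std_features: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(std_features, dtype=float))
    if X.shape[1] != t.component_means.size:
        raise ValueError("feature count does not match the fitted PCA")
    return (X - t.component_means) @ t.loadings


# ---------------------------------------------------------------------------
# signature reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuralSignature:
    """Per-task voxel/feature-space weight maps reconstructed from PC weights."""

    voxel_weights: np.ndarray  # (p features/voxels, t tasks)
    space: str  # "standardized" or "raw"
    mask_reference: str = ""
    task_ids: tuple[str, ...] = ()


def reconstruct_signature(model: CoefficientMatrix, pca: PcaTransform,
                          std: Standardizer | None = None,
                          space: str = "standardized",
                          mask_reference: str = "",
                          task_ids: tuple[str, ...] = ()) -> NeuralSignature:
    """Project PC-space model weights back to the original feature space.

    The standardized-space signature is ``loadings @ W`` (one column per
    task, in units of the standardized signal); the raw-space variant
    additionally divides each feature row by the training standard
    deviation so the map applies to unstandardized data.
    """
    if model.p != pca.k:
        raise ValueError(
            f"model has {model.p} coefficient rows but the PCA retained {pca.k} components")
    if space not in ("standardized", "raw"):
        raise ValueError("space must be 'standardized' or 'raw'")
    V = pca.loadings @ model.values  # (p, t)
    if space == "raw":
        if std is None:
            raise ValueError("raw-space reconstruction needs the training Standardizer")
        V = V / std.sds[:, None]
    return NeuralSignature(V, space, mask_reference, task_ids)


def signature_to_nifti(signature: NeuralSignature, mask_img, task: int = 0):
    """Place one task's signature into the nonzero voxels of a binary mask.

    Voxels are filled in row-major (C) order of the mask's flattened
    array, matching how voxel vectors are extracted from masked volumes.
    Returns a ``nibabel`` image in the mask's space.
    """
    import nibabel as nib

    mask = np.asarray(mask_img.dataobj)
    flat = mask.reshape(-1) != 0
    vec = signature.voxel_weights[:, task]
    if vec.size != int(flat.sum()):
        raise ValueError(
            f"signature has {vec.size} voxels, mask has {int(flat.sum())} nonzero voxels")
    out = np.zeros(flat.size, dtype=float)
    out[flat] = vec
    return nib.Nifti1Image(out.reshape(mask.shape), mask_img.affine, dtype=np.float64)


def signature_to_table(signature: NeuralSignature, feature_names: list[str]):
    """Tabular (DataFrame) export for non-imaging features."""
    import pandas as pd

    if len(feature_names) != signature.voxel_weights.shape[0]:
        raise ValueError("feature_names length mismatch")
    cols = signature.task_ids or tuple(
        f"task{i}" for i in range(signature.voxel_weights.shape[1]))
    return pd.DataFrame(signature.voxel_weights, index=feature_names,
                        columns=list(cols))
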