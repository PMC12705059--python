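"""End-to-end pipeline: I/O, center splitting, gated hold-out access, runner.

The run mirrors the study design: centers are split 4/4 into development
and hold-out groups (entire centers, never subjects), the penalty is
chosen by leave-one-center-out cross-validation on the development
centers, the selected model is refit on all development centers and
tested per hold-out center with one-sided permutation tests, the
increasing-penalty robustness path classifies features into comorbidity
markers and discriminators, and (for PCA models) the signature is
projected back to feature/voxel space.

Hold-out outcomes are wrapped in a :class:`GatedOutcomes` guard: no
stage can read them until the permutation-test stage explicitly reveals
them, which makes the no-leakage contract structural rather than a
convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import DEFAULT_B, holdout_evaluation
from .model_selection import (FittedPipeline, default_lambda_grid, loco_cv,
                              refit_development, robustness_path)
from .mtl_core import TaskCollection, TaskData
from .preprocessing import reconstruct_signature
from .synthetic import GroundTruth

__all__ = ["PipelineConfig", "GatedOutcomes", "LeakageError", "read_dataset",
           "write_dataset", "add_missing_indicators", "split_centers",
           "run_pipeline"]

log = logging.getLogger("comorbmtl")

SUBJECT_COL = "subject"
CENTER_COL = "center"


class LeakageError(RuntimeError):
    """Raised when hold-out outcomes are touched before the inference stage."""


class GatedOutcomes:
    """Hold-out outcome vault; readable only after an explicit reveal."""

    def __init__(self, outcomes: list[np.ndarray]):
        self._outcomes = [np.asarray(y, dtype=float) for y in outcomes]
        self.revealed_for: str | None = None

    def reveal(self, purpose: str) -> list[np.ndarray]:
        if not purpose:
            raise ValueError("a reveal needs a stated purpose")
        self.revealed_for = purpose
        return [y.copy() for y in self._outcomes]

    @property
    def outcomes(self):
        raise LeakageError(
            "hold-out outcomes are gated; call reveal(purpose) in the "
            "permutation-test stage")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    features_path: str = ""
    outcomes_path: str = ""
    centers_path: str = ""
    mask_path: str | None = None
    split_mode: str = "random_half"          # or "explicit"
    development_centers: list[str] = field(default_factory=list)
    holdout_centers: list[str] = field(default_factory=list)
    weighting_exponent: float = 1.0
    lambda_grid: list[float] = field(default_factory=lambda: default_lambda_grid().tolist())
    use_pca: bool = False
    pca_k: int | str = "max"
    n_permutations: int = DEFAULT_B
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")
        if self.split_mode not in ("random_half", "explicit"):
            raise ValueError("split_mode must be 'random_half' or 'explicit'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_dataset(features_path: str | Path, outcomes_path: str | Path,
                 centers_path: str | Path) -> TaskCollection:
    """Load a subject-aligned TaskCollection from delimited text tables.

    Each table needs a shared ``subject`` column; the outcomes table has
    one column per task, the centers table a ``center`` column.  Subjects
    with any missing value in used columns are dropped (logged), and
    zero-variance feature columns are removed (logged by name).
    """
    feats = _read_table(features_path)
    outs = _read_table(outcomes_path)
    cents = _read_table(centers_path)
    for name, df in (("features", feats), ("outcomes", outs), ("centers", cents)):
        if SUBJECT_COL not in df.columns:
            raise ValueError(f"{name} table lacks a '{SUBJECT_COL}' column")
    if CENTER_COL not in cents.columns:
        raise ValueError("centers table lacks a 'center' column")

    merged = feats.merge(outs, on=SUBJECT_COL, validate="one_to_one") \
                  .merge(cents[[SUBJECT_COL, CENTER_COL]], on=SUBJECT_COL,
                         validate="one_to_one")
    if merged.empty:
        raise ValueError("no subjects shared across the three tables")

    n_before = len(merged)
    merged = merged.dropna()
    dropped = n_before - len(merged)
    if dropped:
        log.info("dropped %d subjects with missing values", dropped)

    feature_cols = [c for c in feats.columns if c != SUBJECT_COL]
    task_cols = [c for c in outs.columns if c != SUBJECT_COL]
    values = merged[feature_cols].to_numpy(dtype=float)
    variances = values.std(axis=0)
    keep = variances > 0
    removed = [c for c, k in zip(feature_cols, keep) if not k]
    if removed:
        log.info("removed zero-variance features: %s", removed)
        feature_cols = [c for c, k in zip(feature_cols, keep) if k]
        values = values[:, keep]

    centers = merged[CENTER_COL].astype(str).to_numpy()
    if np.unique(centers).size < 2:
        raise ValueError("need at least 2 centers")
    tasks = [TaskData(values.copy(), merged[c].to_numpy(dtype=float), c, centers.copy())
             for c in task_cols]
    return TaskCollection(tasks, feature_cols)


def write_dataset(data: TaskCollection, outdir: str | Path,
                  truth: GroundTruth | None = None) -> None:
    """Write features.tsv / outcomes.tsv / centers.tsv (and truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = data.tasks[0]
    subjects = [f"s{i}" for i in range(ref.n)]
    pd.DataFrame(ref.features, columns=data.feature_names) \
        .assign(subject=subjects)[["subject", *data.feature_names]] \
        .to_csv(outdir / "features.tsv", sep="\t", index=False)
    pd.DataFrame({"subject": subjects,
                  **{t.task_id: t.outcomes for t in data.tasks}}) \
        .to_csv(outdir / "outcomes.tsv", sep="\t", index=False)
    pd.DataFrame({"subject": subjects, "center": ref.centers}) \
        .to_csv(outdir / "centers.tsv", sep="\t", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(json.dumps({
            "true_coefficients": truth.true_coefficients.tolist(),
            "support_labels": truth.support_labels.tolist(),
        }, indent=1))


def add_missing_indicators(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Zero-impute designated columns and append 0/1 missingness indicators.

    Used for items whose absence plausibly means "experience did not
    occur" (e.g., age at first use of a substance never used).
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise KeyError(col)
        miss = out[col].isna()
        out[f"{col}_missing"] = miss.astype(int)
        out[col] = out[col].fillna(0)
    return out


def split_centers(centers: np.ndarray, mode: str = "random_half", seed: int = 0,
                  development: list[str] | None = None,
                  holdout: list[str] | None = None) -> tuple[list[str], list[str]]:
    """Split whole centers into development and hold-out groups.

    random_half: a seeded half/half split of the center labels (4/4 for
    eight centers); explicit: the caller's lists, validated to be
    disjoint and jointly exhaustive.
    """
    labels = sorted(set(np.asarray(centers, dtype=str).tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 centers to split")
    if mode == "random_half":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(labels))
        half = len(labels) // 2
        dev = sorted(labels[i] for i in perm[:half])
        hold = sorted(labels[i] for i in perm[half:])
        return dev, hold
    if mode == "explicit":
        dev = sorted(map(str, development or []))
        hold = sorted(map(str, holdout or []))
        if set(dev) & set(hold):
            raise ValueError("development and hold-out centers overlap")
        if set(dev) | set(hold) != set(labels):
            raise ValueError("split does not cover all centers exactly")
        if not dev or not hold:
            raise ValueError("both groups need at least one center")
        return dev, hold
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 data: TaskCollection | None = None) -> dict:
    """Execute split -> LOCOCV -> refit -> hold-out permutation -> robustness.

    ``data`` may be passed directly (e.g., from the simulator); otherwise
    the three tables named in the config are read.  Writes result tables,
    a JSON manifest, and returns the in-memory artifacts.
    """
    if data is None:
        data = read_dataset(config.features_path, config.outcomes_path,
                            config.centers_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    ref_centers = data.tasks[0].centers
    dev_labels, hold_labels = split_centers(
        ref_centers, config.split_mode, seed=int(rng.integers(2**31 - 1)),
        development=config.development_centers, holdout=config.holdout_centers)
    log.info("split: development=%s hold-out=%s", dev_labels, hold_labels)

    dev = data.subset_centers(dev_labels)
    hold = data.subset_centers(hold_labels)
    # gate the hold-out outcomes: stages below see features only
    gated = GatedOutcomes([t.outcomes for t in hold.tasks])
    hold_features = [t.features for t in hold.tasks]
    hold_centers = [t.centers for t in hold.tasks]

    grid = np.asarray(config.lambda_grid, dtype=float)
    cv = loco_cv(dev, grid, config.weighting_exponent, config.use_pca,
                 config.pca_k)
    log.info("LOCOCV selected lambda=%.2f (mean MSE %.4f)",
             cv.selected_lambda, cv.selected_mse)
    model = refit_development(dev, cv.selected_lambda, config.weighting_exponent,
                              config.use_pca, config.pca_k)

    # inference stage: the only place the gate opens
    revealed = gated.reveal("hold-out permutation test")
    hold_eval = TaskCollection(
        [TaskData(X, y, t.task_id, c) for X, y, c, t in
         zip(hold_features, revealed, hold_centers, hold.tasks)],
        list(data.feature_names))
    perms = holdout_evaluation(model, hold_eval, B=config.n_permutations,
                               seed=int(rng.integers(2**31 - 1)))

    profile = robustness_path(dev, cv.selected_lambda, 0.01, 0.99,
                              config.weighting_exponent, config.use_pca,
                              config.pca_k)

    signature = None
    if config.use_pca and model.transforms.pca is not None:
        signature = reconstruct_signature(
            model.model, model.transforms.pca, model.transforms.feature_std,
            task_ids=tuple(data.task_ids))

    # ---- outputs -----------------------------------------------------------
    cv.to_frame().to_csv(outdir / "cv.tsv", sep="\t", index=False)
    pd.DataFrame([{"center": r.center, "task": r.task, "mae": r.observed_mae,
                   "p_value": r.p_value, "B": r.n_permutations, "seed": r.seed,
                   "significant": r.significant} for r in perms]) \
        .to_csv(outdir / "holdout_permutation.tsv", sep="\t", index=False)
    profile.to_frame().to_csv(outdir / "robustness.tsv", sep="\t", index=False)
    if signature is not None:
        from .preprocessing import signature_to_table
        signature_to_table(signature, list(data.feature_names)) \
            .to_csv(outdir / "signature.tsv", sep="\t")
        if config.mask_path:
            import nibabel as nib

            from .preprocessing import signature_to_nifti
            mask = nib.load(config.mask_path)
            for i, tid in enumerate(data.task_ids):
                signature_to_nifti(signature, mask, task=i) \
                    .to_filename(str(outdir / f"signature_{tid}.nii.gz"))

    manifest = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "development_centers": dev_labels,
        "holdout_centers": hold_labels,
        "selected_lambda": cv.selected_lambda,
        "mean_mse": cv.selected_mse,
        "n_subjects": int(data.tasks[0].n),
        "n_features": int(data.p),
        "holdout_gate_revealed_for": gated.revealed_for,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"cv": cv, "model": model, "permutations": perms,
            "robustness": profile, "signature": signature,
            "manifest": manifest, "development": dev_labels,
            "holdout": hold_labels}
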