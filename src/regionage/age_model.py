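"""Per-region brain-age models: GP regression, bias correction, gaps.

One Gaussian-process regressor is trained per atlas region on that
region's key voxels (healthy training cohort only). Five-fold
cross-validation produces an out-of-fold predicted age for every training
subject; regressing those predictions on chronological age gives the
bias-correction coefficients

    brain age ~= alpha * chronological age + beta

and each prediction is then corrected by adding back the systematic
shortfall,

    corrected = raw + [chronological - (alpha * chronological + beta)],
    gap       = corrected - chronological.

Model performance (MAE and Pearson r) is evaluated on the corrected
out-of-fold predictions. The deployed regressor is refit on the full
training cohort; its (alpha, beta) are frozen and reused for every test
cohort — bias is never refit on test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .features import FeatureMask

__all__ = [
    "RegionAgeModel", "fit_bias", "correct_age", "compute_gap",
    "evaluate_predictions", "train_region_model", "apply_model",
    "save_model", "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class RegionAgeModel:
    """A trained per-region regressor plus its bias correction and CV scores.

    ``feature_mean``/``feature_std`` are the training-set standardization
    parameters applied to the masked voxel columns before the kernel sees
    them. ``alpha``/``beta`` are the predicted-on-chronological OLS slope
    and intercept fitted on pooled out-of-fold training predictions.
    """

    modality: str
    region_id: int
    feature_mask: FeatureMask
    regressor: GaussianProcessRegressor
    feature_mean: np.ndarray
    feature_std: np.ndarray
    alpha: float
    beta: float
    cv_mae: float
    cv_r: float
    n_region_voxels: int
    # correlation of the *uncorrected* out-of-fold predictions with age; the
    # honest null diagnostic, since the additive correction makes corrected
    # ages track chronological age even for an uninformative model
    cv_raw_r: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.alpha) or self.alpha == 0:
            raise ValueError("bias slope alpha must be finite and non-zero")
        if self.cv_mae < 0 or abs(self.cv_r) > 1 + 1e-12:
            raise ValueError("invalid CV performance values")


def fit_bias(predicted: np.ndarray, chronological: np.ndarray) -> tuple[float, float]:
    """OLS fit of predicted age on chronological age -> (alpha, beta)."""
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.shape != c.shape or p.ndim != 1 or p.size < 3:
        raise ValueError("need matching 1-D arrays with at least 3 points")
    cc = c - c.mean()
    var = (cc ** 2).sum()
    if var == 0:
        raise ValueError("chronological ages are constant; slope undefined")
    alpha = float((cc * (p - p.mean())).sum() / var)
    beta = float(p.mean() - alpha * c.mean())
    return alpha, beta


def correct_age(raw, chronological, alpha: float, beta: float):
    """Bias-corrected brain age:
    raw + [chronological - (alpha * chronological + beta)], element-wise."""
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise ValueError("alpha and beta must be finite")
    raw = np.asarray(raw, dtype=float)
    chron = np.asarray(chronological, dtype=float)
    out = raw + (chron - (alpha * chron + beta))
    return float(out) if out.ndim == 0 else out


def compute_gap(corrected, chronological):
    """Brain age gap = corrected brain age - chronological age."""
    c = np.asarray(corrected, dtype=float)
    a = np.asarray(chronological, dtype=float)
    if c.shape != a.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {a.shape}")
    out = c - a
    return float(out) if out.ndim == 0 else out


def evaluate_predictions(corrected: np.ndarray, chronological: np.ndarray) -> tuple[float, float]:
    """(MAE in years, Pearson r) between corrected and chronological age."""
    c = np.asarray(corrected, dtype=float)
    a = np.asarray(chronological, dtype=float)
    if c.shape != a.shape or c.size < 3:
        raise ValueError("need matching arrays with at least 3 points")
    if np.std(c) == 0 or np.std(a) == 0:
        raise ValueError("constant input; correlation undefined")
    mae = float(np.mean(np.abs(c - a)))
    r = float(sps.pearsonr(c, a).statistic)
    return mae, r


def _make_gp(n_features: int, n_restarts: int, random_state: int) -> GaussianProcessRegressor:
    # squared-exponential + white noise; length scale initialized at sqrt(d)
    # which is the natural scale for z-scored features
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=np.sqrt(max(n_features, 1)), length_scale_bounds=(1e-2, 1e5))
        + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-8, 1e2))
    )
    return GaussianProcessRegressor(kernel=kernel, n_restarts_optimizer=n_restarts,
                                    normalize_y=True, random_state=random_state)


def train_region_model(
    features: np.ndarray,
    ages: np.ndarray,
    *,
    modality: str = "GM",
    region_id: int = 0,
    mask: FeatureMask | None = None,
    k_folds: int = 5,
    n_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> RegionAgeModel:
    """Train one region's GP brain-age model with k-fold cross-validation.

    ``features`` is the (n_subjects, n_voxels) region matrix; if ``mask``
    is given its ``feature_voxels`` columns are used, otherwise all
    columns. Folds are a random permutation split (no stratification).
    Per-fold regressors run a single marginal-likelihood optimization;
    the deployed full-data regressor uses ``n_restarts`` restarts.

    Out-of-fold predictions feed the bias fit (alpha, beta) and, after
    correction, the cv_mae / cv_r performance scores.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    X_all = np.asarray(features, dtype=float)
    y = np.asarray(ages, dtype=float)
    n = X_all.shape[0]
    if n < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} subjects, got {n}")
    if mask is not None:
        if X_all.shape[1] != mask.n_region_voxels:
            raise ValueError(
                f"feature matrix has {X_all.shape[1]} voxels but mask describes "
                f"{mask.n_region_voxels}")
        X_all = X_all[:, mask.feature_voxels]
    if X_all.shape[1] < 1:
        raise ValueError("need at least one feature")

    mu = X_all.mean(axis=0)
    sd = X_all.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    X = (X_all - mu) / sd
    d = X.shape[1]

    # k-fold out-of-fold predictions
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    oof = np.empty(n)
    base_seed = int(rng.integers(2 ** 31 - 1))
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        gp = _make_gp(d, n_restarts=0, random_state=base_seed + i)
        with warnings.catch_warnings():
            # a fold fit stopping at the lbfgs iteration cap is acceptable:
            # fold models only produce out-of-fold predictions
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X[train_idx], y[train_idx])
        oof[test_idx] = gp.predict(X[test_idx])
    if not np.all(np.isfinite(oof)):
        raise ValueError(f"{modality} region {region_id}: degenerate kernel fit "
                         "(non-finite out-of-fold predictions)")

    alpha, beta = fit_bias(oof, y)
    corrected = correct_age(oof, y, alpha, beta)
    cv_mae, cv_r = evaluate_predictions(corrected, y)
    raw_r = 0.0 if np.std(oof) == 0 else float(sps.pearsonr(oof, y).statistic)

    final = _make_gp(d, n_restarts=n_restarts, random_state=base_seed + k_folds)
    final.fit(X, y)

    return RegionAgeModel(
        modality=modality, region_id=region_id,
        feature_mask=mask if mask is not None else FeatureMask(
            modality=modality, region_id=region_id,
            selected_voxels=np.arange(d), selection_counts=np.zeros(d, dtype=int),
            n_outer=0, count_threshold=-1, n_region_voxels=d),
        regressor=final, feature_mean=mu, feature_std=sd,
        alpha=alpha, beta=beta, cv_mae=cv_mae, cv_r=cv_r,
        n_region_voxels=int(np.asarray(features).shape[1]), cv_raw_r=raw_r,
    )


def apply_model(
    model: RegionAgeModel,
    features: np.ndarray,
    subject_ids,
    chronological: np.ndarray,
) -> pd.DataFrame:
    """Predict brain ages for a cohort with a trained region model.

    ``features`` is the full (n_subjects, n_region_voxels) region matrix;
    the model slices its own mask columns. The stored (alpha, beta) are
    applied — never refit. Returns a table with columns subject_id,
    modality, region_id, raw_brain_age, corrected_brain_age,
    brain_age_gap.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_region_voxels:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} voxels but model "
            f"expects {model.n_region_voxels}")
    chron = np.asarray(chronological, dtype=float)
    if len(subject_ids) != X.shape[0] or chron.shape[0] != X.shape[0]:
        raise ValueError("subject_ids, features and chronological must align")
    Xm = (X[:, model.feature_mask.feature_voxels] - model.feature_mean) / model.feature_std
    raw = model.regressor.predict(Xm)
    corrected = correct_age(raw, chron, model.alpha, model.beta)
    gap = compute_gap(corrected, chron)
    return pd.DataFrame({
        "subject_id": list(subject_ids),
        "modality": model.modality,
        "region_id": model.region_id,
        "raw_brain_age": raw,
        "corrected_brain_age": corrected,
        "brain_age_gap": gap,
    })


# ---------------------------------------------------------------------------
# Persistence: JSON metadata + array blob per model
# ---------------------------------------------------------------------------

def save_model(model: RegionAgeModel, stem) -> None:
    """Persist a model as ``<stem>.json`` + ``<stem>.npz``.

    The GP is stored as its optimized kernel hyperparameters plus the
    standardized training set; loading refits with the optimizer disabled,
    which reproduces predictions exactly.
    """
    import json
    from pathlib import Path

    stem = Path(stem)
    gp = model.regressor
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "modality": model.modality,
        "region_id": model.region_id,
        "alpha": model.alpha,
        "beta": model.beta,
        "cv_mae": model.cv_mae,
        "cv_r": model.cv_r,
        "cv_raw_r": model.cv_raw_r,
        "n_region_voxels": model.n_region_voxels,
        "kernel_theta": list(map(float, gp.kernel_.theta)),
        "mask": {
            "n_outer": model.feature_mask.n_outer,
            "count_threshold": model.feature_mask.count_threshold,
            "fallback_used": model.feature_mask.fallback_used,
        },
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    np.savez_compressed(
        stem.with_suffix(".npz"),
        X_train=gp.X_train_,
        y_train=gp.y_train_ * gp._y_train_std + gp._y_train_mean,
        feature_mean=model.feature_mean, feature_std=model.feature_std,
        selected_voxels=model.feature_mask.selected_voxels,
        selection_counts=model.feature_mask.selection_counts,
    )


def load_model(stem) -> RegionAgeModel:
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {meta.get('format_version')}")
    blobs = np.load(stem.with_suffix(".npz"))
    X, y = blobs["X_train"], blobs["y_train"]
    gp = _make_gp(X.shape[1], n_restarts=0, random_state=0)
    gp.optimizer = None
    gp.kernel.theta = np.asarray(meta["kernel_theta"])
    gp.fit(X, y)
    mask = FeatureMask(
        modality=meta["modality"], region_id=meta["region_id"],
        selected_voxels=blobs["selected_voxels"],
        selection_counts=blobs["selection_counts"],
        n_outer=meta["mask"]["n_outer"],
        count_threshold=meta["mask"]["count_threshold"],
        fallback_used=meta["mask"]["fallback_used"],
        n_region_voxels=int(blobs["selection_counts"].shape[0]),
    )
    return RegionAgeModel(
        modality=meta["modality"], region_id=meta["region_id"], feature_mask=mask,
        regressor=gp, feature_mean=blobs["feature_mean"], feature_std=blobs["feature_std"],
        alpha=meta["alpha"], beta=meta["beta"], cv_mae=meta["cv_mae"], cv_r=meta["cv_r"], cv_raw_r=meta.get("cv_raw_r", 0.0),
        n_region_voxels=meta["n_region_voxels"],
    )
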