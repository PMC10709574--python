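"""Nearest shrunken centroid (NSC) classification, implemented from scratch.

The model shrinks standardized class-centroid offsets toward zero with a
soft threshold, performing embedded feature selection.  With overall
centroid x̄_i, class centroids x̄_ik, pooled within-class standard
deviation s_i, offset s0 (a quantile of the s_i, the median by default)
and normalizer m_k = sqrt(1/n_k - 1/n):

    d_ik  = (x̄_ik - x̄_i) / (m_k (s_i + s0))
    d'_ik = sign(d_ik) max(|d_ik| - Δ, 0)
    x̄'_ik = x̄_i + m_k (s_i + s0) d'_ik

Prediction uses the discriminant score

    δ_k(x*) = Σ_i (x*_i - x̄'_ik)² / (s_i + s0)² - 2 log π_k

and class posteriors p_k = exp(-δ_k/2) / Σ_l exp(-δ_l/2), computed in
log space with max-subtraction.  The shrinkage threshold Δ is chosen by
stratified cross-validation, preferring the largest Δ (fewest features)
whose mean balanced accuracy ties the maximum.

Some formulations print m_k = sqrt(1/n_k + 1/n); the subtraction form
(variance of the class-vs-overall centroid difference) is the default
here, with ``m_convention="plus"`` available for cross-checking against
other implementations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

SCHEMA = "leukotype-nsc/1"


@dataclass
class CentroidStats:
    """Sufficient statistics of the training data for one NSC model."""

    class_labels: list
    overall_centroid: np.ndarray  # (p,)
    class_centroids: np.ndarray  # (K, p)
    pooled_sd: np.ndarray  # (p,)
    s0: float
    m_k: np.ndarray  # (K,)
    class_counts: np.ndarray  # (K,)
    n: int


@dataclass
class NSCModel:
    """A fitted nearest shrunken centroid model."""

    stats: CentroidStats
    delta: float
    shrunken_centroids: np.ndarray  # (K, p)
    priors: np.ndarray  # (K,)
    feature_ids: list
    imputation_values: np.ndarray  # (p,)
    prior_mode: str = "uniform"
    m_convention: str = "minus"
    s0_quantile: float = 0.5

    @property
    def class_labels(self) -> list:
        return self.stats.class_labels


def _compute_stats(
    X: np.ndarray,
    y: np.ndarray,
    *,
    s0_quantile: float = 0.5,
    m_convention: str = "minus",
) -> CentroidStats:
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    counts = np.array([int(np.sum(y == c)) for c in classes])
    small = [c for c, nk in zip(classes, counts) if nk < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    overall = X.mean(axis=0)
    centroids = np.vstack([X[y == c].mean(axis=0) for c in classes])
    sse = np.zeros(p)
    for k, c in enumerate(classes):
        diff = X[y == c] - centroids[k]
        sse += (diff * diff).sum(axis=0)
    pooled_sd = np.sqrt(sse / (n - len(classes)))
    s0 = float(np.quantile(pooled_sd, s0_quantile))
    if m_convention == "minus":
        m_k = np.sqrt(1.0 / counts - 1.0 / n)
    elif m_convention == "plus":
        m_k = np.sqrt(1.0 / counts + 1.0 / n)
    else:
        raise ValueError(f"unknown m_convention {m_convention!r}")
    return CentroidStats(classes, overall, centroids, pooled_sd, s0, m_k, counts, n)


def _shrink(stats: CentroidStats, delta: float):
    """Soft-threshold the standardized offsets; return (d', shrunken centroids)."""
    denom = stats.m_k[:, None] * (stats.pooled_sd + stats.s0)[None, :]
    d = (stats.class_centroids - stats.overall_centroid) / denom
    if delta == 0:  # exact identity, no reconstruction round-off
        return d, stats.class_centroids.copy()
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = stats.overall_centroid + denom * d_shrunk
    return d_shrunk, shrunken


def _priors(stats: CentroidStats, prior_mode: str) -> np.ndarray:
    if prior_mode == "uniform":
        return np.full(len(stats.class_labels), 1.0 / len(stats.class_labels))
    if prior_mode == "empirical":
        return stats.class_counts / stats.n
    raise ValueError(f"unknown prior_mode {prior_mode!r}")


def fit_nsc(
    X,
    y,
    delta: float = 0.0,
    prior_mode: str = "uniform",
    *,
    feature_ids=None,
    s0_quantile: float = 0.5,
    m_convention: str = "minus",
) -> NSCModel:
    """Fit an NSC model at a fixed shrinkage threshold.

    Missing values (NaN) are imputed per feature with the training-set
    median; the imputation values are frozen into the model for reuse
    at prediction time.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X.shape[1])]
    feature_ids = list(map(str, feature_ids))
    if len(feature_ids) != X.shape[1]:
        raise ValueError("feature_ids length mismatch")

    imputation = np.nanmedian(X, axis=0)
    imputation = np.where(np.isnan(imputation), 0.0, imputation)
    if np.isnan(X).any():
        X = np.where(np.isnan(X), imputation[None, :], X)

    stats = _compute_stats(X, y, s0_quantile=s0_quantile, m_convention=m_convention)
    _, shrunken = _shrink(stats, delta)
    return NSCModel(
        stats=stats,
        delta=float(delta),
        shrunken_centroids=shrunken,
        priors=_priors(stats, prior_mode),
        feature_ids=feature_ids,
        imputation_values=imputation,
        prior_mode=prior_mode,
        m_convention=m_convention,
        s0_quantile=s0_quantile,
    )


def _align(model: NSCModel, X: np.ndarray, feature_ids) -> np.ndarray:
    """Reindex columns of X to the model's feature order, imputing gaps."""
    if feature_ids is None:
        if X.shape[1] != len(model.feature_ids):
            raise ValueError(
                f"matrix has {X.shape[1]} features, model expects "
                f"{len(model.feature_ids)}; pass feature_ids to align"
            )
        nan = np.isnan(X)
        if nan.any():
            X = np.where(nan, np.broadcast_to(model.imputation_values, X.shape), X)
        return X
    feature_ids = list(map(str, feature_ids))
    pos = {f: i for i, f in enumerate(feature_ids)}
    idx = np.array([pos.get(f, -1) for f in model.feature_ids])
    missing = idx < 0
    if missing.mean() > 0.5:
        raise ValueError(
            f"{int(missing.sum())}/{len(idx)} model features absent from input"
        )
    extra = len(set(feature_ids) - set(model.feature_ids))
    if extra:
        warnings.warn(f"{extra} input features unknown to the model; ignored")
    aligned = np.empty((X.shape[0], len(model.feature_ids)))
    aligned[:, ~missing] = X[:, idx[~missing]]
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} model features missing from input; imputed"
        )
        aligned[:, missing] = model.imputation_values[missing][None, :]
    nan = np.isnan(aligned)
    if nan.any():
        aligned = np.where(nan, np.broadcast_to(model.imputation_values, aligned.shape), aligned)
    return aligned


def discriminant_scores(model: NSCModel, X, feature_ids=None) -> np.ndarray:
    """Per-sample per-class discriminant δ_k (lower is closer)."""
    X = _align(model, np.asarray(X, dtype=float), feature_ids)
    inv = 1.0 / (model.stats.pooled_sd + model.stats.s0)
    delta_k = np.empty((X.shape[0], len(model.class_labels)))
    for k in range(len(model.class_labels)):
        diff = (X - model.shrunken_centroids[k]) * inv
        delta_k[:, k] = (diff * diff).sum(axis=1)
    return delta_k - 2.0 * np.log(model.priors)[None, :]


def predict_scores(model: NSCModel, X, feature_ids=None) -> pd.DataFrame:
    """Posterior class probabilities, rows summing to 1.

    Computed stably in log space: p_k ∝ exp(-δ_k/2) after subtracting
    the row minimum of δ, so total underflow resolves to the
    prior-weighted argmin of δ_k.
    """
    d = discriminant_scores(model, X, feature_ids)
    log_unnorm = -0.5 * d
    log_unnorm -= log_unnorm.max(axis=1, keepdims=True)
    p = np.exp(log_unnorm)
    p /= p.sum(axis=1, keepdims=True)
    index = list(X.index) if isinstance(X, pd.DataFrame) else None
    return pd.DataFrame(p, columns=model.class_labels, index=index)


def predict_labels(model: NSCModel, X, feature_ids=None) -> np.ndarray:
    p = predict_scores(model, X, feature_ids)
    return p.columns.to_numpy()[np.argmax(p.to_numpy(), axis=1)]


def standardized_offsets(model: NSCModel, delta: float | None = None) -> np.ndarray:
    """The (K, p) soft-thresholded standardized offsets d'_ik.

    Uses the model's own Δ unless *delta* is given; ``delta=0`` returns
    the raw offsets d_ik.
    """
    d_shrunk, _ = _shrink(model.stats, model.delta if delta is None else delta)
    return d_shrunk


def selected_features(model: NSCModel) -> list:
    """Ids of features surviving shrinkage in any class, original order."""
    d_shrunk, _ = _shrink(model.stats, model.delta)
    keep = (d_shrunk != 0).any(axis=0)
    return [f for f, k in zip(model.feature_ids, keep) if k]


def default_delta_grid(X, y, size: int = 30, **fit_kwargs) -> np.ndarray:
    """Evenly spaced thresholds from 0 to the full-fit max |d_ik|."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), np.where(np.isnan(med), 0.0, med)[None, :], X)
    stats = _compute_stats(np.asarray(X, dtype=float), np.asarray(y), **fit_kwargs)
    d, _ = _shrink(stats, 0.0)
    return np.linspace(0.0, float(np.abs(d).max()), size)


def select_delta_cv(
    X,
    y,
    delta_grid=None,
    folds: int = 10,
    seed: int = 0,
    prior_mode: str = "uniform",
    *,
    tie_tolerance: float = 0.0,
    s0_quantile: float = 0.5,
    m_convention: str = "minus",
):
    """Choose the shrinkage threshold by stratified k-fold cross-validation.

    Returns ``(delta_star, cv_curve)`` where the curve is a DataFrame
    with per-Δ mean balanced accuracy and surviving-feature count.
    ``delta_star`` is the largest Δ whose mean balanced accuracy is
    within ``tie_tolerance`` of the maximum (fewest features preferred).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if delta_grid is None:
        delta_grid = default_delta_grid(
            X, y, s0_quantile=s0_quantile, m_convention=m_convention
        )
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0:
        raise ValueError("delta_grid is empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    min_class = min(np.sum(y == c) for c in set(y))
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds from {folds}"
        )
        folds = max(2, int(min_class))

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = np.zeros((folds, delta_grid.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # folds may miss a predicted class
        for f, (tr, va) in enumerate(splitter.split(X, y)):
            fold = fit_nsc(
                X[tr],
                y[tr],
                0.0,
                prior_mode,
                s0_quantile=s0_quantile,
                m_convention=m_convention,
            )
            for j, delta in enumerate(delta_grid):
                _, fold.shrunken_centroids = _shrink(fold.stats, delta)
                fold.delta = float(delta)
                pred = predict_labels(fold, X[va])
                acc[f, j] = balanced_accuracy_score(y[va], pred)

    mean_acc = acc.mean(axis=0)
    full = fit_nsc(
        X, y, 0.0, prior_mode, s0_quantile=s0_quantile, m_convention=m_convention
    )
    n_feat = []
    for delta in delta_grid:
        d_shrunk, _ = _shrink(full.stats, delta)
        n_feat.append(int((d_shrunk != 0).any(axis=0).sum()))
    best = mean_acc.max()
    eligible = np.flatnonzero(mean_acc >= best - tie_tolerance)
    delta_star = float(delta_grid[eligible[-1]])
    curve = pd.DataFrame(
        {"delta": delta_grid, "balanced_accuracy": mean_acc, "n_features": n_feat}
    )
    return delta_star, curve


def model_to_dict(model: NSCModel) -> dict:
    return {
        "schema": SCHEMA,
        "class_labels": list(model.class_labels),
        "feature_ids": list(model.feature_ids),
        "delta": model.delta,
        "prior_mode": model.prior_mode,
        "m_convention": model.m_convention,
        "s0_quantile": model.s0_quantile,
        "priors": model.priors.tolist(),
        "imputation_values": model.imputation_values.tolist(),
        "shrunken_centroids": model.shrunken_centroids.tolist(),
        "stats": {
            "overall_centroid": model.stats.overall_centroid.tolist(),
            "class_centroids": model.stats.class_centroids.tolist(),
            "pooled_sd": model.stats.pooled_sd.tolist(),
            "s0": model.stats.s0,
            "m_k": model.stats.m_k.tolist(),
            "class_counts": model.stats.class_counts.tolist(),
            "n": model.stats.n,
        },
    }


def model_from_dict(d: dict) -> NSCModel:
    if d.get("schema") != SCHEMA:
        raise ValueError(f"unsupported model schema {d.get('schema')!r}")
    s = d["stats"]
    stats = CentroidStats(
        class_labels=list(d["class_labels"]),
        overall_centroid=np.array(s["overall_centroid"], dtype=float),
        class_centroids=np.array(s["class_centroids"], dtype=float),
        pooled_sd=np.array(s["pooled_sd"], dtype=float),
        s0=float(s["s0"]),
        m_k=np.array(s["m_k"], dtype=float),
        class_counts=np.array(s["class_counts"], dtype=int),
        n=int(s["n"]),
    )
    return NSCModel(
        stats=stats,
        delta=float(d["delta"]),
        shrunken_centroids=np.array(d["shrunken_centroids"], dtype=float),
        priors=np.array(d["priors"], dtype=float),
        feature_ids=list(d["feature_ids"]),
        imputation_values=np.array(d["imputation_values"], dtype=float),
        prior_mode=d["prior_mode"],
        m_convention=d["m_convention"],
        s0_quantile=float(d["s0_quantile"]),
    )


def save_model(model: NSCModel, path) -> None:
    """Serialize to a JSON text container; floats round-trip bit-exactly."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> NSCModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


__all__ = [
    "CentroidStats",
    "NSCModel",
    "fit_nsc",
    "predict_scores",
    "predict_labels",
    "discriminant_scores",
    "standardized_offsets",
    "selected_features",
    "select_delta_cv",
    "default_delta_grid",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]
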