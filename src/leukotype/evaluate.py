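"""Classifier evaluation and cross-modality decomposition.

Performance is reported the way subtype classifiers are benchmarked in
this field: a full confusion table (with NO_CLASS and CONTROL as
possible predicted columns), per-class sensitivity / specificity /
precision / F1 / balanced accuracy, macro averages, and concordance
(the exact-match fraction).  A NO_CLASS prediction counts against its
true class's sensitivity and never as a positive prediction.

PLS canonical analysis (symmetric-mode NIPALS with deflation of both
blocks) quantifies the covariance between the two modalities' selected
signatures: weights are fit on a train partition and per-component
Pearson correlations between the two modalities' scores are reported
on train and test partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrices import LabeledCohort
from .vocabulary import CONTROL, NO_CLASS


@dataclass
class MetricsReport:
    confusion: pd.DataFrame  # true x predicted counts
    per_class: pd.DataFrame  # rows: class; cols: the five rates
    overall: dict  # concordance + macro (or pooled) averages


def score_predictions(
    truth: LabeledCohort, calls, *, average: str = "macro"
) -> MetricsReport:
    """Score resolved calls against truth labels.

    ``calls`` is a list of objects with ``sample_id`` and
    ``resolved_label`` (e.g. :class:`~leukotype.classifier.SubtypeCall`).
    ``average`` selects macro (per-class mean, default) or pooled
    (micro) aggregation of sensitivity/specificity/precision.
    """
    missing = [c.sample_id for c in calls if c.sample_id not in truth.labels]
    if missing:
        raise ValueError(f"samples without truth labels: {missing[:10]}")
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")

    y_true = np.array([truth[c.sample_id] for c in calls])
    y_pred = np.array([c.resolved_label for c in calls])
    classes = sorted(set(y_true))
    pred_cols = sorted(set(classes) | set(y_pred) | {NO_CLASS, CONTROL})

    confusion = pd.DataFrame(0, index=classes, columns=pred_cols, dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion.loc[t, p] += 1

    n = len(calls)
    rows = {}
    tp_sum = fp_sum = fn_sum = tn_sum = 0
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        tn = n - tp - fn - fp
        tp_sum += tp; fp_sum += fp; fn_sum += fn; tn_sum += tn
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 1.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        rows[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
            "balanced_accuracy": 0.5 * (sens + spec),
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")

    if average == "macro":
        agg = per_class.mean(axis=0).to_dict()
    else:
        sens = tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else 0.0
        spec = tn_sum / (tn_sum + fp_sum) if tn_sum + fp_sum else 1.0
        prec = tp_sum / (tp_sum + fp_sum) if tp_sum + fp_sum else 0.0
        agg = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": 2 * prec * sens / (prec + sens) if prec + sens else 0.0,
            "balanced_accuracy": 0.5 * (sens + spec),
        }
    overall = {f"{average}_{k}": float(v) for k, v in agg.items()}
    overall["concordance"] = float(np.mean(y_true == y_pred))
    overall["n"] = n
    return MetricsReport(confusion=confusion, per_class=per_class, overall=overall)


@dataclass
class PLSResult:
    n_components: int
    train_correlations: np.ndarray  # (n_components,)
    test_correlations: np.ndarray
    x_loadings: np.ndarray  # (p_x, n_components)
    y_loadings: np.ndarray
    train_index: np.ndarray
    test_index: np.ndarray


def _standardize(train, other):
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mean) / sd, (other - mean) / sd


def _nipals_component(X, Y, tol, max_iter):
    """One pair of canonical weight vectors by alternating least squares."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if np.allclose(u, 0):
        u = np.ones(Y.shape[0])
    w = c = None
    for _ in range(max_iter):
        w_new = X.T @ u
        w_new /= np.linalg.norm(w_new) or 1.0
        t = X @ w_new
        c_new = Y.T @ t
        c_new /= np.linalg.norm(c_new) or 1.0
        u = Y @ c_new
        if w is not None and np.linalg.norm(w_new - w) < tol:
            w, c = w_new, c_new
            break
        w, c = w_new, c_new
    return w, c


def pls_canonical(
    X_a,
    X_b,
    n_components: int = 2,
    train_fraction: float = 0.67,
    seed: int = 0,
    *,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> PLSResult:
    """Symmetric (canonical-mode) PLS linking two modality matrices.

    Rows of ``X_a`` and ``X_b`` are the same samples.  The sample set is
    randomly split; weights are fit on the train partition (variables
    standardized to train mean/sd) and Pearson correlations between the
    two blocks' component scores are reported for both partitions.
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    if X_a.shape[0] != X_b.shape[0]:
        raise ValueError("modality matrices must share samples (rows)")
    n = X_a.shape[0]
    n_train = int(round(n * train_fraction))
    if n_components > min(X_a.shape[1], X_b.shape[1], n_train):
        raise ValueError("n_components exceeds the smallest dimension")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    Xa_tr, Xa_te = _standardize(X_a[train_idx], X_a[test_idx])
    Xb_tr, Xb_te = _standardize(X_b[train_idx], X_b[test_idx])

    Wa = np.zeros((X_a.shape[1], n_components))
    Wb = np.zeros((X_b.shape[1], n_components))
    Pa = np.zeros_like(Wa)
    Pb = np.zeros_like(Wb)
    Xd, Yd = Xa_tr.copy(), Xb_tr.copy()
    for comp in range(n_components):
        w, c = _nipals_component(Xd, Yd, tol, max_iter)
        t = Xd @ w
        u = Yd @ c
        p = Xd.T @ t / (t @ t)
        q = Yd.T @ u / (u @ u)
        Xd = Xd - np.outer(t, p)  # deflate both blocks on their own scores
        Yd = Yd - np.outer(u, q)
        Wa[:, comp], Wb[:, comp] = w, c
        Pa[:, comp], Pb[:, comp] = p, q

    # rotations map original (standardized) data to component scores
    Ra = Wa @ np.linalg.pinv(Pa.T @ Wa)
    Rb = Wb @ np.linalg.pinv(Pb.T @ Wb)

    def correlations(Xa_s, Xb_s):
        if Xa_s.shape[0] < 2:
            return np.full(n_components, np.nan)
        Ta, Tb = Xa_s @ Ra, Xb_s @ Rb
        out = np.empty(n_components)
        for comp in range(n_components):
            sa, sb = Ta[:, comp], Tb[:, comp]
            if sa.std() < 1e-12 or sb.std() < 1e-12:
                out[comp] = 0.0
            else:
                out[comp] = sps.pearsonr(sa, sb).statistic
        return out

    return PLSResult(
        n_components=n_components,
        train_correlations=correlations(Xa_tr, Xb_tr),
        test_correlations=correlations(Xa_te, Xb_te),
        x_loadings=Pa,
        y_loadings=Pb,
        train_index=train_idx,
        test_index=test_idx,
    )


def feature_overlap(selected_a, selected_b):
    """Overlap of two selected-feature lists: |A∩B| and |A∩B| / |B|."""
    a, b = set(selected_a), set(selected_b)
    count = len(a & b)
    fraction = count / len(b) if b else float("nan")
    return count, fraction


def min_max_scale(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Min-max scale to [0, 1] along an axis (visualization helper)."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=axis, keepdims=True)
    hi = values.max(axis=axis, keepdims=True)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    return (values - lo) / span


__all__ = [
    "MetricsReport",
    "PLSResult",
    "score_predictions",
    "pls_canonical",
    "feature_overlap",
    "min_max_scale",
]
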