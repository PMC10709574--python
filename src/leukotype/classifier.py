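"""Per-modality hierarchical subtype classification.

One binary one-vs-rest NSC model is trained per step-1 class — each of
the nine standalone subtypes, the three subtype groups, and the
non-leukemic CONTROL class — each with its own cross-validated
shrinkage threshold.  A step-2 model per group (multi-class for the
aneuploidies, one-vs-one for the two-member groups) assigns the final
subtype when a group wins step 1.  Samples whose target posteriors all
fall below the positive threshold resolve to NO_CLASS; multiple
positives are resolved to the highest-scoring class (lexicographic
tie-break, flagged).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nsc
from .matrices import LabeledCohort
from .vocabulary import CONTROL, DEFAULT_VOCAB, NO_CLASS, SubtypeVocabulary

MODEL_SCHEMA = "leukotype-subtype-model/1"
REST = "REST"


@dataclass
class SubtypeCall:
    """Resolved classification of one sample by one modality."""

    sample_id: str
    modality: str
    step1_scores: dict  # step-1 class -> target posterior
    positives: list  # step-1 classes scoring >= positive_threshold
    resolved_label: str  # subtype | CONTROL | NO_CLASS
    resolved_score: float  # step-1 score of the winning class
    step2_label: str | None = None
    step2_score: float | None = None
    tie: bool = False


@dataclass
class SubtypeModel:
    """All NSC models and resolution settings for one modality."""

    modality: str
    vocab: SubtypeVocabulary
    step1_models: dict  # step-1 class -> binary NSCModel (target vs REST)
    step2_models: dict  # group -> NSCModel over its members
    positive_threshold: float = 0.5
    feature_union: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    # group -> its only observed member, for groups whose step-2 model
    # was skipped at training time
    group_fallbacks: dict = field(default_factory=dict)

    @property
    def step1_classes(self) -> list:
        return sorted(self.step1_models)


def resolve_multiclass(step1_scores: dict, positive_threshold: float):
    """Reduce per-class posteriors to a single call.

    Returns ``(label, score, positives, tie)``: classes at or above the
    threshold are positives; with none the call is NO_CLASS (score =
    best score seen); otherwise the highest-scoring positive wins, ties
    broken lexicographically and flagged.
    """
    if not step1_scores:
        raise ValueError("no step-1 scores")
    best = max(step1_scores.values())
    positives = sorted(c for c, s in step1_scores.items() if s >= positive_threshold)
    if not positives:
        return NO_CLASS, float(best), [], False
    top = max(step1_scores[c] for c in positives)
    winners = [c for c in positives if step1_scores[c] == top]
    return winners[0], float(top), positives, len(winners) > 1


def _seed_for(base_seed: int, name: str) -> int:
    # stable per-model seed, independent of training order
    h = 0
    for ch in name:
        h = (h * 31 + ord(ch)) % 1_000_000_007
    return int((base_seed * 2_654_435_761 + h) % (2**31 - 1))


def train_subtype_model(
    X,
    feature_ids,
    labels: LabeledCohort,
    vocab: SubtypeVocabulary = DEFAULT_VOCAB,
    *,
    modality: str = "dnam",
    sample_ids=None,
    positive_threshold: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    delta_grid_size: int = 30,
    tie_tolerance: float = 0.0,
    step1_prior_mode: str = "uniform",
    step2_prior_mode: str = "empirical",
) -> SubtypeModel:
    """Train the full two-step architecture on design samples.

    ``X`` is samples x features; ``sample_ids`` defaults to the order of
    ``labels``.  Subtypes absent from the design set are dropped with a
    warning; a group reduced to a single observed member skips its
    step-2 model and resolves directly to that member.
    """
    X = np.asarray(X, dtype=float)
    feature_ids = list(map(str, feature_ids))
    if sample_ids is None:
        sample_ids = labels.sample_ids
    sample_ids = list(map(str, sample_ids))
    if X.shape[0] != len(sample_ids):
        raise ValueError("X rows and sample_ids length differ")
    y = np.array([labels[s] for s in sample_ids])

    observed = set(y)
    dropped = [s for s in vocab.subtypes if s not in observed]
    if dropped:
        warnings.warn(f"subtypes absent from design set, dropped: {dropped}")
    if CONTROL not in observed:
        warnings.warn("no CONTROL samples; control classifier skipped")

    step1_targets = []
    for cls in vocab.step1_classes(include_control=CONTROL in observed):
        if cls in vocab.groups:
            members = [m for m in vocab.group_members(cls) if m in observed]
            if members:
                step1_targets.append((cls, set(members)))
        elif cls in observed:
            step1_targets.append((cls, {cls}))

    cfg = {
        "positive_threshold": positive_threshold,
        "folds": folds,
        "seed": seed,
        "delta_grid_size": delta_grid_size,
        "tie_tolerance": tie_tolerance,
        "step1_prior_mode": step1_prior_mode,
        "step2_prior_mode": step2_prior_mode,
    }

    step1_models: dict = {}
    for cls, members in step1_targets:
        y_bin = np.where(np.isin(y, list(members)), cls, REST)
        m_seed = _seed_for(seed, f"step1:{cls}")
        grid = nsc.default_delta_grid(X, y_bin, size=delta_grid_size)
        delta_star, _ = nsc.select_delta_cv(
            X, y_bin, grid, folds=folds, seed=m_seed,
            prior_mode=step1_prior_mode, tie_tolerance=tie_tolerance,
        )
        step1_models[cls] = nsc.fit_nsc(
            X, y_bin, delta_star, step1_prior_mode, feature_ids=feature_ids
        )

    step2_models: dict = {}
    group_fallbacks: dict = {}
    for group in vocab.groups:
        members = [m for m in vocab.group_members(group) if m in observed]
        if len(members) < 2:
            if members and group in step1_models:
                warnings.warn(
                    f"group {group} has a single observed member {members[0]}; "
                    "step-2 model skipped"
                )
                group_fallbacks[group] = members[0]
            continue
        mask = np.isin(y, members)
        Xg, yg = X[mask], y[mask]
        g_seed = _seed_for(seed, f"step2:{group}")
        grid = nsc.default_delta_grid(Xg, yg, size=delta_grid_size)
        delta_star, _ = nsc.select_delta_cv(
            Xg, yg, grid, folds=folds, seed=g_seed,
            prior_mode=step2_prior_mode, tie_tolerance=tie_tolerance,
        )
        step2_models[group] = nsc.fit_nsc(
            Xg, yg, delta_star, step2_prior_mode, feature_ids=feature_ids
        )

    union: list = []
    seen: set = set()
    for model in list(step1_models.values()) + list(step2_models.values()):
        for f in nsc.selected_features(model):
            if f not in seen:
                seen.add(f)
                union.append(f)
    union = [f for f in feature_ids if f in seen]

    return SubtypeModel(
        modality=modality,
        vocab=vocab,
        step1_models=step1_models,
        step2_models=step2_models,
        positive_threshold=positive_threshold,
        feature_union=union,
        config=cfg,
        group_fallbacks=group_fallbacks,
    )


def predict_subtype(
    model: SubtypeModel, X, feature_ids=None, sample_ids=None
) -> list:
    """Classify each row of X; returns a list of :class:`SubtypeCall`."""
    X = np.asarray(X, dtype=float)
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(X.shape[0])]
    sample_ids = list(map(str, sample_ids))

    step1_scores = {
        cls: nsc.predict_scores(m, X, feature_ids)[cls].to_numpy()
        for cls, m in sorted(model.step1_models.items())
    }
    step2_scores = {
        g: nsc.predict_scores(m, X, feature_ids)
        for g, m in sorted(model.step2_models.items())
    }

    vocab = model.vocab
    calls = []
    for i, sid in enumerate(sample_ids):
        scores = {cls: float(v[i]) for cls, v in step1_scores.items()}
        label, score, positives, tie = resolve_multiclass(
            scores, model.positive_threshold
        )
        step2_label = step2_score = None
        resolved = label
        if label in vocab.groups:
            if label in step2_scores:
                row = step2_scores[label].iloc[i]
                step2_label = str(row.idxmax())
                step2_score = float(row.max())
                resolved = step2_label
            else:
                # group trained on a single observed member: descend directly
                resolved = model.group_fallbacks.get(
                    label, vocab.group_members(label)[0]
                )
        calls.append(
            SubtypeCall(
                sample_id=sid,
                modality=model.modality,
                step1_scores=scores,
                positives=positives,
                resolved_label=resolved,
                resolved_score=score,
                step2_label=step2_label,
                step2_score=step2_score,
                tie=tie,
            )
        )
    return calls


def calls_to_frame(calls) -> pd.DataFrame:
    """Tabular form of a list of calls (one row per sample)."""
    rows = []
    classes = sorted({c for call in calls for c in call.step1_scores})
    for call in calls:
        row = {
            "sample_id": call.sample_id,
            "modality": call.modality,
            "resolved_label": call.resolved_label,
            "resolved_score": call.resolved_score,
            "step2_label": call.step2_label if call.step2_label is not None else "",
            "step2_score": call.step2_score if call.step2_score is not None else "",
            "positives": ";".join(call.positives),
            "tie": call.tie,
        }
        for c in classes:
            row[f"score_{c}"] = call.step1_scores.get(c, "")
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_calls(df: pd.DataFrame) -> list:
    """Inverse of :func:`calls_to_frame` (scores sufficient for consensus)."""
    calls = []
    score_cols = [c for c in df.columns if c.startswith("score_")]
    for _, row in df.iterrows():
        step2_label = row.get("step2_label", "")
        step2_score = row.get("step2_score", "")
        calls.append(
            SubtypeCall(
                sample_id=str(row["sample_id"]),
                modality=str(row.get("modality", "")),
                step1_scores={
                    c[len("score_"):]: float(row[c]) for c in score_cols
                    if row[c] != "" and pd.notna(row[c])
                },
                positives=[p for p in str(row.get("positives", "")).split(";") if p],
                resolved_label=str(row["resolved_label"]),
                resolved_score=float(row["resolved_score"]),
                step2_label=None if step2_label in ("", None) or pd.isna(step2_label) else str(step2_label),
                step2_score=None if step2_score in ("", None) or pd.isna(step2_score) else float(step2_score),
                tie=bool(row.get("tie", False)),
            )
        )
    return calls


def model_to_dict(model: SubtypeModel) -> dict:
    return {
        "schema": MODEL_SCHEMA,
        "modality": model.modality,
        "positive_threshold": model.positive_threshold,
        "vocab": {
            "subtypes": list(model.vocab.subtypes),
            "groups": {g: list(m) for g, m in model.vocab.groups.items()},
        },
        "step1_models": {
            cls: nsc.model_to_dict(m) for cls, m in sorted(model.step1_models.items())
        },
        "step2_models": {
            g: nsc.model_to_dict(m) for g, m in sorted(model.step2_models.items())
        },
        "feature_union": list(model.feature_union),
        "config": model.config,
        "group_fallbacks": dict(sorted(model.group_fallbacks.items())),
    }


def model_from_dict(d: dict) -> SubtypeModel:
    if d.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {d.get('schema')!r}")
    vocab = SubtypeVocabulary(
        subtypes=tuple(d["vocab"]["subtypes"]),
        groups={g: tuple(m) for g, m in d["vocab"]["groups"].items()},
    )
    return SubtypeModel(
        modality=d["modality"],
        vocab=vocab,
        step1_models={
            cls: nsc.model_from_dict(m) for cls, m in d["step1_models"].items()
        },
        step2_models={
            g: nsc.model_from_dict(m) for g, m in d["step2_models"].items()
        },
        positive_threshold=float(d["positive_threshold"]),
        feature_union=list(d["feature_union"]),
        config=dict(d.get("config", {})),
        group_fallbacks=dict(d.get("group_fallbacks", {})),
    )


def save_model(model: SubtypeModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> SubtypeModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


__all__ = [
    "REST",
    "SubtypeCall",
    "SubtypeModel",
    "resolve_multiclass",
    "train_subtype_model",
    "predict_subtype",
    "calls_to_frame",
    "frame_to_calls",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]
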