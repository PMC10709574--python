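"""End-to-end convenience pipeline: cohort -> preprocess -> train -> score.

Chains the package's pieces the way a study would run them: variance
filtering of betas, gene filtering + GeTMM for counts, a stratified
design/hold-out split, per-modality training, hold-out prediction and
metric computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifier, evaluate, preprocessing
from .matrices import LabeledCohort
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort, with_blast_fraction
from .vocabulary import CONTROL, NO_CLASS


def preprocess_modality(cohort: SyntheticCohort, modality: str, variance_threshold: float = 0.01):
    """Model-ready matrix for one modality of a cohort."""
    if modality == "dnam":
        return preprocessing.filter_cpgs(cohort.dnam, variance_threshold)
    filtered = preprocessing.filter_genes(cohort.gex, cohort.annotation)
    return preprocessing.getmm_normalize(filtered, cohort.annotation)


@dataclass
class ModalityRun:
    modality: str
    model: classifier.SubtypeModel
    design: LabeledCohort
    holdout: LabeledCohort
    holdout_calls: list
    report: evaluate.MetricsReport


def train_and_evaluate(
    cohort: SyntheticCohort,
    modality: str,
    seed: int,
    holdout_fraction: float = 0.33,
    variance_threshold: float = 0.01,
) -> ModalityRun:
    """Split, train and score one modality of a (synthetic) cohort."""
    matrix = preprocess_modality(cohort, modality, variance_threshold)
    design, holdout = preprocessing.stratified_split(
        cohort.labels, holdout_fraction, seed=seed
    )
    ids_design = [s for s in matrix.sample_ids if s in design.labels]
    ids_holdout = [s for s in matrix.sample_ids if s in holdout.labels]
    X_design = matrix.subset_samples(ids_design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = classifier.train_subtype_model(
            X_design.values,
            matrix.feature_ids,
            design.subset(ids_design),
            modality=modality,
            seed=seed,
        )
    X_holdout = matrix.subset_samples(ids_holdout)
    calls = classifier.predict_subtype(
        model, X_holdout.values, matrix.feature_ids, ids_holdout
    )
    report = evaluate.score_predictions(holdout.subset(ids_holdout), calls)
    return ModalityRun(modality, model, design, holdout.subset(ids_holdout), calls, report)


def dilution_sweep(
    config: SimulationConfig,
    model: classifier.SubtypeModel,
    fractions=(1.0, 0.6, 0.2, 0.05),
    n_samples: int = 100,
) -> pd.DataFrame:
    """Re-simulate the same cohort structure at decreasing blast fractions
    and classify the first *n_samples* leukemic samples with *model*.

    Returns one row per blast fraction with the mean step-1 score of the
    sample's own (true) step-1 class, the mean CONTROL score, and the
    fraction of samples resolving to CONTROL or NO_CLASS.
    """
    base = simulate_cohort(config)
    leukemic = [s for s in base.labels.sample_ids if base.labels[s] != CONTROL]
    leukemic = leukemic[:n_samples]
    vocab = model.vocab
    rows = []
    for bf in fractions:
        cohort = simulate_cohort(with_blast_fraction(config, bf))
        sub = cohort.dnam.subset_samples(leukemic)
        calls = classifier.predict_subtype(
            model, sub.values, cohort.dnam.cpg_ids, leukemic
        )
        own = [
            c.step1_scores.get(vocab.step1_class_of(base.labels[c.sample_id]), 0.0)
            for c in calls
        ]
        ctrl = [c.step1_scores.get(CONTROL, 0.0) for c in calls]
        resolved_out = np.mean(
            [c.resolved_label in (CONTROL, NO_CLASS) for c in calls]
        )
        rows.append(
            {
                "blast_fraction": bf,
                "mean_own_class_score": float(np.mean(own)),
                "mean_control_score": float(np.mean(ctrl)),
                "fraction_control_or_no_class": float(resolved_out),
            }
        )
    return pd.DataFrame(rows)


__all__ = ["ModalityRun", "preprocess_modality", "train_and_evaluate", "dilution_sweep"]
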