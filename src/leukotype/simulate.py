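"""Seeded generator of multimodal synthetic cohorts.

The generator emulates the statistical structure the classifier
assumes, at desk scale:

- CpG beta values: baseline (non-leukemic) means drawn from a bimodal
  mixture concentrated near 0.1 and 0.9 (the classic array-like U
  shape); each subtype shifts a disjoint set of informative CpGs by
  ±``dnam_effect`` (clipped to [0.02, 0.98]); per-sample betas are Beta
  draws around the sample's mean profile with precision
  ``dnam_concentration``.
- Gene expression: baseline log2 mean levels are Normal; each subtype
  shifts disjoint informative genes by ±``gex_log_effect``; raw counts
  are negative-binomial with dispersion ``nb_dispersion``, mean
  proportional to expression level, gene length (kb) and a per-sample
  sequencing-depth factor.
- Blast fraction: each leukemic sample's mean profile is a mixture
  blast_fraction * subtype + (1 - blast_fraction) * control, applied at
  the signal level before noise, modeling dilution of the leukemic
  signal by normal cells in low-blast samples.
- Modalities may be dropped per sample, and orthogonal molecular
  evidence naming the true subtype is emitted for a fraction of
  leukemic samples.

Structure (baseline profiles, informative-feature manifest, gene
lengths) and sampling noise use separate child RNG streams of the one
seed, so two configs differing only in ``blast_fraction`` share an
identical cohort structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import EVIDENCE_KINDS, EvidenceRecord, read_evidence_tsv, write_evidence_tsv
from .matrices import (
    ExpressionMatrix,
    GeneAnnotation,
    LabeledCohort,
    MethylationMatrix,
    load_matrix,
    write_matrix,
)
from .vocabulary import CONTROL, DEFAULT_VOCAB, SubtypeVocabulary


@dataclass
class SimulationConfig:
    """Cohort-generation parameters (defaults = the package's study scale)."""

    vocab: SubtypeVocabulary = DEFAULT_VOCAB
    n_per_subtype: int = 20
    n_controls: int = 30
    n_cpgs_total: int = 2000
    n_genes_total: int = 1500
    n_informative_per_subtype: int = 25
    dnam_effect: float = 0.35  # beta-mean shift of informative CpGs
    dnam_concentration: float = 30.0  # Beta-distribution precision
    gex_log_effect: float = 2.0  # log2 mean shift of informative genes
    nb_dispersion: float = 0.1  # NB variance = mu + disp * mu^2
    gene_length_range: tuple = (200, 10000)  # bp
    blast_fraction: float = 1.0  # leukemic-cell fraction per sample
    missing_modality_rate: float = 0.0
    evidence_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        n_subtypes = len(self.vocab.subtypes)
        if min(self.n_per_subtype, self.n_controls, self.n_cpgs_total,
               self.n_genes_total, self.n_informative_per_subtype) <= 0:
            raise ValueError("counts must be positive")
        needed = n_subtypes * self.n_informative_per_subtype
        if needed > self.n_cpgs_total or needed > self.n_genes_total:
            raise ValueError(
                f"{needed} informative features exceed the feature totals"
            )
        if not 0 <= self.blast_fraction <= 1:
            raise ValueError("blast_fraction must be in [0, 1]")
        if self.dnam_effect < 0 or self.gex_log_effect < 0:
            raise ValueError("effect sizes must be >= 0")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    dnam: MethylationMatrix
    gex: ExpressionMatrix  # raw counts
    annotation: GeneAnnotation
    labels: LabeledCohort  # truth, includes CONTROL samples
    evidence: list = field(default_factory=list)
    blast_fractions: dict = field(default_factory=dict)
    informative: dict = field(default_factory=dict)  # modality -> subtype -> ids


def _clip_means(m: np.ndarray) -> np.ndarray:
    return np.clip(m, 0.02, 0.98)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort; bit-reproducible for a given config."""
    vocab = config.vocab
    subtypes = list(vocab.subtypes)
    n_subtypes = len(subtypes)
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_noise, rng_assign = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )

    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpgs_total)]
    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes_total)]
    sample_ids = [f"P{i:04d}" for i in range(n_subtypes * config.n_per_subtype)]
    control_ids = [f"N{i:04d}" for i in range(config.n_controls)]
    truth = {
        sid: subtypes[i // config.n_per_subtype] for i, sid in enumerate(sample_ids)
    }
    truth.update({sid: CONTROL for sid in control_ids})

    # --- structure stream: baselines, manifests, lengths, shift signs ---
    k = config.n_informative_per_subtype
    hi = rng_struct.random(config.n_cpgs_total) < 0.5
    cpg_base = np.where(
        hi,
        rng_struct.beta(45, 5, config.n_cpgs_total),
        rng_struct.beta(5, 45, config.n_cpgs_total),
    )
    cpg_pick = rng_struct.choice(
        config.n_cpgs_total, size=n_subtypes * k, replace=False
    )
    gene_base = np.clip(rng_struct.normal(5.0, 1.5, config.n_genes_total), 0.5, None)
    gene_pick = rng_struct.choice(
        config.n_genes_total, size=n_subtypes * k, replace=False
    )
    lengths = rng_struct.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1,
        config.n_genes_total,
    )
    # shift away from the nearer boundary when a random sign would clip
    # (hypermethylate unmethylated CpGs and vice versa), so informative
    # features carry the full stated effect size
    raw_c = rng_struct.choice([-1.0, 1.0], size=n_subtypes * k)
    raw_g = rng_struct.choice([-1.0, 1.0], size=n_subtypes * k)
    base_c = cpg_base[cpg_pick]
    up_ok = base_c + config.dnam_effect <= 0.98
    down_ok = base_c - config.dnam_effect >= 0.02
    cpg_signs = np.where(up_ok & down_ok, raw_c, np.where(up_ok, 1.0, -1.0))
    base_g = gene_base[gene_pick]
    g_down_ok = base_g - config.gex_log_effect >= 0.0
    gene_signs = np.where(g_down_ok, raw_g, 1.0)

    informative = {"dnam": {}, "gex": {}}
    cpg_means = {}  # subtype -> mean profile
    gex_means = {}
    for j, subtype in enumerate(subtypes):
        ci = cpg_pick[j * k:(j + 1) * k]
        gi = gene_pick[j * k:(j + 1) * k]
        informative["dnam"][subtype] = [cpg_ids[i] for i in ci]
        informative["gex"][subtype] = [gene_ids[i] for i in gi]
        cm = cpg_base.copy()
        cm[ci] = _clip_means(cm[ci] + cpg_signs[j * k:(j + 1) * k] * config.dnam_effect)
        cpg_means[subtype] = cm
        gm = gene_base.copy()
        gm[gi] = np.clip(
            gm[gi] + gene_signs[j * k:(j + 1) * k] * config.gex_log_effect, 0.0, None
        )
        gex_means[subtype] = gm

    # --- noise stream: per-sample draws ---
    all_ids = sample_ids + control_ids
    bf = {
        sid: (config.blast_fraction if truth[sid] != CONTROL else 1.0)
        for sid in all_ids
    }
    conc = config.dnam_concentration
    betas = np.empty((len(all_ids), config.n_cpgs_total))
    counts = np.empty((len(all_ids), config.n_genes_total))
    depth = rng_noise.uniform(0.5, 1.5, len(all_ids))
    r = 1.0 / config.nb_dispersion
    for i, sid in enumerate(all_ids):
        if truth[sid] == CONTROL:
            mean_cpg, mean_gex = cpg_base, gene_base
        else:
            f = bf[sid]
            mean_cpg = f * cpg_means[truth[sid]] + (1 - f) * cpg_base
            mean_gex = f * gex_means[truth[sid]] + (1 - f) * gene_base
        m = np.clip(mean_cpg, 1e-3, 1 - 1e-3)
        betas[i] = rng_noise.beta(m * conc, (1 - m) * conc)
        mu = depth[i] * (2.0 ** mean_gex) * (lengths / 1000.0)
        counts[i] = rng_noise.negative_binomial(r, r / (r + mu))

    # --- assignment stream: missing modalities, evidence ---
    drop_dnam, drop_gex = set(), set()
    for sid in all_ids:
        if rng_assign.random() < config.missing_modality_rate:
            (drop_dnam if rng_assign.random() < 0.5 else drop_gex).add(sid)
    evidence = []
    kinds = sorted(EVIDENCE_KINDS)
    for sid in sample_ids:
        if rng_assign.random() < config.evidence_rate:
            kind = kinds[rng_assign.integers(len(kinds))]
            evidence.append(EvidenceRecord(sid, truth[sid], frozenset({kind})))

    keep_d = [i for i, sid in enumerate(all_ids) if sid not in drop_dnam]
    keep_g = [i for i, sid in enumerate(all_ids) if sid not in drop_gex]
    dnam = MethylationMatrix(
        [all_ids[i] for i in keep_d], cpg_ids, betas[keep_d]
    )
    gex = ExpressionMatrix(
        [all_ids[i] for i in keep_g], gene_ids, counts[keep_g], "raw_counts"
    )
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chromosome": [str(1 + i % 22) for i in range(config.n_genes_total)],
                "length_bp": lengths,
                "biotype": "protein_coding",
                "symbol": [f"SYM{i:05d}" for i in range(config.n_genes_total)],
            }
        )
    )
    return SyntheticCohort(
        dnam=dnam,
        gex=gex,
        annotation=annotation,
        labels=LabeledCohort(truth),
        evidence=evidence,
        blast_fractions=bf,
        informative=informative,
    )


def with_blast_fraction(config: SimulationConfig, blast_fraction: float) -> SimulationConfig:
    """The same cohort structure at a different leukemic-cell fraction."""
    return replace(config, blast_fraction=blast_fraction)


def write_fixtures(cohort: SyntheticCohort, out_dir) -> dict:
    """Write all cohort files as delimited text; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dnam": out / "dnam_betas.tsv",
        "gex": out / "gex_counts.tsv",
        "annotation": out / "gene_annotation.tsv",
        "labels": out / "labels.tsv",
        "evidence": out / "evidence.tsv",
        "blast_fractions": out / "blast_fractions.tsv",
        "informative": out / "informative_features.json",
    }
    write_matrix(cohort.dnam, paths["dnam"])
    write_matrix(cohort.gex, paths["gex"])
    cohort.annotation.write_tsv(paths["annotation"])
    cohort.labels.write_tsv(paths["labels"])
    write_evidence_tsv(cohort.evidence, paths["evidence"])
    pd.DataFrame(
        {
            "sample_id": list(cohort.blast_fractions),
            "blast_fraction": list(cohort.blast_fractions.values()),
        }
    ).to_csv(paths["blast_fractions"], sep="\t", index=False, float_format="%.17g")
    with open(paths["informative"], "w") as fh:
        json.dump(cohort.informative, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def load_fixtures(in_dir) -> SyntheticCohort:
    """Round-trip loader for :func:`write_fixtures` output."""
    d = Path(in_dir)
    labels = LabeledCohort.read_tsv(d / "labels.tsv")
    bf = pd.read_csv(d / "blast_fractions.tsv", sep="\t")
    with open(d / "informative_features.json") as fh:
        informative = json.load(fh)
    return SyntheticCohort(
        dnam=load_matrix(d / "dnam_betas.tsv", "dnam", sample_ids=labels.sample_ids),
        gex=load_matrix(d / "gex_counts.tsv", "gex", sample_ids=labels.sample_ids),
        annotation=GeneAnnotation.read_tsv(d / "gene_annotation.tsv"),
        labels=labels,
        evidence=read_evidence_tsv(d / "evidence.tsv"),
        blast_fractions=dict(zip(bf["sample_id"].astype(str), bf["blast_fraction"])),
        informative=informative,
    )


__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "with_blast_fraction",
    "write_fixtures",
    "load_fixtures",
]
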