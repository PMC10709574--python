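"""Filtering, normalization and cohort splitting.

The methylation side keeps CpGs that vary across samples (population
variance at or above a threshold, optionally intersected with an array
manifest whitelist).  The expression side removes sex-chromosome,
mitochondrial, scaffold, ribosomal-protein and non-protein-coding genes,
then normalizes counts with gene-length-corrected trimmed mean of
M-values (GeTMM): reads per kilobase, TMM scaling of effective library
sizes, counts-per-million scaling and a log2(x + 1) transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import (
    LOG2_GETMM,
    RAW_COUNTS,
    ExpressionMatrix,
    GeneAnnotation,
    LabeledCohort,
    MethylationMatrix,
)
from .vocabulary import B_OTHER

#: Chromosomes retained by the gene filter (autosomes + X).
CANONICAL_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X"])


def filter_cpgs(
    m: MethylationMatrix,
    variance_threshold: float = 0.01,
    whitelist=None,
) -> MethylationMatrix:
    """Keep CpGs with across-sample variance >= threshold (and in whitelist).

    Variance is the population variance (divide by n), NaN-aware.  The
    surviving CpGs keep their original order and values.
    """
    if variance_threshold < 0:
        raise ValueError("variance_threshold must be >= 0")
    with np.errstate(invalid="ignore"):
        var = np.nanvar(m.values, axis=0, ddof=0)
    keep = var >= variance_threshold
    keep &= ~np.isnan(var)
    if whitelist is not None:
        wl = set(map(str, whitelist))
        keep &= np.array([c in wl for c in m.cpg_ids])
    if not keep.any():
        raise ValueError(
            "no CpGs survive filtering; reduce variance_threshold "
            f"(currently {variance_threshold}) or relax the whitelist"
        )
    idx = np.flatnonzero(keep)
    return MethylationMatrix(
        list(m.sample_ids), [m.cpg_ids[i] for i in idx], m.values[:, idx]
    )


def _normalize_chromosome(chrom: str) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return "MT" if c.upper() in ("M", "MT") else c.upper() if c.upper() in ("X", "Y") else c


def filter_genes(e: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Drop Y/MT/scaffold genes, RPS/RPL ribosomal genes, non-protein-coding."""
    if e.state != RAW_COUNTS:
        raise ValueError("filter_genes expects a raw-count matrix")
    rows = ann.require(e.gene_ids)
    chrom = rows["chromosome"].map(_normalize_chromosome)
    symbol = rows["symbol"].astype(str)
    keep = (
        chrom.isin(CANONICAL_CHROMOSOMES)
        & ~symbol.str.startswith(("RPS", "RPL"))
        & (rows["biotype"] == "protein_coding")
    ).to_numpy()
    idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        list(e.sample_ids), [e.gene_ids[i] for i in idx], e.values[:, idx], RAW_COUNTS
    )


def _tmm_factor(rpk_s, rpk_r, trim_m: float, trim_a: float) -> float:
    """Doubly trimmed weighted mean of M-values for one sample vs reference."""
    n_s, n_r = rpk_s.sum(), rpk_r.sum()
    use = (rpk_s > 0) & (rpk_r > 0)
    if not use.any():
        return 1.0
    p_s, p_r = rpk_s[use] / n_s, rpk_r[use] / n_r
    m = np.log2(p_s / p_r)
    a = 0.5 * np.log2(p_s * p_r)
    # precision weights on relative abundances (delta-method form, written
    # in proportions so the factor is exactly library-size invariant)
    w = (1.0 - p_s) / p_s + (1.0 - p_r) / p_r
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    kept = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not kept.any() or w[kept].sum() == 0:
        return 1.0
    return float(2 ** (np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])))


def getmm_normalize(
    e: ExpressionMatrix,
    ann: GeneAnnotation,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> ExpressionMatrix:
    """GeTMM normalization of a raw-count matrix, returning log2 values.

    Per gene, reads per kilobase rpk = count / (length_bp / 1000).  TMM
    scaling factors are computed on the rpk matrix against a reference
    sample (the one whose upper-quartile of relative rpk is closest to
    the cohort mean), with symmetric trimming of ``trim_m`` on M-values
    and ``trim_a`` on A-values; factors are renormalized to geometric
    mean 1.  Output values are log2(rpk * 1e6 / (sum(rpk) * factor) + 1).

    The result is invariant under scaling any one sample's counts by a
    positive constant (library-size removal).
    """
    if e.state != RAW_COUNTS:
        raise ValueError("getmm_normalize expects a raw-count matrix")
    rows = ann.require(e.gene_ids)
    lengths = rows["length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = e.values.sum(axis=1)
    if (lib == 0).any():
        zero = [e.sample_ids[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"all-zero samples cannot be normalized: {zero}")

    rpk = e.values / (lengths / 1000.0)
    n = rpk.sum(axis=1)

    if len(e.sample_ids) == 1:
        factors = np.array([1.0])
    else:
        # reference: upper quartile of relative rpk closest to the mean
        uq = np.array([np.quantile(rpk[i] / n[i], 0.75) for i in range(rpk.shape[0])])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        factors = np.array(
            [
                1.0 if i == ref else _tmm_factor(rpk[i], rpk[ref], trim_m, trim_a)
                for i in range(rpk.shape[0])
            ]
        )
        factors /= np.exp(np.mean(np.log(factors)))

    scaled = rpk * 1e6 / (n * factors)[:, None]
    return ExpressionMatrix(
        list(e.sample_ids), list(e.gene_ids), np.log2(scaled + 1.0), LOG2_GETMM
    )


def stratified_split(
    cohort: LabeledCohort, holdout_fraction: float = 0.33, seed: int = 0
):
    """Split a labeled cohort into design and hold-out sets, per label.

    Per label with n samples, round(n * holdout_fraction) (half-up) go
    to the hold-out set, at least 1 when n >= 2 and 0 when n == 1.
    Deterministic for a given seed; design and hold-out partition the
    input.  Discovery (B_OTHER) samples must be split off beforehand.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    if B_OTHER in cohort.labels.values():
        raise ValueError("split cohort must not contain B_OTHER (discovery) samples")
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for sid, lab in cohort.labels.items():
        by_label.setdefault(lab, []).append(sid)
    design, holdout = {}, {}
    for lab in sorted(by_label):
        ids = sorted(by_label[lab])
        n = len(ids)
        n_hold = 0 if n == 1 else max(1, int(np.floor(n * holdout_fraction + 0.5)))
        n_hold = min(n_hold, n - 1)
        perm = rng.permutation(n)
        chosen = {ids[i] for i in perm[:n_hold]}
        for sid in ids:
            (holdout if sid in chosen else design)[sid] = lab
    return LabeledCohort(design), LabeledCohort(holdout)


__all__ = [
    "CANONICAL_CHROMOSOMES",
    "filter_cpgs",
    "filter_genes",
    "getmm_normalize",
    "stratified_split",
]
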