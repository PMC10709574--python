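"""Consensus subtype assignment across modalities with confidence tiers.

Per-modality calls and orthogonal molecular evidence (an expressed
fusion gene, copy-number aberration, karyotype or mutation supporting a
subtype) are combined into a single consensus subtype with a confidence
tier:

- Tier 1: a high-score call from either modality matches the evidence.
- Tier 2: both modalities agree on a subtype, without conclusive
  evidence.
- Tier 3: only one informative call — a single available modality, or
  one modality NO_CLASS — provided that call scores high.
- Tier 4: conflicting calls, evidence contradicting every call, or only
  low-confidence information; the sample stays UNRESOLVED.

CONTROL calls are treated as NO_CLASS here: a sample predicted as
non-leukemic cannot be subtype-annotated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .vocabulary import CONTROL, NO_CLASS, UNRESOLVED

EVIDENCE_KINDS = frozenset({"fusion", "CNA", "karyotype", "mutation"})


@dataclass(frozen=True)
class EvidenceRecord:
    """Orthogonal molecular support for one sample's subtype."""

    sample_id: str
    supported_subtype: str | None
    evidence_kind: frozenset = frozenset()

    def __post_init__(self):
        kinds = frozenset(self.evidence_kind)
        object.__setattr__(self, "evidence_kind", kinds)
        unknown = kinds - EVIDENCE_KINDS
        if unknown:
            raise ValueError(f"unknown evidence kinds: {sorted(unknown)}")
        if bool(self.supported_subtype) != bool(kinds):
            raise ValueError(
                "evidence_kind must be non-empty exactly when a supported "
                "subtype is present"
            )


@dataclass(frozen=True)
class ConsensusCall:
    sample_id: str
    consensus_subtype: str  # subtype or UNRESOLVED
    tier: int
    rationale: str
    inputs_used: tuple  # modalities that contributed


def _as_subtype_call(call):
    """(label, score) with CONTROL and NO_CLASS collapsed to no call."""
    if call is None:
        return None
    label = call.resolved_label
    if label in (NO_CLASS, CONTROL):
        return (None, float(call.resolved_score))
    return (label, float(call.resolved_score))


def assign_tier(
    dnam=None,
    gex=None,
    evidence: EvidenceRecord | None = None,
    high_score: float = 0.8,
) -> ConsensusCall:
    """Combine up to two modality calls and evidence into a consensus call.

    Rules are applied in priority order (first match wins); every
    combination of inputs maps to exactly one tier.
    """
    if dnam is None and gex is None:
        raise ValueError("at least one modality call is required")
    if not 0 < high_score < 1:
        raise ValueError("high_score must be in (0, 1)")

    present = {}
    if dnam is not None:
        present["dnam"] = _as_subtype_call(dnam)
    if gex is not None:
        present["gex"] = _as_subtype_call(gex)
    inputs = tuple(sorted(present))
    sample_id = (dnam or gex).sample_id

    calls = {m: v for m, v in present.items() if v[0] is not None}
    labels = {v[0] for v in calls.values()}
    supported = evidence.supported_subtype if evidence is not None else None

    def done(subtype, tier, rule):
        return ConsensusCall(sample_id, subtype, tier, rule, inputs)

    # Tier 1: high-score call matching molecular evidence
    if supported is not None:
        for m in sorted(calls):
            label, score = calls[m]
            if label == supported and score >= high_score:
                return done(supported, 1, "T1_evidence_high_score")
        if labels and supported not in labels:
            # evidence contradicts every modality call: conservative demotion
            return done(UNRESOLVED, 4, "T4_evidence_conflict")

    # Tier 2: both modalities call the same subtype
    if len(present) == 2 and len(calls) == 2 and len(labels) == 1:
        return done(next(iter(labels)), 2, "T2_concordant_modalities")

    # Tier 3: a single informative high-score call
    if len(calls) == 1:
        (label, score), = calls.values()
        if score >= high_score:
            rule = (
                "T3_single_modality"
                if len(present) == 1
                else "T3_one_no_class_one_high"
            )
            return done(label, 3, rule)

    # Tier 4: conflicting or low-confidence information
    rule = "T4_conflicting_calls" if len(labels) > 1 else "T4_low_confidence"
    return done(UNRESOLVED, 4, rule)


def consensus_calls(
    dnam_calls=None,
    gex_calls=None,
    evidence=None,
    high_score: float = 0.8,
) -> list:
    """Apply :func:`assign_tier` across a cohort.

    ``dnam_calls``/``gex_calls`` are lists of per-sample calls;
    ``evidence`` a list of :class:`EvidenceRecord`.  Samples present in
    either modality are tiered.
    """
    dnam_by = {c.sample_id: c for c in (dnam_calls or [])}
    gex_by = {c.sample_id: c for c in (gex_calls or [])}
    ev_by = {e.sample_id: e for e in (evidence or [])}
    out = []
    for sid in sorted(set(dnam_by) | set(gex_by)):
        out.append(
            assign_tier(
                dnam_by.get(sid), gex_by.get(sid), ev_by.get(sid), high_score
            )
        )
    return out


def consensus_table(calls) -> pd.DataFrame:
    """Counts per (tier, consensus subtype), empty strata omitted.

    The table carries the grand total in ``df.attrs["total"]``; the sum
    of counts always equals the number of input calls.
    """
    if not calls:
        raise ValueError("no consensus calls to summarize")
    df = pd.DataFrame(
        {
            "tier": [c.tier for c in calls],
            "consensus_subtype": [c.consensus_subtype for c in calls],
        }
    )
    table = (
        df.groupby(["tier", "consensus_subtype"], sort=True)
        .size()
        .reset_index(name="count")
    )
    table.attrs["total"] = len(calls)
    table.attrs["by_tier"] = df.groupby("tier").size().to_dict()
    return table


def read_evidence_tsv(path) -> list:
    """Two-plus-column TSV: sample_id, supported_subtype [, kinds (;-list)]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        subtype = row.iloc[1] or None
        kinds = (
            frozenset(k for k in str(row.iloc[2]).split(";") if k)
            if len(row) > 2 and row.iloc[2]
            else (frozenset({"fusion"}) if subtype else frozenset())
        )
        out.append(EvidenceRecord(str(row.iloc[0]), subtype, kinds))
    return out


def write_evidence_tsv(records, path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "supported_subtype": [r.supported_subtype or "" for r in records],
            "evidence_kind": [";".join(sorted(r.evidence_kind)) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


__all__ = [
    "EVIDENCE_KINDS",
    "EvidenceRecord",
    "ConsensusCall",
    "assign_tier",
    "consensus_calls",
    "consensus_table",
    "read_evidence_tsv",
    "write_evidence_tsv",
]
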