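"""The molecular subtype vocabulary and the two-step class hierarchy.

Seventeen established subtypes of pediatric acute lymphoblastic leukemia
are classified either standalone or, for subtypes with closely related
molecular profiles, through an intermediate group: the aneuploidies
(HeH, low HeH, iAMP21, hypodiploidy), the ETV6-rearranged pair
(ETV6::RUNX1 and its -like signature), and the Philadelphia-chromosome
pair (BCR::ABL1 and BCR::ABL1-like).  Sentinel labels cover
non-leukemic controls, unclassifiable samples, and the B-other
discovery category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONTROL = "CONTROL"
NO_CLASS = "NO_CLASS"
B_OTHER = "B_OTHER"
UNRESOLVED = "UNRESOLVED"

SUBTYPES = (
    "HeH",
    "low_HeH",
    "iAMP21",
    "hypodiploidy",
    "ETV6_RUNX1",
    "ETV6_RUNX1_like",
    "KMT2A_r",
    "NUTM1_r",
    "PAX5alt",
    "PAX5_P80R",
    "TCF3_PBX1",
    "MEF2D_r",
    "BCR_ABL1",
    "BCR_ABL1_like",
    "DUX4_r",
    "ZNF384_r",
    "T_ALL",
)

GROUPS = {
    "ANEUPLOIDY": ("HeH", "low_HeH", "iAMP21", "hypodiploidy"),
    "ETV6_GROUP": ("ETV6_RUNX1", "ETV6_RUNX1_like"),
    "PH_GROUP": ("BCR_ABL1", "BCR_ABL1_like"),
}


@dataclass(frozen=True)
class SubtypeVocabulary:
    """Subtype labels plus the group hierarchy used for step-1 classes."""

    subtypes: tuple = SUBTYPES
    groups: dict = field(default_factory=lambda: dict(GROUPS))

    def __post_init__(self):
        members = [m for g in self.groups.values() for m in g]
        if len(members) != len(set(members)):
            raise ValueError("groups must not share member subtypes")
        unknown = set(members) - set(self.subtypes)
        if unknown:
            raise ValueError(f"group members not in subtype list: {sorted(unknown)}")

    @property
    def grouped_subtypes(self) -> set:
        return {m for g in self.groups.values() for m in g}

    @property
    def standalone_subtypes(self) -> tuple:
        return tuple(s for s in self.subtypes if s not in self.grouped_subtypes)

    def step1_class_of(self, subtype: str) -> str:
        """The step-1 class a subtype is called through (its group or itself)."""
        for group, members in self.groups.items():
            if subtype in members:
                return group
        if subtype in self.subtypes or subtype == CONTROL:
            return subtype
        raise KeyError(f"unknown subtype {subtype!r}")

    def step1_classes(self, include_control: bool = True) -> tuple:
        classes = self.standalone_subtypes + tuple(self.groups)
        if include_control:
            classes = classes + (CONTROL,)
        return tuple(sorted(classes))

    def group_members(self, group: str) -> tuple:
        return tuple(self.groups[group])


DEFAULT_VOCAB = SubtypeVocabulary()

__all__ = [
    "CONTROL",
    "NO_CLASS",
    "B_OTHER",
    "UNRESOLVED",
    "SUBTYPES",
    "GROUPS",
    "SubtypeVocabulary",
    "DEFAULT_VOCAB",
]
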