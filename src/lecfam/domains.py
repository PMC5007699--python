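"""Domain-hit model, the dual-domain family filter and G/L/C typing.

A protein belongs to the LecRLK family iff it carries at least one lectin
domain and at least one protein-kinase domain.  The lectin identity then
fixes the subfamily: bulb (mannose-binding) lectin -> G-type, legume
lectin -> L-type, calcium-dependent lectin -> C-type.  Accessory domains
(S-locus glycoprotein, EGF, PAN, DUF3403) are carried in the architecture
string but play no role in membership.  Domain hits arrive as a table
(protein, accession, start, end, score) emulating Pfam/InterPro output;
accessions map to roles through a fully overridable vocabulary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

logger = logging.getLogger(__name__)

Role = Literal[
    "lectin_bulb",
    "lectin_legume",
    "lectin_C",
    "kinase",
    "s_locus",
    "egf",
    "pan",
    "duf3403",
    "other",
]

LECTIN_ROLES = frozenset({"lectin_bulb", "lectin_legume", "lectin_C"})

#: lectin role -> subfamily letter
TYPE_BY_LECTIN: Mapping[str, str] = {
    "lectin_bulb": "G",
    "lectin_legume": "L",
    "lectin_C": "C",
}


class AmbiguousTypeError(ValueError):
    """A protein carries lectin domains of more than one identity.

    Never resolved silently: mixed lectin identities indicate an
    annotation problem upstream, not a real subfamily.
    """

    def __init__(self, protein_id: str, roles: Sequence[str]):
        self.protein_id = protein_id
        self.roles = tuple(sorted(set(roles)))
        super().__init__(f"{protein_id}: multiple distinct lectin roles {self.roles}")


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    accession: str
    role: str
    start: int  # 1-based inclusive
    end: int
    score: float

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates [{self.start}, {self.end}] for {self.protein_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainVocabulary:
    """Accession -> (role, expected full model length in residues)."""

    mapping: Mapping[str, tuple[str, int]]

    def __post_init__(self):
        roles = {role for role, _ in self.mapping.values()}
        for lectin in LECTIN_ROLES:
            if lectin not in roles:
                raise ValueError(f"vocabulary maps no accession to lectin role {lectin!r}")
        for acc, (_, model_length) in self.mapping.items():
            if model_length <= 10:
                raise ValueError(f"{acc}: model_length must exceed 10 residues")

    def role_of(self, accession: str) -> str:
        return self.mapping[accession][0]

    def model_length(self, accession: str) -> int:
        return self.mapping[accession][1]

    def __contains__(self, accession: str) -> bool:
        return accession in self.mapping


# Pfam-style names; model lengths are the expected full-length domain sizes
# used by the truncation rule (hit shorter by >= 10 residues => truncated).
DEFAULT_VOCABULARY = DomainVocabulary(
    {
        "B_lectin": ("lectin_bulb", 108),
        "Lectin_legB": ("lectin_legume", 233),
        "Lectin_C": ("lectin_C", 108),
        "Pkinase": ("kinase", 253),
        "Pkinase_Tyr": ("kinase", 259),
        "S_locus_glycop": ("s_locus", 176),
        "PAN_1": ("pan", 86),
        "PAN_2": ("pan", 74),
        "EGF": ("egf", 36),
        "EGF_CA": ("egf", 42),
        "DUF3403": ("duf3403", 89),
    }
)


@dataclass(frozen=True)
class FamilyMember:
    protein_id: str
    lec_type: str  # G | L | C
    architecture: tuple[str, ...]  # roles ordered by start coordinate
    truncated_lectin: bool
    truncated_kinase: bool


@dataclass(frozen=True)
class RejectedProtein:
    protein_id: str
    reason: Literal["no_lectin", "no_kinase", "neither"]


def _dedupe(hits: Sequence[DomainHit]) -> list[DomainHit]:
    seen: dict[tuple, DomainHit] = {}
    for hit in hits:
        key = (hit.protein_id, hit.accession, hit.start, hit.end)
        if key in seen:
            logger.warning("duplicate hit %s dropped", key)
            continue
        seen[key] = hit
    return list(seen.values())


def assign_type(hits: Sequence[DomainHit]) -> str:
    """Subfamily letter from the lectin identity of a filtered member."""
    lectins = sorted({h.role for h in hits if h.role in LECTIN_ROLES})
    if not lectins:
        raise ValueError("assign_type called on a protein without a lectin hit")
    if len(lectins) > 1:
        raise AmbiguousTypeError(hits[0].protein_id, lectins)
    return TYPE_BY_LECTIN[lectins[0]]


def architecture_string(hits: Sequence[DomainHit]) -> tuple[str, ...]:
    """Roles ordered along the sequence, multiplicities preserved."""
    return tuple(h.role for h in sorted(hits, key=lambda h: (h.start, h.end, h.role)))


def detect_truncation(hit: DomainHit, vocab: DomainVocabulary = DEFAULT_VOCABULARY, margin: int = 10) -> bool:
    """A hit is truncated iff it is at least ``margin`` residues shorter
    than the full domain model."""
    if hit.accession not in vocab:
        raise KeyError(f"unknown accession {hit.accession!r}")
    return hit.length <= vocab.model_length(hit.accession) - margin


def filter_lecrlk(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
    truncation_margin: int = 10,
) -> tuple[list[FamilyMember], list[RejectedProtein]]:
    """Dual-domain family filter: members need a lectin AND a kinase hit.

    Returns members (with subfamily type, architecture and truncation
    flags) and the rejected proteins with reasons.  Together they
    partition the input.  Truncated domains are reported, never filtered:
    a member with a shortened kinase domain is still a member.
    """
    members: list[FamilyMember] = []
    rejected: list[RejectedProtein] = []
    for protein_id in hits_by_protein:
        hits = _dedupe(list(hits_by_protein[protein_id]))
        has_lectin = any(h.role in LECTIN_ROLES for h in hits)
        has_kinase = any(h.role == "kinase" for h in hits)
        if has_lectin and has_kinase:
            lec_type = assign_type(hits)
            trunc_lectin = any(
                h.role in LECTIN_ROLES and h.accession in vocab and detect_truncation(h, vocab, truncation_margin)
                for h in hits
            )
            trunc_kinase = any(
                h.role == "kinase" and h.accession in vocab and detect_truncation(h, vocab, truncation_margin)
                for h in hits
            )
            members.append(
                FamilyMember(
                    protein_id=protein_id,
                    lec_type=lec_type,
                    architecture=architecture_string(hits),
                    truncated_lectin=trunc_lectin,
                    truncated_kinase=trunc_kinase,
                )
            )
        else:
            if has_lectin:
                reason = "no_kinase"
            elif has_kinase:
                reason = "no_lectin"
            else:
                reason = "neither"
            rejected.append(RejectedProtein(protein_id, reason))
    return members, rejected


def group_hits(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.protein_id, []).append(hit)
    return grouped
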