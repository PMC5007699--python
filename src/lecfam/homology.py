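"""Pairwise protein alignment and reciprocal percent-similarity homolog search.

The family search follows the classical manual protocol for gene-family
expansion: a known query is aligned against the whole proteome with an
affine-gap Smith-Waterman (BLOSUM62, gap open 10 / extend 0.2), every
subject with more than 30% amino-acid similarity is collected, and the
best hit is then used as the next query ("reciprocal" expansion) until
no new homologs appear.  Percent similarity is the fraction of alignment
columns (gap columns included in the denominator) whose substitution
score is positive; this "positives" definition is stated explicitly
because database front-ends that report percent similarity rarely
document their denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

Mode = Literal["local", "global"]


class InvalidResidueError(ValueError):
    """A sequence contains a symbol outside the 20 standard amino acids + X."""

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position
        super().__init__(f"invalid residue {symbol!r} at position {position} (1-based)")


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in VALID_RESIDUES:
            raise InvalidResidueError(ch, i + 1)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix and affine gap costs.

    A gap of length k costs ``gap_open_cost + k * gap_extend_cost``.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open_cost: float = 10.0
    gap_extend_cost: float = 0.2

    def __post_init__(self):
        if not (self.gap_open_cost >= self.gap_extend_cost > 0):
            raise ValueError("require gap_open_cost >= gap_extend_cost > 0")

    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix)


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    aligned_pairs: tuple[tuple[int, int], ...]  # 1-based residue coordinates
    similarity: float
    identity: float
    mode: Mode

    def __post_init__(self):
        if not (0.0 <= self.identity <= self.similarity <= 1.0):
            raise ValueError("require 0 <= identity <= similarity <= 1")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with the locus identity shared by its isoforms."""

    id: str
    sequence: str
    isoform_group: str

    def __post_init__(self):
        _check_sequence(self.sequence)


_ISOFORM_SUFFIX = re.compile(r"\.\d+$")


def isoform_group_from_id(protein_id: str) -> str:
    """Strip a trailing ``.N`` isoform suffix (Phytozome-style ids)."""
    return _ISOFORM_SUFFIX.sub("", protein_id)


def _make_aligner(scheme: ScoringScheme, mode: Mode) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = scheme.matrix()
    aligner.mode = mode
    # Biopython scores the first gap position with open_gap_score and each
    # further position with extend_gap_score; our convention charges
    # open + k*extend for a length-k gap.
    aligner.open_gap_score = -(scheme.gap_open_cost + scheme.gap_extend_cost)
    aligner.extend_gap_score = -scheme.gap_extend_cost
    return aligner


def align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME, mode: Mode = "local") -> AlignmentResult:
    """Optimal affine-gap pairwise alignment of two protein sequences.

    similarity = positive-scoring columns / alignment length (gaps included);
    identity   = identical columns / alignment length.
    In local mode an all-non-positive comparison yields the empty alignment
    with score 0.
    """
    _check_sequence(a)
    _check_sequence(b)
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    aligner = _make_aligner(scheme, mode)
    alignments = aligner.align(a, b)
    if mode == "local" and float(alignments.score) <= 0:
        return AlignmentResult(0.0, (), 0.0, 0.0, mode)
    best = alignments[0]
    score = float(best.score)

    matrix = scheme.matrix()
    row_a, row_b = best[0], best[1]
    length = len(row_a)
    positives = identities = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        if matrix[x, y] > 0:
            positives += 1
        if x == y:
            identities += 1

    pairs: list[tuple[int, int]] = []
    blocks_a, blocks_b = best.aligned
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        for k in range(ea - sa):
            pairs.append((sa + k + 1, sb + k + 1))

    return AlignmentResult(
        score=score,
        aligned_pairs=tuple(pairs),
        similarity=positives / length if length else 0.0,
        identity=identities / length if length else 0.0,
        mode=mode,
    )


def reciprocal_expand(
    seed_id: str,
    proteome: Iterable[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    similarity_threshold: float = 0.30,
    max_rounds: int = 5,
) -> set[str]:
    """Iterative reciprocal homolog search above a similarity threshold.

    Round 1 screens the whole proteome against the seed; each later round
    re-queries with the highest-similarity hit not yet used as a query.
    Expansion stops when a round contributes no new hits, when no unused
    query remains, or after ``max_rounds``.  The seed is always a member
    of the result.
    """
    records = {r.id: r for r in proteome}
    if not records:
        raise ValueError("empty proteome")
    if seed_id not in records:
        raise KeyError(f"seed {seed_id!r} not in proteome")
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")

    # best similarity at which each hit was ever seen; seed pinned on top
    hits: dict[str, float] = {seed_id: 1.0}
    used: set[str] = set()

    for _ in range(max_rounds):
        unused = [pid for pid in hits if pid not in used]
        if not unused:
            break
        # deterministic choice: highest similarity, ties by smallest id
        query_id = sorted(unused, key=lambda pid: (-hits[pid], pid))[0]
        used.add(query_id)
        query = records[query_id]
        new_found = False
        for pid, rec in records.items():
            if pid == query_id:
                continue
            result = align(query.sequence, rec.sequence, scheme, mode="local")
            if result.similarity >= similarity_threshold:
                if pid not in hits:
                    new_found = True
                    hits[pid] = result.similarity
                else:
                    hits[pid] = max(hits[pid], result.similarity)
        if not new_found:
            break
    return set(hits)


def select_longest_isoform(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep one record per isoform group: the longest (ties: smallest id).

    Output order follows the first appearance of each group in the input.
    """
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        group = rec.isoform_group
        if group not in best:
            best[group] = rec
            order.append(group)
        else:
            cur = best[group]
            if len(rec.sequence) > len(cur.sequence) or (
                len(rec.sequence) == len(cur.sequence) and rec.id < cur.id
            ):
                best[group] = rec
    return [best[g] for g in order]
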