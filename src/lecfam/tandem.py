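"""Tandem-duplication cluster detection over chromosome-ordered gene loci.

Two family genes are tandem-adjacent when they lie on the same
chromosome and either at most ``max_intervening`` non-family genes sit
between them in the full annotation order or their base-pair gap is at
most ``max_gap_bp``.  Clusters are the maximal chains under this
relation.  A cluster with more than 20 members is a "super tandem
repeat region".  Scaffold-placed genes (indeterminate chromosomal
location) are excluded from clustering and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

SUPER_CLUSTER_MIN = 21  # "more than 20 genes clustered together"


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive bp
    end: int
    strand: str = "+"
    rank: Optional[int] = None  # ordinal among ALL annotated genes on the chromosome

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass(frozen=True)
class TandemCluster:
    members: tuple[str, ...]  # gene ids ordered by rank
    chromosome: str
    span_bp: int
    is_super: bool

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs at least two members")
        if self.is_super != (len(self.members) > 20):
            raise ValueError("is_super must hold exactly when the cluster exceeds 20 members")


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple[TandemCluster, ...]
    scaffold_genes: tuple[str, ...]  # family genes excluded for lacking a chromosome placement

    def clustered_ids(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out.update(c.members)
        return out


def is_scaffold(chromosome: str, scaffold_prefix: str = "scaffold") -> bool:
    return chromosome.lower().startswith(scaffold_prefix.lower())


def assign_ranks(all_loci: Sequence[GeneLocus]) -> list[GeneLocus]:
    """Rank every gene by start position within its chromosome (1-based)."""
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in all_loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    ranked: dict[str, GeneLocus] = {}
    for chrom, loci in by_chrom.items():
        loci.sort(key=lambda l: (l.start, l.end, l.gene_id))
        for i, locus in enumerate(loci):
            ranked[locus.gene_id] = replace(locus, rank=i + 1)
    return [ranked[l.gene_id] for l in all_loci]


def find_clusters(
    family_loci: Sequence[GeneLocus],
    all_loci: Sequence[GeneLocus],
    max_intervening: int = 5,
    max_gap_bp: int = 100_000,
    scaffold_prefix: str = "scaffold",
) -> ClusterResult:
    """Maximal tandem chains of family genes.

    Ranks are recomputed against the full annotation, so ``all_loci``
    must contain every annotated gene on the relevant chromosomes
    (including the family genes themselves).  Output is deterministic
    and independent of input order.
    """
    ranked_all = assign_ranks(list(all_loci))
    rank_of = {l.gene_id: l.rank for l in ranked_all}
    missing = [l.gene_id for l in family_loci if l.gene_id not in rank_of]
    if missing:
        raise ValueError(f"family loci absent from the annotation: {missing[:5]}")

    family_ids = {l.gene_id for l in family_loci}
    scaffold = sorted(l.gene_id for l in family_loci if is_scaffold(l.chromosome, scaffold_prefix))

    # per-chromosome family genes in rank order
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in family_loci:
        if is_scaffold(locus.chromosome, scaffold_prefix):
            continue
        by_chrom.setdefault(locus.chromosome, []).append(locus)

    # non-family ranks per chromosome for intervening counts
    nonfam_ranks: dict[str, list[int]] = {}
    for locus in ranked_all:
        if locus.gene_id not in family_ids:
            nonfam_ranks.setdefault(locus.chromosome, []).append(locus.rank)
    for ranks in nonfam_ranks.values():
        ranks.sort()

    import bisect

    def intervening(chrom: str, rank_a: int, rank_b: int) -> int:
        ranks = nonfam_ranks.get(chrom, [])
        lo, hi = sorted((rank_a, rank_b))
        return bisect.bisect_left(ranks, hi) - bisect.bisect_right(ranks, lo)

    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom):
        loci = sorted(by_chrom[chrom], key=lambda l: rank_of[l.gene_id])
        chain: list[GeneLocus] = [loci[0]]
        for prev, cur in zip(loci, loci[1:]):
            gap = max(0, cur.start - prev.end)
            adjacent = (
                intervening(chrom, rank_of[prev.gene_id], rank_of[cur.gene_id]) <= max_intervening
                or gap <= max_gap_bp
            )
            if adjacent:
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chain, chrom))
                chain = [cur]
        if len(chain) >= 2:
            clusters.append(_make_cluster(chain, chrom))
    return ClusterResult(tuple(clusters), tuple(scaffold))


def _make_cluster(chain: Sequence[GeneLocus], chrom: str) -> TandemCluster:
    span = max(l.end for l in chain) - min(l.start for l in chain) + 1
    return TandemCluster(
        members=tuple(l.gene_id for l in chain),
        chromosome=chrom,
        span_bp=span,
        is_super=len(chain) > 20,
    )


def clustered_fraction(
    clusters: Iterable[TandemCluster] | ClusterResult,
    family_loci: Sequence[GeneLocus],
    types: Optional[Mapping[str, str]] = None,
    type_filter: Optional[str] = None,
    scaffold_prefix: str = "scaffold",
) -> float:
    """Fraction of chromosome-placed family genes (optionally of one
    subfamily type) that fall inside a tandem cluster."""
    if isinstance(clusters, ClusterResult):
        cluster_list = clusters.clusters
    else:
        cluster_list = tuple(clusters)
    clustered: set[str] = set()
    for c in cluster_list:
        clustered.update(c.members)

    def keep(gene_id: str) -> bool:
        if type_filter is None:
            return True
        if types is None:
            raise ValueError("type_filter given without a gene -> type mapping")
        return types.get(gene_id) == type_filter

    placed = [
        l.gene_id
        for l in family_loci
        if not is_scaffold(l.chromosome, scaffold_prefix) and keep(l.gene_id)
    ]
    if not placed:
        raise ZeroDivisionError("no chromosome-placed family genes match the filter")
    return sum(1 for g in placed if g in clustered) / len(placed)
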