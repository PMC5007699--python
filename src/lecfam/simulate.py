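"""Synthetic LecRLK catalogues with fully specified ground truth.

The generator emulates the five inputs of a genome-wide family study —
proteome FASTA, domain-hit table, membrane-topology table, gene
coordinates (GFF3) and an FPKM expression matrix — with every label
(subfamily type, orientation class, tandem cluster, expression zone)
planted and recorded, so each downstream stage can be tested against
known truth without genome downloads.

Design highlights:

* Domain "sequences" are fixed synthetic signature blocks (one archetype
  per domain role, drawn once per seed), so the exact-DP homolog search
  finds family members through their shared blocks without any real HMM
  models.  Members of one type and class are identical before
  divergence; ``divergence_rate`` applies independent per-site
  substitutions (uniform over the other 19 residues), which has the
  closed-form expected p-distance equal to the rate.
* Background proteins are random sequences at least 250 residues long
  (short random subjects can reach spuriously high local-alignment
  percent similarity) and never carry both a lectin and a kinase
  annotation, guaranteeing the dual-domain filter's negative set.
* Tandem clusters are planted as consecutive family loci separated by
  small gaps; unclustered family genes are isolated behind six
  background genes and >100 kb on either side.
* Designed "expressed" FPKM values are drawn from a range whose lower
  bound is at least 1, "not expressed" values uniformly from [0, 0.5]
  and "undetectable" ones are exactly 0, keeping both designed states
  away from the detection cutoff even under replicate noise.

The default configuration encodes the reference Populus-scale study
design: 231 family members (180 G / 50 L / 1 C), the eight-class
orientation census, three super tandem regions (>20 genes) plus an
8-gene L-type cluster, 36 scaffold-placed genes, the published zone
census and the female/male-specific counts.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .domains import DEFAULT_VOCABULARY, DomainHit
from .homology import ProteinRecord
from .tandem import GeneLocus
from .topology import Segment, TopologyModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "LIVFAM"

ORIENT_CLASSES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "NO_TM")
ZONE_KEYS = ("I", "II", "III", "IV", "other")
CATEGORY_OF_ZONE = {"I": "low_or_no", "II": "all_four", "III": "root_only", "IV": "bud_only"}
EXTENDED_CATEGORIES = (
    "low_or_no",
    "all_four",
    "root_only",
    "bud_only",
    "stem_only",
    "leaf_only",
    "two_tissues",
    "three_tissues",
)

_TWO_TISSUE_CYCLE = (
    ("root", "stem"),
    ("root", "leaf"),
    ("leaf", "stem"),
    ("leaf", "bud"),
    ("stem", "bud"),
    ("root", "bud"),
)
_THREE_TISSUE_CYCLE = (
    ("root", "leaf", "stem"),
    ("root", "leaf", "bud"),
    ("root", "stem", "bud"),
    ("leaf", "stem", "bud"),
)


def _default_type_proportions() -> dict[str, float]:
    return {"G": 180 / 231, "L": 50 / 231, "C": 1 / 231}


def _default_class_distribution() -> dict[str, dict[str, float]]:
    # the published per-type orientation census
    g = {"I": 24, "II": 100, "III": 1, "IV": 7, "V": 3, "VI": 10, "VII": 1, "VIII": 1, "NO_TM": 33}
    l = {"I": 15, "II": 14, "III": 1, "IV": 4, "V": 3, "VI": 1, "NO_TM": 12}
    c = {"II": 1}
    return {
        "G": {k: v / 180 for k, v in g.items()},
        "L": {k: v / 50 for k, v in l.items()},
        "C": {k: v / 1 for k, v in c.items()},
    }


def _default_zone_distribution() -> dict[str, dict[str, float]]:
    # the published specificity census (root/stem/leaf/bud-only, all four,
    # two or three tissues, low-or-no)
    g = {
        "root_only": 16, "stem_only": 3, "leaf_only": 1, "bud_only": 41,
        "all_four": 13, "two_tissues": 29, "three_tissues": 18, "low_or_no": 59,
    }
    l = {
        "root_only": 6, "bud_only": 4, "all_four": 14,
        "two_tissues": 5, "three_tissues": 2, "low_or_no": 19,
    }
    c = {"all_four": 1}
    return {
        "G": {k: v / 180 for k, v in g.items()},
        "L": {k: v / 50 for k, v in l.items()},
        "C": {k: v / 1 for k, v in c.items()},
    }


@dataclass
class FamilySimConfig:
    """Study design of a synthetic catalogue (defaults: the reference
    Populus-scale design)."""

    n_family_members: int = 231
    type_proportions: Mapping[str, float] = field(default_factory=_default_type_proportions)
    class_distribution: Mapping = field(default_factory=_default_class_distribution)
    n_background_proteins: int = 100
    tandem_cluster_sizes: Sequence[int] = field(default_factory=lambda: [21, 22, 23, 8])
    cluster_types: Optional[Sequence[str]] = field(default_factory=lambda: ["G", "G", "G", "L"])
    super_cluster_size: Optional[int] = None
    divergence_rate: float = 0.05
    tissue_types: Mapping[str, int] = field(
        default_factory=lambda: {"root": 2, "leaf": 3, "stem": 2, "bud": 5}
    )
    reproductive_tissue_types: Mapping[str, int] = field(
        default_factory=lambda: {"female": 2, "male": 2}
    )
    zone_distribution: Mapping = field(default_factory=_default_zone_distribution)
    sex_specific: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"G": (21, 9), "L": (9, 1)}
    )
    fpkm_expressed_range: tuple[float, float] = (5.0, 100.0)
    fpkm_noise_sd: float = 0.1
    scaffold_genes: Mapping[str, int] = field(default_factory=lambda: {"G": 6, "L": 30})
    lectin_only_decoys: int = 40
    kinase_only_decoys: int = 20
    n_extra_isoforms: int = 20
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        if self.n_family_members < 0 or self.n_background_proteins < 0:
            raise ValueError("counts must be nonnegative")
        if abs(sum(self.type_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1")
        for dist in self._per_type(self.class_distribution).values():
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("class_distribution fractions must sum to 1")
        for dist in self._per_type(self.zone_distribution).values():
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("zone_distribution fractions must sum to 1")
        if not (0.0 <= self.divergence_rate < 0.95):
            raise ValueError("divergence_rate must lie in [0, 0.95)")
        lo, hi = self.fpkm_expressed_range
        if lo < 1.0 or hi < lo:
            raise ValueError("fpkm_expressed_range lower bound must be >= 1 (the detection cutoff)")
        if self.fpkm_noise_sd < 0:
            raise ValueError("fpkm_noise_sd must be nonnegative")
        if any(s < 2 for s in self.tandem_cluster_sizes):
            raise ValueError("tandem clusters need at least two members")
        if self.n_family_members == 0 and self.tandem_cluster_sizes:
            raise ValueError("cannot plant tandem clusters with zero family members")
        if self.cluster_types is not None and len(self.cluster_types) != len(self.tandem_cluster_sizes):
            raise ValueError("cluster_types must parallel tandem_cluster_sizes")
        if self.lectin_only_decoys + self.kinase_only_decoys > self.n_background_proteins:
            raise ValueError("decoy counts exceed n_background_proteins")

        # orientation classes VII/VIII occur only in G-type catalogues
        per_type = self._per_type(self.class_distribution)
        for t, dist in per_type.items():
            if t != "G" and (dist.get("VII", 0) > 0 or dist.get("VIII", 0) > 0):
                raise ValueError(
                    f"classes VII/VIII requested for {t}-type: triple-TM fusion architectures "
                    "are a G-type feature and cannot be planted for other types"
                )

    def _per_type(self, dist: Mapping) -> dict[str, dict[str, float]]:
        """Normalize a flat or per-type distribution to per-type form."""
        types = list(self.type_proportions)
        if dist and all(isinstance(v, Mapping) for v in dist.values()):
            return {t: dict(dist.get(t, {})) for t in types}
        return {t: dict(dist) for t in types}


# -- ground truth -------------------------------------------------------------


@dataclass(frozen=True)
class ProteinTruth:
    family: bool
    lec_type: Optional[str] = None
    orientation_class: Optional[str] = None
    architecture: tuple[str, ...] = ()
    truncated_lectin: bool = False
    truncated_kinase: bool = False


@dataclass(frozen=True)
class GeneTruth:
    cluster_id: Optional[str]
    is_super: bool
    zone: str
    specificity: str
    sex: str
    scaffold: bool
    chromosome: str


@dataclass
class GroundTruth:
    per_protein: dict[str, ProteinTruth]
    per_gene: dict[str, GeneTruth]
    seed_proteins: dict[str, str]  # type -> a representative member protein id

    def family_proteins(self) -> list[str]:
        return [p for p, t in self.per_protein.items() if t.family]

    def to_json(self) -> str:
        payload = {
            "per_protein": {k: asdict(v) for k, v in self.per_protein.items()},
            "per_gene": {k: asdict(v) for k, v in self.per_gene.items()},
            "seed_proteins": self.seed_proteins,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# -- deterministic allocation --------------------------------------------------


def largest_remainder(fractions: Mapping[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` items over categories, exactly, deterministically."""
    if total == 0:
        return {k: 0 for k in fractions}
    quotas = {k: f * total for k, f in fractions.items()}
    counts = {k: int(np.floor(q + 1e-9)) for k, q in quotas.items()}
    short = total - sum(counts.values())
    order = sorted(fractions, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


# -- sequence construction -----------------------------------------------------


def mutate_sequence(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution (uniform over the other 19 residues)."""
    if not sequence:
        raise ValueError("empty seed sequence")
    if rate == 0:
        return sequence
    chars = list(sequence)
    hits = np.where(rng.random(len(chars)) < rate)[0]
    for i in hits:
        current = chars[i]
        choices = [a for a in AMINO_ACIDS if a != current]
        chars[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def mutate_family(seed_sequence: str, n_copies: int, divergence_rate: float, seed: int) -> list[str]:
    """Diverged copies of a seed sequence; expected p-distance to the
    seed equals ``divergence_rate`` (closed form of the substitution
    scheme)."""
    if not seed_sequence:
        raise ValueError("empty seed sequence")
    if not (0.0 <= divergence_rate < 0.95):
        raise ValueError("divergence_rate must lie in [0, 0.95)")
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng(seed)
    return [mutate_sequence(seed_sequence, divergence_rate, rng) for _ in range(n_copies)]


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), n)])


#: domain role -> accession planted by the generator
_ACCESSION_OF_ROLE = {
    "lectin_bulb": "B_lectin",
    "lectin_legume": "Lectin_legB",
    "lectin_C": "Lectin_C",
    "kinase": "Pkinase",
    "s_locus": "S_locus_glycop",
    "duf3403": "DUF3403",
}

_LECTIN_OF_TYPE = {"G": "lectin_bulb", "L": "lectin_legume", "C": "lectin_C"}

# class -> topology layout; each entry is a side segment (label, contents)
# or the marker "TM".  Contents name the domain blocks placed in that
# segment ("lectin", "kinase", accessory roles) plus linker padding.
_CLASS_LAYOUT: dict[str, list] = {
    "NO_TM": [("outside", ["lectin", "accessories", "linker", "kinase", "tail_domains"])],
    "I": [("outside", ["lectin", "accessories"]), "TM", ("inside", ["kinase", "tail_domains"])],
    "II": [("inside", ["lectin", "accessories"]), "TM", ("outside", ["kinase", "tail_domains"])],
    "III": [("outside", ["lectin", "accessories", "linker", "kinase", "tail_domains"]), "TM", ("inside", ["linker"])],
    "IV": [("outside", ["lectin", "accessories"]), "TM", ("inside", ["linker"]), "TM", ("outside", ["kinase", "tail_domains"])],
    "V": [("inside", ["lectin", "accessories"]), "TM", ("outside", ["kinase", "tail_domains"]), "TM", ("inside", ["linker"])],
    "VI": [("outside", ["lectin", "accessories"]), "TM", ("inside", ["kinase", "tail_domains"]), "TM", ("outside", ["linker"])],
    "VII": [("outside", ["lectin"]), "TM", ("inside", ["kinase"]), "TM", ("outside", ["lectin"]), "TM", ("inside", ["kinase"])],
    "VIII": [("inside", ["lectin", "accessories"]), "TM", ("outside", ["kinase", "tail_domains"]), "TM", ("inside", ["linker"]), "TM", ("outside", ["linker"])],
}

_LINKER_LEN = 30
_TM_LEN = 21


class _ArchetypeFactory:
    """Builds one archetype (sequence + domain hits + topology) per
    (type, class), from signature blocks drawn once per seed."""

    def __init__(self, rng: np.random.Generator):
        self.blocks = {
            acc: _random_seq(rng, DEFAULT_VOCABULARY.model_length(acc))
            for acc in ("B_lectin", "Lectin_legB", "Lectin_C", "Pkinase", "S_locus_glycop", "DUF3403")
        }
        self.tm_block = _random_seq(rng, _TM_LEN, HYDROPHOBIC)
        self.linkers = [_random_seq(rng, _LINKER_LEN) for _ in range(8)]
        self._cache: dict[tuple[str, str], tuple[str, list, list]] = {}

    def archetype(self, lec_type: str, orient_class: str) -> tuple[str, list, list]:
        """Returns (sequence, [(role, accession, start, end)], [segments])."""
        key = (lec_type, orient_class)
        if key in self._cache:
            return self._cache[key]

        lectin_role = _LECTIN_OF_TYPE[lec_type]
        seq_parts: list[str] = []
        hits: list[tuple[str, str, int, int]] = []
        segments: list[Segment] = []
        pos = 1
        linker_i = 0

        def emit(block: str):
            nonlocal pos
            seq_parts.append(block)
            pos += len(block)

        def emit_domain(role: str):
            accession = _ACCESSION_OF_ROLE[role]
            block = self.blocks[accession]
            hits.append((role, accession, pos, pos + len(block) - 1))
            emit(block)

        def next_linker() -> str:
            nonlocal linker_i
            link = self.linkers[linker_i % len(self.linkers)]
            linker_i += 1
            return link

        for part in _CLASS_LAYOUT[orient_class]:
            if part == "TM":
                start = pos
                emit(self.tm_block)
                segments.append(Segment("membrane", start, pos - 1, 0.95))
                continue
            side, contents = part
            start = pos
            for item in contents:
                if item == "lectin":
                    emit_domain(lectin_role)
                elif item == "accessories":
                    if lec_type == "G":
                        emit_domain("s_locus")
                elif item == "kinase":
                    emit_domain("kinase")
                elif item == "tail_domains":
                    if lec_type == "G":
                        emit_domain("duf3403")
                elif item == "linker":
                    emit(next_linker())
                else:  # pragma: no cover - layout typo guard
                    raise ValueError(f"unknown layout item {item!r}")
            if pos == start:
                emit(next_linker())
            segments.append(Segment(side, start, pos - 1, 0.9))

        sequence = "".join(seq_parts)
        result = (sequence, hits, segments)
        self._cache[key] = result
        return result


# -- catalogue container -------------------------------------------------------


@dataclass
class SyntheticCatalogue:
    config: FamilySimConfig
    proteome: list[ProteinRecord]
    domain_hits: list[DomainHit]
    topology_models: dict[str, TopologyModel]
    family_loci: list[GeneLocus]
    all_loci: list[GeneLocus]
    fpkm: pd.DataFrame
    grouping: dict[str, str]
    ground_truth: GroundTruth

    # ---- standard-format payloads ----

    def fasta_text(self, width: int = 60) -> str:
        out = io.StringIO()
        for rec in self.proteome:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")
        return out.getvalue()

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for locus in self.all_loci:
            lines.append(
                "\t".join(
                    [
                        locus.chromosome,
                        "lecfam_sim",
                        "gene",
                        str(locus.start),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={locus.gene_id}",
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    def domain_table_text(self) -> str:
        rows = ["\t".join(["protein_id", "accession", "role", "start", "end", "score"])]
        for h in self.domain_hits:
            rows.append(f"{h.protein_id}\t{h.accession}\t{h.role}\t{h.start}\t{h.end}\t{h.score:g}")
        return "\n".join(rows) + "\n"

    def topology_table_text(self) -> str:
        rows = ["\t".join(["protein_id", "segment_label", "start", "end", "score", "sp_score"])]
        for pid in self.topology_models:
            model = self.topology_models[pid]
            sp = "" if model.sp_score is None else f"{model.sp_score:g}"
            for seg in model.segments:
                rows.append(f"{pid}\t{seg.label}\t{seg.start}\t{seg.end}\t{seg.score:g}\t{sp}")
        return "\n".join(rows) + "\n"

    def fpkm_text(self) -> str:
        return self.fpkm.to_csv(sep="\t", index_label="gene_id", float_format="%.4f")

    def grouping_yaml(self) -> str:
        return yaml.safe_dump({"samples": dict(self.grouping)}, sort_keys=True)

    def config_yaml(self) -> str:
        def plain(obj):
            if isinstance(obj, Mapping):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return yaml.safe_dump(plain(asdict(self.config)), sort_keys=True, default_flow_style=False)

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "proteome.fasta").write_text(self.fasta_text())
        (d / "genes.gff3").write_text(self.gff3_text())
        (d / "domains.tsv").write_text(self.domain_table_text())
        (d / "topology.tsv").write_text(self.topology_table_text())
        (d / "fpkm.tsv").write_text(self.fpkm_text())
        (d / "grouping.yaml").write_text(self.grouping_yaml())
        (d / "ground_truth.json").write_text(self.ground_truth.to_json())
        (d / "config.yaml").write_text(self.config_yaml())


# -- generator -----------------------------------------------------------------


def generate_catalogue(config: FamilySimConfig) -> SyntheticCatalogue:
    """Deterministically generate a full synthetic catalogue.

    Identical config + seed give byte-identical payloads.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    factory = _ArchetypeFactory(rng)

    n = config.n_family_members
    type_counts = largest_remainder(dict(config.type_proportions), n)
    types_in_order: list[str] = []
    for t in config.type_proportions:
        types_in_order.extend([t] * type_counts[t])

    gene_ids = [f"SynPt.{i + 1:04d}" for i in range(n)]
    gene_type = dict(zip(gene_ids, types_in_order))
    members_of_type: dict[str, list[str]] = {}
    for g in gene_ids:
        members_of_type.setdefault(gene_type[g], []).append(g)

    # per-type class and zone assignment, in member order
    class_dist = config._per_type(config.class_distribution)
    zone_dist = config._per_type(config.zone_distribution)
    gene_class: dict[str, str] = {}
    gene_category: dict[str, str] = {}
    for t, members in members_of_type.items():
        counts = largest_remainder(class_dist[t], len(members))
        labels: list[str] = []
        for cls in ORIENT_CLASSES:
            labels.extend([cls] * counts.get(cls, 0))
        for g, cls in zip(members, labels):
            gene_class[g] = cls

        zcounts_raw = largest_remainder(zone_dist[t], len(members))
        zcounts: dict[str, int] = {}
        for key, count in zcounts_raw.items():
            if key in CATEGORY_OF_ZONE:
                zcounts[CATEGORY_OF_ZONE[key]] = zcounts.get(CATEGORY_OF_ZONE[key], 0) + count
            elif key == "other":
                # split a lumped "other" round-robin over the non-zone patterns
                split = ("two_tissues", "three_tissues", "stem_only", "leaf_only")
                for i in range(count):
                    cat = split[i % len(split)]
                    zcounts[cat] = zcounts.get(cat, 0) + 1
            elif key in EXTENDED_CATEGORIES:
                zcounts[key] = zcounts.get(key, 0) + count
            else:
                raise ValueError(f"unknown zone/category key {key!r}")
        zlabels: list[str] = []
        for cat in EXTENDED_CATEGORIES:
            zlabels.extend([cat] * zcounts.get(cat, 0))
        for g, cat in zip(members, zlabels):
            gene_category[g] = cat

    # sex-specific designation, per type, in member order
    gene_sex: dict[str, str] = {}
    for t, members in members_of_type.items():
        n_female, n_male = config.sex_specific.get(t, (0, 0))
        if n_female + n_male > len(members):
            raise ValueError(f"sex-specific counts for type {t} exceed the member count")
        for g in members[:n_female]:
            gene_sex[g] = "female_only"
        for g in members[n_female : n_female + n_male]:
            gene_sex[g] = "male_only"
    for g in gene_ids:
        if g not in gene_sex:
            gene_sex[g] = "both" if gene_category[g] == "all_four" else "neither"

    # --- tandem clusters and chromosome placement ---
    cluster_sizes = list(config.tandem_cluster_sizes)
    cluster_types = list(config.cluster_types) if config.cluster_types else ["G"] * len(cluster_sizes)
    if config.super_cluster_size is not None:
        cluster_sizes.append(config.super_cluster_size)
        cluster_types.append("G")

    unassigned: dict[str, list[str]] = {t: list(m) for t, m in members_of_type.items()}
    cluster_members: list[list[str]] = []
    gene_cluster: dict[str, Optional[str]] = {g: None for g in gene_ids}
    for idx, (size, t) in enumerate(zip(cluster_sizes, cluster_types)):
        pool = unassigned.get(t, [])
        if len(pool) < size:
            raise ValueError(f"not enough {t}-type members for a cluster of {size}")
        chosen, unassigned[t] = pool[:size], pool[size:]
        cluster_members.append(chosen)
        for g in chosen:
            gene_cluster[g] = f"cluster_{idx + 1:02d}"

    gene_scaffold: dict[str, bool] = {g: False for g in gene_ids}
    for t, count in config.scaffold_genes.items():
        pool = unassigned.get(t, [])
        if len(pool) < count:
            raise ValueError(f"not enough unclustered {t}-type members for {count} scaffold genes")
        chosen, unassigned[t] = pool[:count], pool[count:]
        for g in chosen:
            gene_scaffold[g] = True

    isolated = [g for t in members_of_type for g in unassigned.get(t, [])]

    # chromosome layout: clusters on their own chromosomes, isolated genes
    # spread round-robin, each separated by 6 filler genes and >100 kb
    chromosomes = [f"Chr{i:02d}" for i in range(1, 20)]
    cluster_chroms = ["Chr01", "Chr10", "Chr11", "Chr09", "Chr02", "Chr03", "Chr04", "Chr05", "Chr06", "Chr07"]
    placement: dict[str, list] = {c: [] for c in chromosomes}  # gene blocks per chromosome
    for idx, members in enumerate(cluster_members):
        chrom = cluster_chroms[idx % len(cluster_chroms)]
        placement[chrom].append(("cluster", members))
    for i, g in enumerate(isolated):
        chrom = chromosomes[i % len(chromosomes)]
        placement[chrom].append(("isolated", [g]))

    background_ids = [f"Bg{i + 1:04d}" for i in range(config.n_background_proteins)]
    filler_queue = list(background_ids)
    filler_extra = 0

    def next_filler() -> str:
        nonlocal filler_extra
        if filler_queue:
            return filler_queue.pop(0)
        filler_extra += 1
        return f"Fill{filler_extra:05d}"

    GENE_LEN = 3000
    ISOLATION_SPACING = 18_000  # end-to-start gap around fillers
    CLUSTER_GAP = 2_000

    family_loci: list[GeneLocus] = []
    all_loci: list[GeneLocus] = []

    def place(chrom: str, gene_id: str, pos: int, is_family: bool) -> int:
        locus = GeneLocus(gene_id, chrom, pos, pos + GENE_LEN - 1)
        all_loci.append(locus)
        if is_family:
            family_loci.append(locus)
        return locus.end

    for chrom in chromosomes:
        pos = 50_000
        blocks = placement[chrom]
        if not blocks:
            continue
        for kind, members in blocks:
            for _ in range(6):
                end = place(chrom, next_filler(), pos, False)
                pos = end + ISOLATION_SPACING
            if kind == "cluster":
                for g in members:
                    end = place(chrom, g, pos, True)
                    pos = end + CLUSTER_GAP
                pos += ISOLATION_SPACING - CLUSTER_GAP
            else:
                end = place(chrom, members[0], pos, True)
                pos = end + ISOLATION_SPACING
        for _ in range(6):
            end = place(chrom, next_filler(), pos, False)
            pos = end + ISOLATION_SPACING

    # leftover background genes placed on their own chromosome region
    tail_pos = 50_000
    while filler_queue:
        end = place("Chr19", filler_queue.pop(0), tail_pos, False)
        tail_pos = end + ISOLATION_SPACING

    scaffold_counter = 0
    for g in gene_ids:
        if gene_scaffold[g]:
            scaffold_counter += 1
            chrom = f"scaffold_{scaffold_counter}"
            locus = GeneLocus(g, chrom, 10_000, 10_000 + GENE_LEN - 1)
            family_loci.append(locus)
            all_loci.append(locus)

    # --- sequences, domain hits, topology ---
    proteome: list[ProteinRecord] = []
    domain_hits: list[DomainHit] = []
    topology_models: dict[str, TopologyModel] = {}
    per_protein: dict[str, ProteinTruth] = {}

    for g in gene_ids:
        t = gene_type[g]
        cls = gene_class[g]
        arch_seq, arch_hits, arch_segments = factory.archetype(t, cls)
        seq = mutate_sequence(arch_seq, config.divergence_rate, rng)
        pid = f"{g}.1"
        proteome.append(ProteinRecord(pid, seq, g))
        for role, accession, start, end in arch_hits:
            domain_hits.append(DomainHit(pid, accession, role, start, end, 50.0))
        topology_models[pid] = TopologyModel(pid, tuple(arch_segments), sp_score=0.05)
        per_protein[pid] = ProteinTruth(
            family=True,
            lec_type=t,
            orientation_class=cls,
            architecture=tuple(role for role, _, _, _ in arch_hits),
        )

    # extra (shorter) isoforms for the first genes: longest-isoform selection fodder
    for g in gene_ids[: config.n_extra_isoforms]:
        full = next(r for r in proteome if r.id == f"{g}.1")
        short = full.sequence[: max(1, int(len(full.sequence) * 0.6))]
        pid = f"{g}.2"
        proteome.append(ProteinRecord(pid, short, g))
        per_protein[pid] = ProteinTruth(family=True, lec_type=gene_type[g])

    lectin_cycle = ["B_lectin", "Lectin_legB", "Lectin_C"]
    for i, bid in enumerate(background_ids):
        length = int(rng.integers(250, 851))
        seq = _random_seq(rng, length)
        pid = f"{bid}.1"
        proteome.append(ProteinRecord(pid, seq, bid))
        per_protein[pid] = ProteinTruth(family=False)
        if i < config.lectin_only_decoys:
            accession = lectin_cycle[i % len(lectin_cycle)]
            model_len = DEFAULT_VOCABULARY.model_length(accession)
            role = DEFAULT_VOCABULARY.role_of(accession)
            domain_hits.append(DomainHit(pid, accession, role, 10, 10 + model_len - 1, 30.0))
        elif i < config.lectin_only_decoys + config.kinase_only_decoys:
            model_len = DEFAULT_VOCABULARY.model_length("Pkinase")
            domain_hits.append(DomainHit(pid, "Pkinase", "kinase", 5, 5 + model_len - 1, 30.0))

    # --- FPKM matrix ---
    tissues = dict(config.tissue_types)
    tissues.update(config.reproductive_tissue_types)
    samples: list[str] = []
    grouping: dict[str, str] = {}
    for tissue, count in tissues.items():
        if count < 1:
            raise ValueError(f"tissue type {tissue!r} has no samples")
        for i in range(count):
            name = f"{tissue}_{i + 1}"
            samples.append(name)
            grouping[name] = tissue

    expressed_tissues: dict[str, tuple[str, ...]] = {}
    cycle_two = cycle_three = 0
    for g in gene_ids:
        cat = gene_category[g]
        if cat == "low_or_no":
            expressed_tissues[g] = ()
        elif cat == "all_four":
            expressed_tissues[g] = tuple(config.tissue_types)
        elif cat.endswith("_only"):
            expressed_tissues[g] = (cat[: -len("_only")],)
        elif cat == "two_tissues":
            expressed_tissues[g] = _TWO_TISSUE_CYCLE[cycle_two % len(_TWO_TISSUE_CYCLE)]
            cycle_two += 1
        else:
            expressed_tissues[g] = _THREE_TISSUE_CYCLE[cycle_three % len(_THREE_TISSUE_CYCLE)]
            cycle_three += 1

    lo, hi = config.fpkm_expressed_range
    values = np.zeros((len(gene_ids), len(samples)))
    undetectable_toggle = 0
    for gi, g in enumerate(gene_ids):
        cat = gene_category[g]
        undetectable = False
        if cat == "low_or_no":
            undetectable = undetectable_toggle % 2 == 0
            undetectable_toggle += 1
        sex = gene_sex[g]
        for si, s in enumerate(samples):
            tissue = grouping[s]
            if tissue in config.reproductive_tissue_types:
                on = (sex == "both") or (sex == "female_only" and tissue == "female") or (
                    sex == "male_only" and tissue == "male"
                )
            else:
                on = tissue in expressed_tissues[g]
            if on:
                values[gi, si] = rng.uniform(lo, hi)
            elif undetectable:
                values[gi, si] = 0.0
            else:
                values[gi, si] = rng.uniform(0.0, 0.5)
    if config.fpkm_noise_sd > 0:
        noise = rng.normal(0.0, config.fpkm_noise_sd, size=values.shape)
        mask = values > 0  # keep designed "undetectable" cells at exactly 0
        values = np.where(mask, np.maximum(0.0, values + noise), values)
    fpkm = pd.DataFrame(np.round(values, 4), index=gene_ids, columns=samples)
    fpkm.index.name = "gene_id"

    # --- ground truth ---
    per_gene: dict[str, GeneTruth] = {}
    cluster_size_of = {f"cluster_{i + 1:02d}": len(m) for i, m in enumerate(cluster_members)}
    chrom_of_gene = {l.gene_id: l.chromosome for l in family_loci}
    for g in gene_ids:
        cid = gene_cluster[g]
        cat = gene_category[g]
        zone = {v: k for k, v in CATEGORY_OF_ZONE.items()}.get(cat, "other")
        per_gene[g] = GeneTruth(
            cluster_id=cid,
            is_super=bool(cid and cluster_size_of[cid] > 20),
            zone=zone,
            specificity=cat,
            sex=gene_sex[g],
            scaffold=gene_scaffold[g],
            chromosome=chrom_of_gene[g],
        )

    seed_proteins = {t: f"{members_of_type[t][0]}.1" for t in members_of_type if members_of_type[t]}

    truth = GroundTruth(per_protein=per_protein, per_gene=per_gene, seed_proteins=seed_proteins)
    return SyntheticCatalogue(
        config=config,
        proteome=proteome,
        domain_hits=domain_hits,
        topology_models=topology_models,
        family_loci=family_loci,
        all_loci=all_loci,
        fpkm=fpkm,
        grouping=grouping,
        ground_truth=truth,
    )
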