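"""End-to-end orchestration and the catalogue summary tables.

Stages run in the order homolog search -> domain filter -> topology
classes -> tandem clusters -> phylogeny -> expression zones, and the
result is condensed into three count tables mirroring the shape of a
published family census: per-type totals, orientation class x type, and
expression specificity x type.  Cross-table marginal consistency is
asserted on every run, and a provenance block (config hash, seed,
thresholds) suffices to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import expression as expr
from .domains import DEFAULT_VOCABULARY, FamilyMember, LECTIN_ROLES, filter_lecrlk, group_hits
from .homology import ScoringScheme, reciprocal_expand, select_longest_isoform
from .phylo import bootstrap_support, progressive_msa
from .simulate import FamilySimConfig, SyntheticCatalogue, generate_catalogue
from .tandem import ClusterResult, clustered_fraction, find_clusters
from .topology import ORIENTATION_CLASSES, TopologyModel, classify_protein, predict_tm_fallback

logger = logging.getLogger(__name__)

CLASS_ROWS = list(ORIENTATION_CLASSES)  # I..VIII, NO_TM, UNCLASSIFIED


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Every numeric threshold of the pipeline, plus inputs and the seed."""

    similarity_threshold: float = 0.30
    max_rounds: int = 5
    tm_threshold: float = 0.8
    sp_threshold: float = 0.7
    fpkm_cutoff: float = 1.0
    all_samples: bool = False
    truncation_margin: int = 10
    max_intervening: int = 5
    max_gap_bp: int = 100_000
    super_cluster_min: int = 21
    bootstrap_replicates: int = 1000
    gap_open_cost: float = 10.0
    gap_extend_cost: float = 0.2
    substitution_matrix: str = "BLOSUM62"
    phylo_max_taxa: int = 40
    run_phylo: bool = True
    seed: int = 0
    simulate: Optional[FamilySimConfig] = None
    # file inputs (used when simulate is None)
    proteome_path: Optional[str] = None
    domain_table_path: Optional[str] = None
    topology_table_path: Optional[str] = None
    gff3_path: Optional[str] = None
    fpkm_path: Optional[str] = None
    grouping_path: Optional[str] = None
    seed_proteins: Optional[Mapping[str, str]] = None

    def __post_init__(self):
        if not (0.0 <= self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold must lie in [0, 1]")
        for name in ("tm_threshold", "sp_threshold"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fpkm_cutoff < 0 or self.truncation_margin < 0 or self.bootstrap_replicates < 1:
            raise ValueError("threshold out of documented range")

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(self.substitution_matrix, self.gap_open_cost, self.gap_extend_cost)

    def provenance(self) -> dict:
        raw = {k: v for k, v in asdict(self).items() if not k.endswith("_path")}
        if raw.get("simulate") is not None:
            raw["simulate"] = _plain(raw["simulate"])
        digest = hashlib.sha256(json.dumps(_plain(raw), sort_keys=True, default=str).encode()).hexdigest()
        return {"config": _plain(raw), "config_sha256": digest, "seed": self.seed}


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class CatalogueSummary:
    """Per-type totals, class x type counts and specificity x type counts."""

    type_totals: pd.Series
    class_table: pd.DataFrame
    specificity_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.assert_consistent()

    def assert_consistent(self) -> None:
        types = [t for t in self.type_totals.index if t != "Total"]
        assert self.type_totals["Total"] == sum(self.type_totals[t] for t in types), "type totals inconsistent"
        for t in types:
            assert self.class_table[t].sum() == self.type_totals[t], f"class column {t} != type total"
        assert (self.class_table["Total"] == self.class_table[types].sum(axis=1)).all(), "class row totals"
        if not self.specificity_table.empty:
            for t in types:
                assert self.specificity_table.loc[t, "Total"] == self.type_totals[t], (
                    f"specificity row {t} != type total"
                )
            cols = [c for c in self.specificity_table.columns if c != "Total"]
            assert (
                self.specificity_table.loc["Total", cols].sum() == self.type_totals["Total"]
            ), "specificity grand total"

    def to_json(self) -> str:
        return json.dumps(
            {
                "type_totals": self.type_totals.to_dict(),
                "class_table": self.class_table.to_dict(),
                "specificity_table": self.specificity_table.to_dict() if not self.specificity_table.empty else {},
                "provenance": self.provenance,
            },
            indent=1,
            sort_keys=True,
            default=int,
        )

    def to_text(self) -> str:
        parts = [
            "Per-type totals",
            self.type_totals.to_string(),
            "",
            "Orientation classes x type",
            self.class_table.to_string(),
        ]
        if not self.specificity_table.empty:
            parts += ["", "Expression specificity x type", self.specificity_table.to_string()]
        return "\n".join(parts) + "\n"


def summarize_counts(
    member_types: Mapping[str, str],
    classes: Mapping[str, str],
    categories: Mapping[str, str],
    gene_of_protein: Optional[Mapping[str, str]] = None,
    provenance: Optional[dict] = None,
    types: Sequence[str] = ("G", "L", "C"),
) -> CatalogueSummary:
    """Aggregate per-protein type/class labels and per-gene specificity
    categories into the three census tables, with marginals enforced.

    ``member_types`` maps protein id -> G/L/C; ``classes`` maps protein
    id -> orientation class; ``categories`` maps gene id -> specificity
    category (may be empty when no expression data exist).
    """
    gene_of = gene_of_protein or {}
    type_totals = pd.Series(0, index=list(types) + ["Total"], dtype=int)
    class_table = pd.DataFrame(0, index=CLASS_ROWS, columns=list(types) + ["Total"], dtype=int)
    for pid, t in member_types.items():
        if t not in types:
            raise StageError("summary", f"unknown type {t!r} for {pid}")
        type_totals[t] += 1
        type_totals["Total"] += 1
        cls = classes.get(pid)
        if cls is None:
            raise StageError("summary", f"protein {pid} lacks an orientation class")
        class_table.loc[cls, t] += 1
        class_table.loc[cls, "Total"] += 1

    if categories:
        gene_type = {}
        for pid, t in member_types.items():
            gene_type[gene_of.get(pid, pid)] = t
        missing = [g for g in gene_type if g not in categories]
        if missing:
            raise StageError("summary", f"genes without expression category: {missing[:5]}")
        spec = pd.DataFrame(
            0, index=list(types) + ["Total"], columns=list(expr.SPECIFICITY_COLUMNS) + ["Total"], dtype=int
        )
        for g, t in gene_type.items():
            cat = categories[g]
            spec.loc[t, cat] += 1
            spec.loc[t, "Total"] += 1
            spec.loc["Total", cat] += 1
            spec.loc["Total", "Total"] += 1
    else:
        spec = pd.DataFrame()

    return CatalogueSummary(type_totals, class_table, spec, provenance or {})


def summary_from_counts(
    class_counts: Mapping[str, Mapping[str, int]],
    specificity_counts: Optional[Mapping[str, Mapping[str, int]]] = None,
) -> CatalogueSummary:
    """Build a summary from printed component counts (e.g. a published
    class x type table), expanding them into pseudo-labels.

    ``class_counts``: type -> {class: count}; ``specificity_counts``:
    type -> {category: count}.  Useful for consistency checks of
    published tables, whose derived totals the summary recomputes.
    """
    member_types: dict[str, str] = {}
    classes: dict[str, str] = {}
    categories: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    i = 0
    per_type_totals: dict[str, int] = {}
    for t, by_class in class_counts.items():
        for cls, count in by_class.items():
            for _ in range(count):
                pid = f"{t}_{i:04d}"
                member_types[pid] = t
                classes[pid] = cls
                gene_of[pid] = pid
                i += 1
        per_type_totals[t] = sum(by_class.values())
    if specificity_counts is not None:
        for t, by_cat in specificity_counts.items():
            if sum(by_cat.values()) != per_type_totals.get(t, 0):
                raise StageError(
                    "summary", f"specificity counts for type {t} disagree with the class census total"
                )
            pids = [p for p, tt in member_types.items() if tt == t]
            k = 0
            for cat, count in by_cat.items():
                for _ in range(count):
                    categories[pids[k]] = cat
                    k += 1
    return summarize_counts(member_types, classes, categories, gene_of, types=list(class_counts))


@dataclass
class PipelineResult:
    summary: CatalogueSummary
    members: list[FamilyMember]
    classes: dict[str, str]  # protein id -> orientation class
    zones: dict[str, str]  # gene id -> zone
    categories: dict[str, str]  # gene id -> specificity category
    sex_labels: dict[str, str]
    clusters: Optional[ClusterResult]
    clustered_fraction_by_type: dict[str, float]
    tree: Optional[object]
    stage_log: list[dict]
    catalogue: Optional[SyntheticCatalogue] = None

    @property
    def member_types(self) -> dict[str, str]:
        return {m.protein_id: m.lec_type for m in self.members}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage on real files or a simulated catalogue.

    Deterministic under fixed config + seed; each stage logs one
    structured line with its input/output record counts.
    """
    log: list[dict] = []

    def record(stage: str, **counts):
        entry = {"stage": stage, **counts}
        log.append(entry)
        logger.info("stage=%s %s", stage, counts)

    # --- inputs ---
    catalogue: Optional[SyntheticCatalogue] = None
    if config.simulate is not None:
        catalogue = generate_catalogue(config.simulate)
        proteome = catalogue.proteome
        domain_hits = catalogue.domain_hits
        topo_models: dict[str, TopologyModel] = catalogue.topology_models
        all_loci = catalogue.all_loci
        fpkm = catalogue.fpkm
        grouping = catalogue.grouping
        seeds = dict(config.seed_proteins or catalogue.ground_truth.seed_proteins)
    else:
        from . import io as lio

        if config.proteome_path is None or config.domain_table_path is None:
            raise StageError("inputs", "need a proteome and a domain table (or simulate config)")
        proteome = lio.read_proteome(config.proteome_path)
        domain_hits = lio.read_domain_table(config.domain_table_path)
        topo_models = (
            lio.read_topology_table(config.topology_table_path) if config.topology_table_path else {}
        )
        all_loci = lio.read_gff3_genes(config.gff3_path) if config.gff3_path else []
        fpkm = lio.read_fpkm_matrix(config.fpkm_path) if config.fpkm_path else pd.DataFrame()
        grouping = lio.read_grouping(config.grouping_path) if config.grouping_path else {}
        seeds = dict(config.seed_proteins or {})
    record("inputs", proteins=len(proteome), domain_hits=len(domain_hits), loci=len(all_loci))

    # --- longest isoform ---
    longest = select_longest_isoform(proteome)
    by_id = {r.id: r for r in longest}
    record("longest_isoform", kept=len(longest), dropped=len(proteome) - len(longest))

    # --- homolog search ---
    scheme = config.scheme()
    if seeds:
        candidates: set[str] = set()
        for t in sorted(seeds):
            seed_id = seeds[t]
            if seed_id not in by_id:
                raise StageError("homology", f"seed protein {seed_id!r} absent after isoform selection")
            found = reciprocal_expand(
                seed_id, longest, scheme, config.similarity_threshold, config.max_rounds
            )
            candidates |= found
    else:
        candidates = set(by_id)
    record("homology", seeds=len(seeds), candidates=len(candidates))

    # --- domain filter ---
    hits_by_protein = group_hits(h for h in domain_hits if h.protein_id in candidates)
    members, rejected = filter_lecrlk(hits_by_protein, DEFAULT_VOCABULARY, config.truncation_margin)
    members.sort(key=lambda m: m.protein_id)
    record("domains", candidates=len(hits_by_protein), members=len(members), rejected=len(rejected))

    # --- topology classes ---
    classes: dict[str, str] = {}
    for m in members:
        hits = sorted(hits_by_protein[m.protein_id], key=lambda h: (h.start, h.end))
        lectin = next(h for h in hits if h.role in LECTIN_ROLES)
        kinase = next(h for h in hits if h.role == "kinase")
        model = topo_models.get(m.protein_id)
        if model is None:
            model = predict_tm_fallback(by_id[m.protein_id].sequence, m.protein_id)
        cls, _ = classify_protein(model, lectin, kinase, config.tm_threshold, config.sp_threshold)
        classes[m.protein_id] = cls
    record("topology", classified=len(classes))

    # --- tandem clusters ---
    gene_of = {m.protein_id: by_id[m.protein_id].isoform_group for m in members}
    member_genes = {gene_of[m.protein_id] for m in members}
    clusters: Optional[ClusterResult] = None
    clustered_by_type: dict[str, float] = {}
    if all_loci:
        family_loci = [l for l in all_loci if l.gene_id in member_genes]
        clusters = find_clusters(family_loci, all_loci, config.max_intervening, config.max_gap_bp)
        gene_types = {gene_of[m.protein_id]: m.lec_type for m in members}
        for t in sorted({m.lec_type for m in members}):
            try:
                clustered_by_type[t] = clustered_fraction(clusters, family_loci, gene_types, t)
            except ZeroDivisionError:
                clustered_by_type[t] = float("nan")
        record(
            "tandem",
            family_loci=len(family_loci),
            clusters=len(clusters.clusters),
            super_clusters=sum(c.is_super for c in clusters.clusters),
            scaffold_genes=len(clusters.scaffold_genes),
        )

    # --- phylogeny ---
    tree = None
    if config.run_phylo and len(members) >= 4:
        ids = sorted(m.protein_id for m in members)
        if len(ids) > config.phylo_max_taxa:
            picks = np.linspace(0, len(ids) - 1, config.phylo_max_taxa).round().astype(int)
            ids = [ids[i] for i in sorted(set(picks.tolist()))]
        msa = progressive_msa({i: by_id[i].sequence for i in ids}, scheme)
        tree = bootstrap_support(msa, config.bootstrap_replicates, config.seed)
        record("phylo", taxa=len(ids), columns=msa.n_columns, replicates=config.bootstrap_replicates)

    # --- expression zones ---
    zones: dict[str, str] = {}
    categories: dict[str, str] = {}
    sex_labels: dict[str, str] = {}
    if not fpkm.empty and grouping:
        missing = sorted(g for g in member_genes if g not in fpkm.index)
        if missing:
            raise StageError("expression", f"member genes absent from the FPKM matrix: {missing[:5]}")
        sub = fpkm.loc[sorted(member_genes)]
        for g in sub.index:
            categories[g] = expr.specificity_category(sub, g, grouping, config.fpkm_cutoff, config.all_samples)
            zones[g] = expr.ZONE_OF_CATEGORY.get(categories[g], "other")
        tissues_present = set(grouping.values())
        if {"female", "male"} <= tissues_present:
            sex_labels = expr.sex_specific_expression(sub, grouping, config.fpkm_cutoff)
        record("expression", genes=len(categories))

    member_types = {m.protein_id: m.lec_type for m in members}
    summary = summarize_counts(
        member_types, classes, categories, gene_of, provenance=config.provenance()
    )
    return PipelineResult(
        summary=summary,
        members=members,
        classes=classes,
        zones=zones,
        categories=categories,
        sex_labels=sex_labels,
        clusters=clusters,
        clustered_fraction_by_type=clustered_by_type,
        tree=tree,
        stage_log=log,
        catalogue=catalogue,
    )
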