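"""Readers and writers for the pipeline's standard file formats.

FASTA goes through Biopython, tables through pandas, gene features
through gffutils, trees through dendropy.  All coordinates are 1-based
inclusive on disk, matching GFF3 and the domain/topology table
conventions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .domains import DomainHit, DomainVocabulary
from .homology import ProteinRecord, isoform_group_from_id
from .tandem import GeneLocus, TandemCluster
from .topology import Segment, TopologyModel


def read_proteome(path) -> list[ProteinRecord]:
    """Multi-record (wrapped) FASTA; isoform groups from Phytozome-style
    ``locus.N`` ids."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(ProteinRecord(rec.id, seq, isoform_group_from_id(rec.id)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_domain_table(path) -> list[DomainHit]:
    """TSV with header: protein_id, accession, role, start, end, score."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "accession", "role", "start", "end", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    return [
        DomainHit(r.protein_id, r.accession, r.role, int(r.start), int(r.end), float(r.score))
        for r in df.itertuples()
    ]


def read_topology_table(path) -> dict[str, TopologyModel]:
    """Segment rows (protein_id, segment_label, start, end, score, sp_score)."""
    df = pd.read_csv(path, sep="\t")
    models: dict[str, TopologyModel] = {}
    for pid, group in df.groupby("protein_id", sort=False):
        group = group.sort_values("start")
        segments = tuple(
            Segment(r.segment_label, int(r.start), int(r.end), float(r.score)) for r in group.itertuples()
        )
        sp_raw = group["sp_score"].iloc[0] if "sp_score" in group else None
        sp_score = None if sp_raw is None or pd.isna(sp_raw) else float(sp_raw)
        models[str(pid)] = TopologyModel(str(pid), segments, sp_score=sp_score)
    return models


def read_gff3_genes(path, id_attribute: str = "ID") -> list[GeneLocus]:
    """Gene features from GFF3 (via gffutils; other feature types ignored)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    loci = []
    for feature in db.features_of_type("gene"):
        ids = feature.attributes.get(id_attribute, [feature.id])
        loci.append(GeneLocus(ids[0], feature.seqid, feature.start, feature.end, feature.strand or "+"))
    return loci


def read_fpkm_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_grouping(path) -> dict[str, str]:
    """Sample -> tissue type mapping from YAML ({samples: {...}}) or
    two-column TSV."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        payload = yaml.safe_load(path.read_text())
        mapping = payload.get("samples", payload) if isinstance(payload, dict) else None
        if not isinstance(mapping, dict):
            raise ValueError("grouping YAML must map sample ids to tissue types")
        return {str(k): str(v) for k, v in mapping.items()}
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("grouping TSV needs sample and tissue columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_vocabulary(path) -> DomainVocabulary:
    """YAML: accession -> {role, model_length}."""
    payload = yaml.safe_load(Path(path).read_text())
    mapping = {
        acc: (spec["role"], int(spec["model_length"])) for acc, spec in payload.items()
    }
    return DomainVocabulary(mapping)


def write_cluster_bed(clusters: Sequence[TandemCluster], loci: Mapping[str, GeneLocus], path) -> None:
    """Cluster spans as BED (0-based half-open), one row per cluster."""
    with open(path, "w") as fh:
        for i, cluster in enumerate(clusters):
            starts = [loci[g].start for g in cluster.members]
            ends = [loci[g].end for g in cluster.members]
            name = f"cluster_{i + 1:02d}" + ("_super" if cluster.is_super else "")
            fh.write(f"{cluster.chromosome}\t{min(starts) - 1}\t{max(ends)}\t{name}\t{len(cluster.members)}\t+\n")


def write_newick(tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
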