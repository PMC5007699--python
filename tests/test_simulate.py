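"""Generator ground truth, determinism, and round-trips through the
standard-format readers."""

import numpy as np
import pytest

from lecfam import FamilySimConfig, generate_catalogue, mutate_family
from lecfam.simulate import largest_remainder, mutate_sequence


class TestConfigValidation:
    def test_class_vii_for_l_type_rejected(self):
        with pytest.raises(ValueError, match="G-type feature"):
            FamilySimConfig(
                n_family_members=10,
                class_distribution={"G": {"I": 1.0}, "L": {"VII": 1.0}, "C": {"II": 1.0}},
            )

    def test_zero_family_with_clusters_rejected(self):
        with pytest.raises(ValueError):
            FamilySimConfig(n_family_members=0, tandem_cluster_sizes=[3], cluster_types=["G"], scaffold_genes={})

    def test_expressed_range_below_cutoff_rejected(self):
        with pytest.raises(ValueError):
            FamilySimConfig(fpkm_expressed_range=(0.5, 10.0))

    def test_type_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FamilySimConfig(type_proportions={"G": 0.6, "L": 0.3, "C": 0.2})


def test_largest_remainder_is_exact():
    counts = largest_remainder({"G": 180 / 231, "L": 50 / 231, "C": 1 / 231}, 231)
    assert counts == {"G": 180, "L": 50, "C": 1}
    assert largest_remainder({"a": 0.5, "b": 0.5}, 0) == {"a": 0, "b": 0}


class TestEmptyCase:
    def test_background_only_proteome(self):
        cfg = FamilySimConfig(
            n_family_members=0,
            n_background_proteins=5,
            tandem_cluster_sizes=[],
            cluster_types=[],
            scaffold_genes={},
            sex_specific={},
            lectin_only_decoys=2,
            kinase_only_decoys=1,
            n_extra_isoforms=0,
            seed=3,
        )
        cat = generate_catalogue(cfg)
        assert len(cat.proteome) == 5
        assert all(not t.family for t in cat.ground_truth.per_protein.values())
        assert cat.fpkm.empty
        assert cat.family_loci == []


def test_single_21_cluster_marks_exactly_one_super():
    cfg = FamilySimConfig(
        n_family_members=30,
        type_proportions={"G": 1.0},
        class_distribution={"I": 1.0},
        zone_distribution={"II": 1.0},
        tandem_cluster_sizes=[21],
        cluster_types=["G"],
        scaffold_genes={},
        sex_specific={},
        n_background_proteins=10,
        lectin_only_decoys=0,
        kinase_only_decoys=0,
        n_extra_isoforms=0,
        divergence_rate=0.0,
        fpkm_noise_sd=0.0,
        seed=5,
    )
    cat = generate_catalogue(cfg)
    super_genes = [g for g, t in cat.ground_truth.per_gene.items() if t.is_super]
    assert len(super_genes) == 21
    cluster_ids = {t.cluster_id for t in cat.ground_truth.per_gene.values() if t.cluster_id}
    assert len(cluster_ids) == 1


def test_zone_ii_only_design_all_fpkm_above_cutoff():
    """With all mass on Zone II and zero noise, every family gene has
    FPKM >= 1 in every standard-tissue sample."""
    cfg = FamilySimConfig(
        n_family_members=8,
        type_proportions={"G": 1.0},
        class_distribution={"I": 1.0},
        zone_distribution={"II": 1.0},
        tandem_cluster_sizes=[],
        cluster_types=[],
        scaffold_genes={},
        sex_specific={},
        n_background_proteins=0,
        lectin_only_decoys=0,
        kinase_only_decoys=0,
        n_extra_isoforms=0,
        divergence_rate=0.0,
        fpkm_noise_sd=0.0,
        seed=2,
    )
    cat = generate_catalogue(cfg)
    standard = [s for s, t in cat.grouping.items() if t in ("root", "leaf", "stem", "bud")]
    assert (cat.fpkm[standard] >= 1.0).all().all()


class TestMutateFamily:
    def test_zero_rate_identical(self):
        assert mutate_family("MKVLIT", 3, 0.0, seed=1) == ["MKVLIT"] * 3

    def test_single_copy_preserves_length(self):
        (copy,) = mutate_family("MKVLIT" * 10, 1, 0.3, seed=2)
        assert len(copy) == 60

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            mutate_family("", 2, 0.1, seed=0)

    def test_deterministic_under_seed(self):
        a = mutate_family("MKVLITAGHW" * 20, 5, 0.2, seed=9)
        b = mutate_family("MKVLITAGHW" * 20, 5, 0.2, seed=9)
        assert a == b

    def test_mean_p_distance_matches_closed_form(self):
        """Each site substitutes with probability r (never to itself), so
        E[p-distance to seed] = r; check within 3 SE over replicates."""
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seed_seq = "".join(rng.choice(aa, 1000))
        rate = 0.1
        copies = mutate_family(seed_seq, 10, rate, seed=4)
        p = np.mean([sum(a != b for a, b in zip(seed_seq, c)) / 1000 for c in copies])
        se = np.sqrt(rate * (1 - rate) / (1000 * 10))
        assert abs(p - rate) <= 3 * se

    def test_p_distance_monotone_in_rate(self):
        rng = np.random.default_rng(1)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seed_seq = "".join(rng.choice(aa, 2000))
        means = []
        for rate in (0.05, 0.2, 0.5):
            copies = mutate_family(seed_seq, 5, rate, seed=8)
            means.append(np.mean([sum(a != b for a, b in zip(seed_seq, c)) / 2000 for c in copies]))
        assert means == sorted(means)


class TestDeterminismAndRoundTrip:
    def test_byte_identical_outputs_under_fixed_seed(self, small_config):
        a = generate_catalogue(small_config)
        b = generate_catalogue(small_config)
        assert a.fasta_text() == b.fasta_text()
        assert a.gff3_text() == b.gff3_text()
        assert a.domain_table_text() == b.domain_table_text()
        assert a.topology_table_text() == b.topology_table_text()
        assert a.fpkm_text() == b.fpkm_text()
        assert a.ground_truth.to_json() == b.ground_truth.to_json()

    def test_different_seed_changes_sequences(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert generate_catalogue(small_config).fasta_text() != generate_catalogue(other).fasta_text()

    def test_payloads_parse_with_standard_readers(self, small_catalogue, tmp_path):
        """Emitted files round-trip through the package's FASTA/GFF3/TSV
        readers."""
        from lecfam import io as lio

        small_catalogue.write(tmp_path)
        proteome = lio.read_proteome(tmp_path / "proteome.fasta")
        assert {r.id for r in proteome} == {r.id for r in small_catalogue.proteome}
        assert {r.sequence for r in proteome} == {r.sequence for r in small_catalogue.proteome}

        hits = lio.read_domain_table(tmp_path / "domains.tsv")
        assert len(hits) == len(small_catalogue.domain_hits)

        models = lio.read_topology_table(tmp_path / "topology.tsv")
        assert set(models) == set(small_catalogue.topology_models)
        pid = next(iter(models))
        assert models[pid].segments == small_catalogue.topology_models[pid].segments

        loci = lio.read_gff3_genes(tmp_path / "genes.gff3")
        assert {(l.gene_id, l.chromosome, l.start, l.end) for l in loci} == {
            (l.gene_id, l.chromosome, l.start, l.end) for l in small_catalogue.all_loci
        }

        fpkm = lio.read_fpkm_matrix(tmp_path / "fpkm.tsv")
        assert fpkm.shape == small_catalogue.fpkm.shape
        assert np.allclose(fpkm.to_numpy(), small_catalogue.fpkm.to_numpy(), atol=1e-4)

        grouping = lio.read_grouping(tmp_path / "grouping.yaml")
        assert grouping == small_catalogue.grouping
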