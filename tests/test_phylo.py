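"""NJ exactness, JC correction, progressive MSA, bootstrap and monophyly."""

import math

import dendropy
import numpy as np
import pytest

from lecfam import (
    SaturatedDistanceError,
    bootstrap_support,
    is_monophyletic,
    msa_distance_matrix,
    nj_tree,
    progressive_msa,
    protein_distance,
)
from lecfam.phylo import MultipleAlignment, tree_bipartitions

from conftest import random_unrooted_tree


def nj_bipartition_lengths(tree):
    """bipartition -> pre-clamp branch length for every edge of an NJ tree."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        canon = min(side, leaves - side, key=lambda s: (len(s), tuple(sorted(s))))
        raw = node.annotations.get_value("raw_length")
        out[canon] = raw if raw is not None else node.edge.length
    return out


class TestProteinDistance:
    def test_identical_rows_zero(self):
        assert protein_distance("ACDEF", "ACDEF", "none") == 0.0
        assert protein_distance("ACDEF", "ACDEF") == 0.0

    def test_closed_form_at_p_01(self):
        row_i = "A" * 90 + "C" * 10
        row_j = "A" * 90 + "D" * 10
        expected = -0.95 * math.log(1 - 0.10 / 0.95)
        assert protein_distance(row_i, row_j) == pytest.approx(expected, rel=1e-12)

    def test_gaps_excluded_from_shared_columns(self):
        assert protein_distance("AC-EF", "ACW-F", "none") == 0.0

    def test_saturation_bound_errors(self):
        row_i = "A" * 20
        row_j = "C" * 19 + "A"  # p = 0.95 exactly
        with pytest.raises(SaturatedDistanceError):
            protein_distance(row_i, row_j)

    def test_no_shared_columns_errors(self):
        with pytest.raises(ValueError):
            protein_distance("A--", "-CC")


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxon_additive_matrix_exact(self):
        # tree ((a:1,b:2):0.5,(c:3,d:4)) — four-point condition holds
        D = np.array(
            [
                [0.0, 3.0, 4.5, 5.5],
                [3.0, 0.0, 5.5, 6.5],
                [4.5, 5.5, 0.0, 7.0],
                [5.5, 6.5, 7.0, 0.0],
            ]
        )
        tree = nj_tree(D, ["a", "b", "c", "d"])
        bp = nj_bipartition_lengths(tree)
        assert bp[frozenset({"a", "b"})] == pytest.approx(0.5, abs=1e-9)
        leaf_lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert leaf_lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})

    @pytest.mark.parametrize("trial", range(25))
    def test_additive_recovery_random_trees(self, trial):
        """On additive matrices from random 4-12 taxon trees NJ recovers
        the topology (RF = 0) and pre-clamp lengths to 1e-9."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 13))
        ids, D, true_bps = random_unrooted_tree(n, rng)
        tree = nj_tree(D, ids)
        got = nj_bipartition_lengths(tree)
        assert set(got) == set(true_bps)  # RF distance 0
        for bp, length in true_bps.items():
            assert got[bp] == pytest.approx(length, abs=1e-9)

    def test_negative_entries_rejected(self):
        D = np.array([[0.0, -0.1, 0.2], [-0.1, 0.0, 0.3], [0.2, 0.3, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(D, list("abc"))

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 0.1, 0.2], [0.4, 0.0, 0.3], [0.2, 0.3, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(D, list("abc"))


class TestProgressiveMSA:
    def test_identical_sequences_gap_free(self):
        msa = progressive_msa({"a": "MKVLIT", "b": "MKVLIT"})
        assert msa.rows == ("MKVLIT", "MKVLIT")

    def test_single_deletion_one_gap_column(self):
        msa = progressive_msa({"a": "ACDEF", "b": "ACEF"})
        row_b = msa.row("b")
        assert msa.row("a") == "ACDEF"
        assert row_b.count("-") == 1
        assert row_b.replace("-", "") == "ACEF"

    def test_pairwise_profile_matches_dp_optimum(self):
        """For two sequences the profile aligner must reach the pairwise
        affine-gap optimum."""
        from lecfam import ScoringScheme, align
        from lecfam.phylo import _profile_align, _substitution_array

        scheme = ScoringScheme()
        a, b = "MKVLITAGHWCDE", "MKVITWGHWDE"
        rows_a, rows_b = _profile_align([a], [b], scheme)
        matrix = scheme.matrix()
        score = 0.0
        gap_run = 0
        for x, y in zip(rows_a[0], rows_b[0]):
            if x == "-" or y == "-":
                gap_run += 1
                score -= scheme.gap_extend_cost
                if gap_run == 1:
                    score -= scheme.gap_open_cost
            else:
                gap_run = 0
                score += matrix[x, y]
        expected = align(a, b, scheme, "global").score
        assert score == pytest.approx(expected, abs=1e-6)

    def test_row_order_invariance(self):
        seqs = {"a": "MKVLITAGHW", "b": "MKVITAGW", "c": "MKVLITW"}
        m1 = progressive_msa(seqs)
        m2 = progressive_msa(dict(reversed(list(seqs.items()))))
        assert m1.ids == m2.ids
        assert m1.rows == m2.rows

    def test_ungapping_recovers_inputs(self):
        seqs = {"a": "MKVLITAGHW", "b": "MKVITAGW", "c": "MKVLITW", "d": "MKWLITAGHW"}
        msa = progressive_msa(seqs)
        for sid, seq in seqs.items():
            assert msa.row(sid).replace("-", "") == seq

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa({"a": "MKV"})


def strong_signal_alignment(seed=0, block=50, base=100):
    """Two pairs of taxa distinguished by a distinct duplicated block
    (zero homoplasy): the single non-trivial split of the 4-taxon tree
    is implied by essentially every resampled column set."""
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    shared = "".join(rng.choice(aa, base))
    block_a = "".join(rng.choice(aa, block))
    block_b = "".join(_shift(block_a))
    rows = {}
    for pair, blk in (("a", block_a), ("b", block_b)):
        for k in range(2):
            row = list(shared + blk)
            # a few private substitutions keep within-pair distances positive
            for pos in range(4):
                idx = 5 * (ord(pair) - ord("a")) + 20 * k + pos
                row[idx] = _shift(row[idx])[0]
            rows[f"{pair}{k}"] = "".join(row)
    ids = tuple(sorted(rows))
    return MultipleAlignment(ids, tuple(rows[i] for i in ids)), [{"a0", "a1"}, {"b0", "b1"}]


def _shift(block):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return [aa[(aa.index(x) + 7) % 20] for x in block]


def hierarchical_family_alignment(n_clades=4, per_clade=3, length=300, seed=0,
                                  deep=0.3, mid=0.15, tip=0.02):
    """Gap-free alignment simulated down a balanced tree: deep splits,
    clade ancestors, then lightly diverged members.  Returns the MSA and
    the designed clades."""
    from lecfam import mutate_family

    rng_root = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    root = "".join(rng_root.choice(aa, length))
    halves = mutate_family(root, 2, deep, seed=seed + 1)
    ancestors = []
    for h, half in enumerate(halves):
        ancestors.extend(mutate_family(half, n_clades // 2, mid, seed=seed + 2 + h))
    seqs = {}
    clades = []
    for c, anc in enumerate(ancestors):
        names = set()
        for k, s in enumerate(mutate_family(anc, per_clade, tip, seed=seed + 10 + c)):
            seqs[f"c{c}_{k}"] = s
            names.add(f"c{c}_{k}")
        clades.append(names)
    ids = tuple(sorted(seqs))
    return MultipleAlignment(ids, tuple(seqs[i] for i in ids)), clades


class TestBootstrap:
    def test_strong_signal_supports_all_one(self):
        msa, clades = strong_signal_alignment()
        tree = bootstrap_support(msa, n_replicates=100, seed=3)
        assert tree.bipartition_supports
        assert all(s == 1.0 for s in tree.bipartition_supports.values())
        for clade in clades:
            assert is_monophyletic(tree, clade)

    def test_hierarchical_clades_strongly_supported(self):
        """12 taxa in four designed clades: every true-clade bipartition
        gets near-unit bootstrap support."""
        msa, clades = hierarchical_family_alignment(seed=6)
        tree = bootstrap_support(msa, n_replicates=200, seed=13)
        leaves = frozenset(msa.ids)
        for clade in clades:
            canon = min(frozenset(clade), leaves - frozenset(clade),
                        key=lambda s: (len(s), tuple(sorted(s))))
            assert tree.bipartition_supports.get(canon, 0.0) >= 0.99
            assert is_monophyletic(tree, clade)

    def test_single_replicate_supports_binary(self):
        msa, _ = strong_signal_alignment(seed=5)
        tree = bootstrap_support(msa, n_replicates=1, seed=9)
        assert set(tree.bipartition_supports.values()) <= {0.0, 1.0}

    def test_fixed_seed_reproducible(self):
        msa, _ = strong_signal_alignment(seed=2)
        t1 = bootstrap_support(msa, n_replicates=50, seed=11)
        t2 = bootstrap_support(msa, n_replicates=50, seed=11)
        assert t1.bipartition_supports == t2.bipartition_supports

    def test_two_column_minimum(self):
        msa = MultipleAlignment(("a", "b", "c"), ("A", "C", "W"))
        with pytest.raises(ValueError):
            bootstrap_support(msa, 10, 0)


@pytest.fixture(scope="module")
def tree():
    newick = "((a:1,b:1):1,(c:1,d:1):1,(e:1,(f:1,g:1):1):1);"
    return dendropy.Tree.get(data=newick, schema="newick")


class TestMonophyly:

    def test_all_leaves_true(self, tree):
        assert is_monophyletic(tree, {"a", "b", "c", "d", "e", "f", "g"})

    def test_singleton_true(self, tree):
        assert is_monophyletic(tree, {"c"})

    def test_matches_exhaustive_bipartition_enumeration(self, tree):
        """Check every subset of <= 10 leaves against the definition:
        monophyletic iff the subset equals one side of some edge split."""
        import itertools

        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        splits = tree_bipartitions(tree)
        full = frozenset(leaves)
        all_splits = set()
        for s in splits:
            all_splits.add(s)
            all_splits.add(full - s)
        for leaf in leaves:
            all_splits.add(frozenset({leaf}))
            all_splits.add(full - frozenset({leaf}))
        all_splits.add(full)
        for r in range(1, len(leaves) + 1):
            for combo in itertools.combinations(leaves, r):
                expected = frozenset(combo) in all_splits
                assert is_monophyletic(tree, set(combo)) == expected

    def test_unknown_leaf_raises(self, tree):
        with pytest.raises(KeyError):
            is_monophyletic(tree, {"zz"})

    def test_cluster_members_form_clade_on_synthetic_family(self):
        """Sequences diverged from per-cluster ancestors, with
        between-cluster divergence far exceeding within-cluster
        divergence, are recovered as monophyletic clusters."""
        from lecfam import mutate_family

        rng = np.random.default_rng(4)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        root = "".join(rng.choice(aa, 300))
        ancestors = mutate_family(root, 3, 0.4, seed=21)
        seqs = {}
        clusters = []
        for c, anc in enumerate(ancestors):
            members = mutate_family(anc, 3, 0.02, seed=30 + c)
            names = set()
            for k, s in enumerate(members):
                name = f"cl{c}_{k}"
                seqs[name] = s
                names.add(name)
            clusters.append(names)
        msa = progressive_msa(seqs)
        tree = nj_tree(msa_distance_matrix(msa), msa.ids)
        for names in clusters:
            assert is_monophyletic(tree, names)
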