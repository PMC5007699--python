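"""Distance phylogenetics: progressive MSA, JC protein distances, NJ, bootstrap.

The tree-building path mirrors the classical distance validation
workflow for protein families: a progressive multiple alignment under
BLOSUM62 with affine gap costs (open 10, extend 0.2), pairwise
p-distances corrected with the 20-state Jukes-Cantor analogue

    d = -(19/20) * ln(1 - (20/19) * p),

neighbor-joining (Saitou-Nei Q-criterion) with negative branch-length
estimates clamped to zero, and nonparametric bootstrap supports from
column resampling.  NJ is exact on additive matrices: it recovers the
generating topology and, before clamping, the generating branch lengths.

Trees are dendropy objects (shared taxon namespace, Newick IO,
bipartition encoding); the NJ agglomeration itself is implemented here
because its determinism rules (lowest-index tie-break, logged clamping)
are part of the contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .homology import DEFAULT_SCHEME, ScoringScheme, align

logger = logging.getLogger(__name__)

GAP = "-"
_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_N_SYMBOLS = len(_ALPHABET) + 1  # + gap
_GAP_INDEX = len(_ALPHABET)

SATURATION_BOUND = 19.0 / 20.0


class SaturatedDistanceError(ValueError):
    """The observed p-distance reaches the correction's saturation bound."""


# --- multiple sequence alignment --------------------------------------------


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def to_matrix(self) -> np.ndarray:
        """(n_sequences, n_columns) int8 codes; gap = last index."""
        out = np.empty((len(self.rows), self.n_columns), dtype=np.int8)
        for i, row in enumerate(self.rows):
            out[i] = [_AA_INDEX.get(c, _GAP_INDEX) if c != GAP else _GAP_INDEX for c in row]
        return out


def _substitution_array(scheme: ScoringScheme) -> np.ndarray:
    m = scheme.matrix()
    S = np.zeros((_N_SYMBOLS, _N_SYMBOLS))
    for a in _ALPHABET:
        for b in _ALPHABET:
            S[_AA_INDEX[a], _AA_INDEX[b]] = m[a, b]
    # gap row/column score zero against residues: gap cost is handled by
    # the affine penalties, not the column score
    return S


def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    """(n_columns, n_symbols) relative frequency profile."""
    n_cols = len(rows[0])
    freqs = np.zeros((n_cols, _N_SYMBOLS))
    for row in rows:
        codes = [_AA_INDEX.get(c, _GAP_INDEX) if c != GAP else _GAP_INDEX for c in row]
        freqs[np.arange(n_cols), codes] += 1.0
    freqs /= len(rows)
    return freqs


def _profile_align(rows_a: Sequence[str], rows_b: Sequence[str], scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    """Global affine-gap profile-profile alignment (Gotoh, numpy rows).

    Column score is the frequency-weighted average substitution score;
    gap characters inside a profile score zero.  Gap costs follow the
    package convention cost(k) = open + k * extend and apply to terminal
    gaps as well, matching the pairwise global aligner.
    """
    S = _substitution_array(scheme)
    fa = _profile_freqs(rows_a)  # (m, s)
    fb = _profile_freqs(rows_b)  # (n, s)
    score = fa @ S @ fb.T  # (m, n) column-pair scores
    m, n = score.shape
    open_cost = scheme.gap_open_cost + scheme.gap_extend_cost
    ext = scheme.gap_extend_cost

    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)  # gap in A (consumes B columns)
    F = np.full((m + 1, n + 1), NEG)  # gap in B (consumes A columns)
    M[0, 0] = 0.0
    j = np.arange(1, n + 1)
    E[0, 1:] = -(scheme.gap_open_cost + j * ext)
    i = np.arange(1, m + 1)
    F[1:, 0] = -(scheme.gap_open_cost + i * ext)

    for r in range(1, m + 1):
        M[r, 1:] = np.maximum.reduce([M[r - 1, :-1], E[r - 1, :-1], F[r - 1, :-1]]) + score[r - 1]
        F[r, 1:] = np.maximum(F[r - 1, 1:] - ext, np.maximum(M[r - 1, 1:], E[r - 1, 1:]) - open_cost)
        # within-row recurrence for E via running max of (best + k*ext)
        best_prev = np.maximum(M[r, :-1], F[r, :-1])
        aug = best_prev + np.arange(n) * ext
        run = np.maximum.accumulate(aug)
        E[r, 1:] = run - scheme.gap_open_cost - np.arange(1, n + 1) * ext

    # traceback by value comparison
    out_a: list[str] = []
    out_b: list[str] = []
    r, c = m, n
    state = int(np.argmax([M[r, c], E[r, c], F[r, c]]))
    tol = 1e-9
    gap_a = GAP * len(rows_a)
    gap_b = GAP * len(rows_b)
    cols_a = ["".join(row[k] for row in rows_a) for k in range(m)]
    cols_b = ["".join(row[k] for row in rows_b) for k in range(n)]
    while r > 0 or c > 0:
        if state == 0:  # M
            out_a.append(cols_a[r - 1])
            out_b.append(cols_b[c - 1])
            prev = [M[r - 1, c - 1], E[r - 1, c - 1], F[r - 1, c - 1]]
            target = M[r, c] - score[r - 1, c - 1]
            state = _pick_state(prev, target, tol)
            r -= 1
            c -= 1
        elif state == 1:  # E: gap in A
            out_a.append(gap_a)
            out_b.append(cols_b[c - 1])
            if abs(E[r, c] - (E[r, c - 1] - ext)) <= tol:
                state = 1
            elif abs(E[r, c] - (M[r, c - 1] - open_cost)) <= tol:
                state = 0
            else:
                state = 2
            c -= 1
        else:  # F: gap in B
            out_a.append(cols_a[r - 1])
            out_b.append(gap_b)
            if abs(F[r, c] - (F[r - 1, c] - ext)) <= tol:
                state = 2
            elif abs(F[r, c] - (M[r - 1, c] - open_cost)) <= tol:
                state = 0
            else:
                state = 1
            r -= 1
        if r == 0 and c > 0:
            state = 1
        elif c == 0 and r > 0:
            state = 2

    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[k] for col in out_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in out_b) for k in range(len(rows_b))]
    return new_a, new_b


def _pick_state(prev: Sequence[float], target: float, tol: float) -> int:
    for idx, value in enumerate(prev):
        if abs(value - target) <= tol:
            return idx
    return int(np.argmax(prev))


def progressive_msa(
    sequences: dict[str, str] | Sequence[tuple[str, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> MultipleAlignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Guide distances are p-distances (1 - identity over aligned residue
    pairs) from pairwise global alignments; profiles are merged with the
    affine-gap profile aligner in guide-tree order.  Deterministic:
    identical inputs (in any order) give the same alignment up to row
    order.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    items.sort(key=lambda kv: kv[0])
    ids = [k for k, _ in items]
    seqs = [v for _, v in items]
    n = len(ids)
    if n < 2:
        raise ValueError("progressive_msa needs at least two sequences")
    if n == 2:
        a, b = _profile_align([seqs[0]], [seqs[1]], scheme)
        return MultipleAlignment((ids[0], ids[1]), (a[0], b[0]))

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = align(seqs[i], seqs[j], scheme, mode="global")
            n_pairs = len(res.aligned_pairs)
            if n_pairs == 0:
                p = 1.0
            else:
                ident = sum(1 for (x, y) in res.aligned_pairs if seqs[i][x - 1] == seqs[j][y - 1])
                p = 1.0 - ident / n_pairs
            dist[i, j] = dist[j, i] = p

    Z = linkage(squareform(dist, checks=False), method="average")
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(n)
    }
    for k, (a_idx, b_idx, _, _) in enumerate(Z):
        ids_a, rows_a = profiles.pop(int(a_idx))
        ids_b, rows_b = profiles.pop(int(b_idx))
        new_a, new_b = _profile_align(rows_a, rows_b, scheme)
        profiles[n + k] = (ids_a + ids_b, new_a + new_b)
    (final_ids, final_rows), = profiles.values()
    order = sorted(range(len(final_ids)), key=lambda i: final_ids[i])
    return MultipleAlignment(
        tuple(final_ids[i] for i in order), tuple(final_rows[i] for i in order)
    )


# --- distances ---------------------------------------------------------------


def protein_distance(row_i: str, row_j: str, correction: str = "jukes_cantor_protein") -> float:
    """Pairwise distance from two aligned rows.

    p = mismatches / shared non-gap columns; the 20-state Jukes-Cantor
    analogue corrects for multiple hits.  p at or beyond 19/20 saturates
    the correction and is an error.
    """
    if len(row_i) != len(row_j):
        raise ValueError("aligned rows differ in length")
    shared = mismatch = 0
    for x, y in zip(row_i, row_j):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x != y:
            mismatch += 1
    if shared == 0:
        raise ValueError("no shared non-gap columns")
    p = mismatch / shared
    if correction == "none":
        return p
    if correction != "jukes_cantor_protein":
        raise ValueError(f"unknown correction {correction!r}")
    if p >= SATURATION_BOUND:
        raise SaturatedDistanceError(f"p-distance {p:.4f} >= {SATURATION_BOUND}")
    return -SATURATION_BOUND * math.log(1.0 - p / SATURATION_BOUND)


def msa_distance_matrix(
    msa: MultipleAlignment,
    correction: str = "jukes_cantor_protein",
    codes: Optional[np.ndarray] = None,
) -> np.ndarray:
    """All-pairs distance matrix (vectorized over alignment columns)."""
    codes = msa.to_matrix() if codes is None else codes
    n = codes.shape[0]
    out = np.zeros((n, n))
    nongap = codes != _GAP_INDEX
    for i in range(n):
        shared = nongap[i] & nongap[i + 1 :]
        n_shared = shared.sum(axis=1)
        if np.any(n_shared == 0):
            raise ValueError("a sequence pair shares no non-gap columns")
        mism = ((codes[i] != codes[i + 1 :]) & shared).sum(axis=1)
        p = mism / n_shared
        if correction == "jukes_cantor_protein":
            if np.any(p >= SATURATION_BOUND):
                raise SaturatedDistanceError("saturated pairwise distance in alignment")
            d = -SATURATION_BOUND * np.log(1.0 - p / SATURATION_BOUND)
        else:
            d = p
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out


# --- neighbor joining --------------------------------------------------------


def nj_tree(matrix: np.ndarray, ids: Sequence[str], taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
    """Classical neighbor joining (Saitou-Nei).

    Tie-breaks on the Q-criterion go to the lowest (i, j) index pair in
    the current active ordering.  Negative branch-length estimates are
    clamped to zero; the pre-clamp value is kept in the node annotation
    ``raw_length`` and the total clamped deficit is logged.
    """
    D = np.asarray(matrix, dtype=float).copy()
    n = D.shape[0]
    if n < 3:
        raise ValueError("nj_tree needs at least three taxa")
    if D.shape[0] != D.shape[1] or len(ids) != n:
        raise ValueError("matrix/id shape mismatch")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be nonnegative")

    ns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False

    def new_leaf(name: str) -> dendropy.Node:
        node = dendropy.Node()
        taxon = ns.get_taxon(name) or ns.new_taxon(name)
        node.taxon = taxon
        return node

    def set_length(node: dendropy.Node, value: float) -> float:
        node.annotations.add_new("raw_length", value)
        clamped = max(0.0, value)
        node.edge.length = clamped
        return value - clamped

    nodes: list[dendropy.Node] = [new_leaf(name) for name in ids]
    active = list(range(n))
    deficit = 0.0

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among minima
        qmin = Q.min()
        ii, jj = min(zip(*np.where(Q == qmin)))
        if ii > jj:
            ii, jj = jj, ii
        a, b = active[ii], active[jj]
        d_ab = D[a, b]
        la = 0.5 * d_ab + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lb = d_ab - la
        parent = dendropy.Node()
        na, nb = nodes[a], nodes[b]
        parent.add_child(na)
        parent.add_child(nb)
        deficit -= min(0.0, set_length(na, la))
        deficit -= min(0.0, set_length(nb, lb))
        # distances from the new node
        new_row = 0.5 * (D[a, active] + D[b, active] - d_ab)
        D = np.pad(D, ((0, 1), (0, 1)))
        idx_new = D.shape[0] - 1
        D[idx_new, active] = new_row
        D[active, idx_new] = new_row
        D[idx_new, idx_new] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (a, b)] + [idx_new]

    # final three-taxon star with the three-point formulas
    x, y, z = active
    root = dendropy.Node()
    for node in (nodes[x], nodes[y], nodes[z]):
        root.add_child(node)
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    for node, length in ((nodes[x], lx), (nodes[y], ly), (nodes[z], lz)):
        deficit -= min(0.0, set_length(node, length))
    tree.seed_node = root
    if deficit > 0:
        logger.info("NJ clamped negative branch lengths; total deficit %.6g", deficit)
    tree.deficit = deficit
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller or
    lexicographically first side)."""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = frozenset(leaves - side)
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def bootstrap_support(
    msa: MultipleAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    correction: str = "jukes_cantor_protein",
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports.

    Each replicate resamples alignment columns with replacement,
    recomputes distances and NJ, and the support of every bipartition of
    the full-data tree is the fraction of replicates containing it.
    Replicates in which some pair shares no sampled non-gap column are
    redrawn (logged).  Deterministic under a fixed seed.
    """
    if msa.n_columns < 2:
        raise ValueError("bootstrap needs an alignment with at least two columns")
    codes = msa.to_matrix()
    full = nj_tree(msa_distance_matrix(msa, correction, codes=codes), msa.ids)
    targets = tree_bipartitions(full)
    counts = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    redraws = 0
    done = 0
    while done < n_replicates:
        cols = rng.integers(0, n_cols, size=n_cols)
        sample = codes[:, cols]
        try:
            dm = msa_distance_matrix(msa, correction, codes=sample)
        except (ValueError, SaturatedDistanceError):
            redraws += 1
            if redraws > 100 * n_replicates:
                raise RuntimeError("bootstrap cannot draw a usable replicate")
            continue
        rep = nj_tree(dm, msa.ids)
        rep_bps = tree_bipartitions(rep)
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
        done += 1
    if redraws:
        logger.info("redrew %d bootstrap replicates with undefined distances", redraws)

    supports = {bp: counts[bp] / n_replicates for bp in targets}
    leaves = {leaf.taxon.label for leaf in full.leaf_node_iter()}
    for node in full.preorder_node_iter():
        if node is full.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(side, frozenset(leaves - side), key=lambda s: (len(s), tuple(sorted(s))))
        if key in supports:
            node.label = f"{supports[key]:.3f}"
    full.bipartition_supports = supports
    return full


def is_monophyletic(tree: dendropy.Tree, gene_set: Iterable[str]) -> bool:
    """True iff some edge bipartition isolates exactly ``gene_set``."""
    wanted = frozenset(gene_set)
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = wanted - leaves
    if unknown:
        raise KeyError(f"unknown leaf ids: {sorted(unknown)[:5]}")
    if wanted == leaves or len(wanted) == 1:
        return True
    if not wanted:
        return False
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if side == wanted or (leaves - side) == wanted:
            return True
    return False
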