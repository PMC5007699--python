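import numpy as np
import pytest

from lecfam import FamilySimConfig, generate_catalogue


@pytest.fixture(scope="session")
def small_config():
    """A compact study design: 12 family members, one planted G-type
    3-gene tandem cluster, no divergence or expression noise."""
    return FamilySimConfig(
        n_family_members=12,
        n_background_proteins=10,
        tandem_cluster_sizes=[3],
        cluster_types=["G"],
        divergence_rate=0.0,
        fpkm_noise_sd=0.0,
        scaffold_genes={},
        sex_specific={},
        lectin_only_decoys=4,
        kinase_only_decoys=2,
        n_extra_isoforms=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_catalogue(small_config):
    return generate_catalogue(small_config)


def random_unrooted_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Built by sequential leaf attachment; returns (leaf ids, additive
    distance matrix, {bipartition frozenset -> branch length}).  Serves
    as an independent oracle for NJ: on the additive matrix NJ must
    recover exactly these bipartitions and lengths.
    """
    ids = [f"t{i}" for i in range(n_leaves)]
    # adjacency: node -> {neighbor: length}; internal nodes get negative ids
    adj: dict = {}
    next_internal = [-1]

    def add_edge(a, b, length):
        adj.setdefault(a, {})[b] = length
        adj.setdefault(b, {})[a] = length

    def new_internal():
        node = next_internal[0]
        next_internal[0] -= 1
        return node

    def blen():
        return float(rng.uniform(0.1, 1.0))

    center = new_internal()
    for leaf in ids[:3]:
        add_edge(center, leaf, blen())
    for leaf in ids[3:]:
        # canonical unordered edge list
        seen = set()
        edge_list = []
        for a in adj:
            for b in adj[a]:
                key = frozenset([a, b])
                if key not in seen:
                    seen.add(key)
                    edge_list.append((a, b))
        a, b = edge_list[int(rng.integers(0, len(edge_list)))]
        old = adj[a].pop(b)
        adj[b].pop(a)
        mid = new_internal()
        split = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, old * split)
        add_edge(mid, b, old * (1 - split))
        add_edge(mid, leaf, blen())

    # distances by BFS from each leaf
    import collections

    D = np.zeros((n_leaves, n_leaves))
    for i, leaf in enumerate(ids):
        dist = {leaf: 0.0}
        queue = collections.deque([leaf])
        while queue:
            node = queue.popleft()
            for nb, length in adj[node].items():
                if nb not in dist:
                    dist[nb] = dist[node] + length
                    queue.append(nb)
        for j, other in enumerate(ids):
            D[i, j] = dist[other]

    # bipartitions: cut each edge, collect the leaf side
    bipartitions = {}
    seen = set()
    for a in adj:
        for b in adj[a]:
            key = frozenset([a, b])
            if key in seen:
                continue
            seen.add(key)
            # leaves reachable from a without crossing (a, b)
            side = set()
            stack = [a]
            visited = {a, b}
            while stack:
                node = stack.pop()
                if isinstance(node, str):
                    side.add(node)
                for nb in adj[node]:
                    if nb not in visited:
                        visited.add(nb)
                        stack.append(nb)
            full = frozenset(ids)
            part = frozenset(side)
            canon = min(part, full - part, key=lambda s: (len(s), tuple(sorted(s))))
            bipartitions[canon] = adj[a][b]
    return ids, D, bipartitions
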