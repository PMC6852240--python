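"""Independent brute-force oracles shared by the unit and acceptance suites.

Each oracle re-derives its quantity from first principles (exhaustive
enumeration, direct recomputation, Monte-Carlo sampling) without touching
the implementation path it checks.
"""

import networkx as nx
import numpy as np


def closure_oracle(site_sets, threshold=0.60, small=5, min_size=5):
    """Site-merging closure: repeatedly merge the first mergeable pair in
    canonical order (size desc, lexicographic residues) until none remains;
    drop results at or below ``min_size``."""

    def key(s):
        return (-len(s), sorted((r.chain, r.number, r.icode) for r in s))

    def mergeable(x, y):
        inter = len(x & y)
        if min(len(x), len(y)) <= small:
            return inter >= 1
        return max(inter / len(x), inter / len(y)) > threshold

    pool = [frozenset(s) for s in site_sets]
    while True:
        pool.sort(key=key)
        merged = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                if mergeable(pool[i], pool[j]):
                    merged = (i, j)
                    break
            if merged:
                break
        if not merged:
            break
        i, j = merged
        union = pool[i] | pool[j]
        pool = [s for k, s in enumerate(pool) if k not in (i, j)] + [union]
    return sorted((s for s in pool if len(s) > min_size), key=key)


def oracle_average_linkage(atom_sets, cut):
    """Exhaustive average-linkage dendrogram: recompute the exact mean
    inter-atom distance between cluster unions at every merge step."""
    clusters = [[i] for i in range(len(atom_sets))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                A = np.vstack([atom_sets[i] for i in clusters[a]])
                B = np.vstack([atom_sets[i] for i in clusters[b]])
                d = np.linalg.norm(A[:, None] - B[None], axis=2).mean()
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        if best[0] > cut:
            break
        _, a, b = best
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return {frozenset(c) for c in clusters}


def tree_splits(tree):
    """Nontrivial leaf bipartitions induced by the edges of an unrooted
    tree (leaves = degree-1 nodes)."""
    leaves = {n for n in tree if tree.degree(n) == 1}
    splits = set()
    for edge in tree.edges:
        cut = tree.copy()
        cut.remove_edge(*edge)
        side = set(nx.node_connected_component(cut, edge[0])) & leaves
        other = leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({frozenset(side), frozenset(other)}))
    return splits


def random_additive_tree(rng, n_leaves):
    """Random binary topology with positive branch lengths; returns
    (leaf names, additive distance matrix, split set)."""
    g = nx.Graph()
    nodes = [f"L{i}" for i in range(n_leaves)]
    g.add_nodes_from(nodes)
    internal = 0
    pool = list(nodes)
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        u = f"I{internal}"
        internal += 1
        g.add_edge(pool[i], u, length=float(rng.uniform(0.05, 1.0)))
        g.add_edge(pool[j], u, length=float(rng.uniform(0.05, 1.0)))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [u]
    g.add_edge(pool[0], pool[1], length=float(rng.uniform(0.05, 1.0)))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    d = np.array([[lengths[a][b] for b in nodes] for a in nodes])
    return nodes, d, tree_splits(g)
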