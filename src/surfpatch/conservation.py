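"""Evolutionary conservation from sampled distance trees (T_JET).

Given a pool of homologs aligned to a query, representative subsets are drawn
so that the four identity bins [20-40), [40-60), [60-80), [80-98] contribute
about one quarter each. For each subset a neighbor-joining distance tree is
built (p-distance over gap-free columns), midpoint rooted, and each query
position receives a tree trace level: the depth of the shallowest ancestor of
the query leaf below which the query's amino acid is conserved in every leaf.
The conservation score averages depth-normalised levels over the trees,

    T_JET(j) = (1/M_j) * sum_t (L_t - l_j^t) / L_t,

where L_t is the maximum leaf depth of tree t and M_j counts the trees where
a trace exists for position j. Scores live in [0, 1]; positions conserved at
the root in every tree score 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HomologPool",
    "TraceTree",
    "sample_subsets",
    "distance_matrix",
    "nj_tree",
    "midpoint_root",
    "trace_levels",
    "compute_tjet",
    "compute_conservation",
    "IDENTITY_BINS",
]

GAP = "-"

#: Identity bins (lower inclusive, upper exclusive except the last, in %).
IDENTITY_BINS: tuple[tuple[float, float], ...] = (
    (20.0, 40.0),
    (40.0, 60.0),
    (60.0, 80.0),
    (80.0, 98.0),
)


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over columns where neither sequence has a gap."""
    if len(a) != len(b):
        raise ValueError("aligned lengths differ")
    comparable = matches = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    return 100.0 * matches / comparable


@dataclass
class HomologPool:
    """Query plus homologs in one alignment (equal aligned lengths)."""

    query_id: str
    query_aligned: str
    homolog_ids: list[str]
    homologs_aligned: list[str]
    identities: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = len(self.query_aligned)
        for hid, seq in zip(self.homolog_ids, self.homologs_aligned):
            if len(seq) != L:
                raise ValueError(f"homolog {hid}: aligned length mismatch")
        if not self.identities:
            self.identities = [
                pairwise_identity(self.query_aligned, h)
                for h in self.homologs_aligned
            ]
        for ident in self.identities:
            if not 0.0 < ident <= 100.0:
                raise ValueError(f"identity {ident} outside (0, 100]")

    def __len__(self) -> int:
        return len(self.homolog_ids)

    @classmethod
    def from_fasta(cls, path) -> "HomologPool":
        """First record is the query; remaining records are homologs."""
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        query = records[0]
        return cls(
            query_id=query.id,
            query_aligned=str(query.seq),
            homolog_ids=[r.id for r in records[1:]],
            homologs_aligned=[str(r.seq) for r in records[1:]],
        )


def _bin_of(identity: float) -> int | None:
    for k, (lo, hi) in enumerate(IDENTITY_BINS):
        last = k == len(IDENTITY_BINS) - 1
        if lo <= identity < hi or (last and identity == hi):
            return k
    return None


def sample_subsets(
    pool: HomologPool,
    n_subsets: int | None = None,
    subset_size: int | None = None,
    rng_seed: int = 0,
) -> list[list[int]]:
    """Draw homolog index subsets balanced across the identity bins.

    Sequences outside (20, 98]% identity to the query are excluded first.
    Each subset is drawn without replacement targeting one quarter per bin;
    when a bin cannot fill its quota the deficit is redistributed to the bins
    with spare sequences. Deterministic for a fixed ``rng_seed``.
    """
    if len(pool) == 0:
        raise ValueError("empty homolog pool")
    binned: list[list[int]] = [[] for _ in IDENTITY_BINS]
    for idx, ident in enumerate(pool.identities):
        b = _bin_of(ident)
        if b is not None:
            binned[b].append(idx)
    usable = sum(len(b) for b in binned)
    if usable == 0:
        raise ValueError("no homolog within (20, 98]% identity")

    if n_subsets is None:
        n_subsets = min(50, max(1, math.ceil(math.sqrt(usable))))
    if subset_size is None:
        subset_size = min(50, max(2, math.ceil(math.sqrt(usable))))

    if usable <= subset_size:
        warnings.warn(
            f"pool ({usable} usable homologs) not larger than subset size "
            f"{subset_size}; returning a single subset with the whole pool"
        )
        return [sorted(i for b in binned for i in b)]

    # quarter quotas with remainder spread over the first bins
    base = [subset_size // 4] * 4
    for k in range(subset_size % 4):
        base[k] += 1
    rng = np.random.default_rng(rng_seed)
    subsets: list[list[int]] = []
    for _ in range(n_subsets):
        quota = list(base)
        # move deficits to the bins with the most spare sequences
        for k in range(4):
            quota[k] = min(quota[k], len(binned[k]))
        remaining = subset_size - sum(quota)
        while remaining > 0:
            spare = [len(binned[k]) - quota[k] for k in range(4)]
            k = max(range(4), key=lambda i: (spare[i], -i))
            if spare[k] <= 0:
                break
            quota[k] += 1
            remaining -= 1
        chosen: list[int] = []
        for k in range(4):
            if quota[k] > 0:
                chosen.extend(
                    rng.choice(binned[k], size=quota[k], replace=False).tolist()
                )
        subsets.append(sorted(chosen))
    return subsets


def distance_matrix(sequences: list[str]) -> np.ndarray:
    """p-distance matrix: mismatch fraction over mutually gap-free columns."""
    n = len(sequences)
    arr = np.array([list(s) for s in sequences])
    gaps = arr == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(
                    f"sequences {i} and {j} share no gap-free column"
                )
            d[i, j] = d[j, i] = (arr[i, ok] != arr[j, ok]).mean()
    return d


def nj_tree(d: np.ndarray, names: list[str]) -> nx.Graph:
    """Neighbor joining with deterministic ties (lowest index pair).

    Returns an unrooted tree as a graph: leaves are ``names``, internal
    nodes are integers, edges carry a ``length`` attribute (negative branch
    lengths clamped to zero with a warning).
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two taxa")
    if len(names) != n:
        raise ValueError("names/matrix size mismatch")

    g = nx.Graph()
    active: list[object] = list(names)
    dist = {
        (a, b): d[i, j]
        for i, a in enumerate(active)
        for j, b in enumerate(active)
        if i < j
    }

    def get(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    def clamp(x, where):
        if x < 0:
            warnings.warn(f"negative branch length at {where} clamped to 0")
            return 0.0
        return x

    next_internal = 0
    while len(active) > 2:
        r = len(active)
        sums = {a: sum(get(a, b) for b in active if b is not a) for a in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * get(a, b) - sums[a] - sums[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        a, b = active[i], active[j]
        dab = get(a, b)
        la = 0.5 * dab + (sums[a] - sums[b]) / (2 * (r - 2))
        lb = dab - la
        u = next_internal
        next_internal += 1
        g.add_edge(a, u, length=clamp(la, a))
        g.add_edge(b, u, length=clamp(lb, b))
        for c in active:
            if c is a or c is b:
                continue
            dist[(u, c)] = 0.5 * (get(a, c) + get(b, c) - dab)
        active = [c for c in active if c is not a and c is not b] + [u]
    a, b = active
    g.add_edge(a, b, length=clamp(get(a, b), (a, b)))
    return g


def midpoint_root(tree: nx.Graph) -> tuple[object, nx.DiGraph]:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Returns ``(root, rooted)`` where ``rooted`` is the tree oriented away
    from the root. A synthetic node ``"__root__"`` is inserted when the
    midpoint falls inside an edge.
    """
    leaves = sorted(
        (n for n in tree if tree.degree(n) == 1), key=str
    )
    if len(leaves) == 1:  # single edge counts both ends as leaves elsewhere
        raise ValueError("tree has fewer than two leaves")
    lengths = dict(nx.all_pairs_dijkstra_path_length(tree, weight="length"))
    best = max(
        ((lengths[u][v], str(u), str(v), u, v)
         for i, u in enumerate(leaves) for v in leaves[i + 1:]),
        key=lambda t: (t[0], t[1], t[2]),
    )
    total, _, _, u, v = best
    path = nx.shortest_path(tree, u, v, weight="length")
    half = total / 2.0
    rooted_tree = tree.copy()
    root: object = path[0]
    walked = 0.0
    for a, b in zip(path, path[1:]):
        edge = tree[a][b]["length"]
        if walked + edge >= half - 1e-12:
            offset = half - walked
            if offset <= 1e-12:
                root = a
            elif abs(edge - offset) <= 1e-12:
                root = b
            else:
                root = "__root__"
                rooted_tree.remove_edge(a, b)
                rooted_tree.add_edge(a, root, length=offset)
                rooted_tree.add_edge(root, b, length=edge - offset)
            break
        walked += edge
    rooted = nx.bfs_tree(rooted_tree, root)
    for a, b in rooted.edges:
        rooted[a][b]["length"] = rooted_tree[a][b]["length"]
    return root, rooted


@dataclass
class TraceTree:
    """A rooted trace tree with per-query-position levels."""

    root: object
    rooted: nx.DiGraph
    max_level: int  # L_t: depth of the deepest leaf
    levels: dict[int, int | None]  # query position -> l (None = no trace)


def trace_levels(
    tree: nx.Graph,
    aligned: dict[str, str],
    query_name: str,
) -> TraceTree:
    """Tree trace level of every query position for one tree.

    For each position the level is the depth (root = 0) of the shallowest
    ancestor of the query leaf whose entire leaf set carries the query's
    amino acid; positions with no such ancestor are flagged as no-trace
    (``None``) and later excluded from the averaging.
    """
    if query_name not in tree:
        raise ValueError(f"query {query_name!r} is not a leaf of the tree")
    root, rooted = midpoint_root(tree)
    depth = nx.shortest_path_length(rooted, root)  # edge counts
    leaves_below: dict[object, set[str]] = {}
    for node in nx.dfs_postorder_nodes(rooted, root):
        kids = list(rooted.successors(node))
        if not kids:
            leaves_below[node] = {node} if isinstance(node, str) and node in aligned else set()
        else:
            leaves_below[node] = set().union(*(leaves_below[k] for k in kids))
    max_level = max(depth[n] for n in rooted if not list(rooted.successors(n)))

    # ancestors of the query leaf, root first, excluding the leaf itself
    path = nx.shortest_path(rooted, root, query_name)
    ancestors = path[:-1]

    qseq = aligned[query_name]
    levels: dict[int, int | None] = {}
    qpos = 0
    for col, aa in enumerate(qseq):
        if aa == GAP:
            continue
        qpos += 1  # 1-based ungapped query position
        level: int | None = None
        for node in ancestors:
            if all(aligned[leaf][col] == aa for leaf in leaves_below[node]):
                level = depth[node]
                break
        levels[qpos] = level
    return TraceTree(root=root, rooted=rooted, max_level=max(max_level, 1),
                     levels=levels)


def compute_tjet(traces: list[TraceTree]) -> pd.DataFrame:
    """Average depth-normalised trace levels over trees.

    Returns a frame indexed by query position with columns ``tjet`` and
    ``m`` (number of trees contributing). Positions with no trace in any
    tree score 0.
    """
    if not traces:
        raise ValueError("no trace trees supplied")
    positions = sorted(traces[0].levels)
    rows = []
    for pos in positions:
        contrib = [
            (t.max_level - t.levels[pos]) / t.max_level
            for t in traces
            if t.levels.get(pos) is not None
        ]
        m = len(contrib)
        rows.append(
            {"position": pos, "tjet": sum(contrib) / m if m else 0.0, "m": m}
        )
    return pd.DataFrame(rows).set_index("position")


def compute_conservation(
    pool: HomologPool,
    n_subsets: int | None = None,
    subset_size: int | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Full pipeline: subsets -> distances -> NJ trees -> traces -> T_JET."""
    subsets = sample_subsets(pool, n_subsets, subset_size, rng_seed)
    traces = []
    for subset in subsets:
        names = [pool.homolog_ids[i] for i in subset] + [pool.query_id]
        seqs = [pool.homologs_aligned[i] for i in subset] + [pool.query_aligned]
        d = distance_matrix(seqs)
        tree = nj_tree(d, names)
        aligned = dict(zip(names, seqs))
        traces.append(trace_levels(tree, aligned, pool.query_id))
    return compute_tjet(traces)
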