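"""Seed clustering and partner-multiplicity analysis.

Seeds predicted by the non-conservation-only strategies (``SC_notLig``,
``SC_geom``, ``SC_dock``; ``SC_cons`` seeds are discarded as too large and
overlapping) are clustered in 3D by agglomerative average linkage over all
inter-atomic distances between seed atom sets, cutting the dendrogram at
23 A. Partner multiplicity of an interacting region is indicated by the
number of distinct strategies contributing a seed lying (almost) completely
within the region (precision >= 80%). The number of distinct partners of a
query is estimated by single-linkage clustering of partner sequences at 90%
global-alignment identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import InteractingRegion, global_alignment_identity
from .structure import ResidueId, Structure

__all__ = [
    "TaggedSeed",
    "ClusteredSeed",
    "cluster_seeds",
    "count_partners",
    "sc_multiplicity",
    "CLUSTER_CUT",
]

CLUSTER_CUT = 23.0  # Angstrom
CLUSTERABLE_STRATEGIES = ("SC_notLig", "SC_geom", "SC_dock")
PARTNER_IDENTITY_THRESHOLD = 90.0
SEED_PPV_MIN = 0.8


@dataclass(frozen=True)
class TaggedSeed:
    strategy: str
    residues: frozenset[ResidueId]

    def atom_coords(self, structure: Structure) -> np.ndarray:
        coords = []
        for rid in self.residues:
            coords.extend(
                a.coord for a in structure.get_residue(rid).heavy_atoms()
            )
        return np.array(coords)


@dataclass
class ClusteredSeed:
    member_indices: list[int]
    strategies: frozenset[str]
    residues: frozenset[ResidueId]


def cluster_seeds(
    seeds: list[TaggedSeed],
    structure: Structure,
    cut: float = CLUSTER_CUT,
    include_all_strategies: bool = False,
) -> list[ClusteredSeed]:
    """Average-linkage clustering of seed atom sets, dendrogram cut at
    ``cut`` A.

    The linkage distance between two clusters is the mean over all atom
    pairs drawn from either side, so clusters are weighted by atom count
    (Lance-Williams update). Ties merge the lowest index pair. ``SC_cons``
    seeds are excluded unless ``include_all_strategies``.
    """
    if include_all_strategies:
        usable = list(enumerate(seeds))
    else:
        usable = [
            (i, s) for i, s in enumerate(seeds)
            if s.strategy in CLUSTERABLE_STRATEGIES
        ]
    if not usable:
        return []
    coords = [s.atom_coords(structure) for _, s in usable]
    n = len(usable)
    # mean pairwise inter-atom distance between seed i and seed j
    dist = np.zeros((n, n))
    sizes = np.array([len(c) for c in coords], dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            diffs = coords[i][:, None, :] - coords[j][None, :, :]
            dist[i, j] = dist[j, i] = np.linalg.norm(diffs, axis=2).mean()

    clusters: list[list[int]] = [[k] for k in range(n)]
    active = list(range(n))
    d = dist.copy()
    w = sizes.copy()
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                if best is None or d[i, j] < best[0] - 1e-12:
                    best = (d[i, j], i, j)
        if best[0] > cut:
            break
        _, i, j = best
        # Lance-Williams average-linkage update, atom-count weighted
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (w[i] * d[i, k] + w[j] * d[j, k]) / (w[i] + w[j])
        w[i] += w[j]
        clusters[i] = clusters[i] + clusters[j]
        active.remove(j)

    out = []
    for i in sorted(active):
        members = sorted(clusters[i])
        residues: set[ResidueId] = set()
        strategies: set[str] = set()
        for m in members:
            orig_index, seed = usable[m]
            residues |= seed.residues
            strategies.add(seed.strategy)
        out.append(
            ClusteredSeed(
                member_indices=[usable[m][0] for m in members],
                strategies=frozenset(strategies),
                residues=frozenset(residues),
            )
        )
    return out


def count_partners(
    partner_sequences: list[str],
    identity_threshold: float = PARTNER_IDENTITY_THRESHOLD,
) -> int:
    """Number of partner clusters at >= 90% identity (single linkage).

    Two partners below the threshold land in different clusters; chains of
    pairwise-similar partners collapse into one.
    """
    n = len(partner_sequences)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident = global_alignment_identity(
                partner_sequences[i], partner_sequences[j]
            )
            if ident >= identity_threshold:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def sc_multiplicity(
    ir: InteractingRegion,
    seeds: list[TaggedSeed],
    ppv_min: float = SEED_PPV_MIN,
) -> int:
    """Number of distinct strategies with a seed lying within the region.

    A seed counts when its precision with respect to the region,
    |seed & IR| / |seed|, reaches ``ppv_min``. The result is in {0..3} for
    the three clusterable strategies.
    """
    strategies: set[str] = set()
    for seed in seeds:
        if not seed.residues or seed.strategy not in CLUSTERABLE_STRATEGIES:
            continue
        ppv = len(seed.residues & ir.residues) / len(seed.residues)
        if ppv >= ppv_min:
            strategies.add(seed.strategy)
    return len(strategies)
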