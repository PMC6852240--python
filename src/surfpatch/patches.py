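"""Seed-extension prediction of interacting patches.

Each scoring strategy names the residue scores used by the three admission
layers of a predicted patch:

* ``SC_cons``   - seed on conservation (T_JET), extend on T_JET+PC, outer
  layer on PC+CV; targets conserved binding sites.
* ``SC_notLig`` - seed and extension on T_JET+CV (conserved but not buried
  in deep pockets), outer on PC+CV; discriminates against small-ligand sites.
* ``SC_geom``   - PC+CV everywhere; geometry/physicochemistry only.
* ``SC_dock``   - the docking-derived NIP score everywhere.

Where a layer names two scores their arithmetic mean on the [0, 1] scale is
used. Admission is quantile-based and strictly ordered (seed > extension >
outer) so the signal is strongest in the seed and fades outward. Seeds are
clusters (>= 3 residues, 5 A atomic connectivity) of residues above the seed
quantile; extension admits contacting surface residues above the extension
quantile in descending score order up to a target patch size; the outer
layer is added once at the end. Growing patches closer than 5 A merge.

The iterative consensus re-runs the prediction (re-sampling the conservation
trees when the strategy uses T_JET) and keeps residues detected in at least
``min_hits`` of ``n_iter`` iterations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import ResidueId, Structure

__all__ = [
    "StrategySpec",
    "STRATEGIES",
    "Patch",
    "ConsensusPatch",
    "PredictionResult",
    "residue_contact_graph",
    "detect_seeds",
    "grow_patch",
    "predict_patches",
]

CONTACT_CUTOFF = 5.0
MIN_SEED_SIZE = 3


@dataclass(frozen=True)
class StrategySpec:
    name: str
    seed_cols: tuple[str, ...]
    ext_cols: tuple[str, ...]
    outer_cols: tuple[str, ...]
    seed_quantile: float = 0.9
    ext_quantile: float = 0.6
    outer_quantile: float = 0.5
    target_fraction: float = 0.25  # of the surface residue count

    def __post_init__(self) -> None:
        if not self.seed_quantile > self.ext_quantile > self.outer_quantile:
            raise ValueError(
                "admission quantiles must decrease seed > extension > outer"
            )

    def required_columns(self) -> set[str]:
        return set(self.seed_cols) | set(self.ext_cols) | set(self.outer_cols)


STRATEGIES: dict[str, StrategySpec] = {
    "SC_cons": StrategySpec(
        "SC_cons", ("tjet",), ("tjet", "pc"), ("pc", "cv"), target_fraction=0.33
    ),
    "SC_notLig": StrategySpec(
        "SC_notLig", ("tjet", "cv"), ("tjet", "cv"), ("pc", "cv"),
        target_fraction=0.33,
    ),
    "SC_geom": StrategySpec(
        "SC_geom", ("pc", "cv"), ("pc", "cv"), ("pc", "cv"),
        target_fraction=0.25,
    ),
    "SC_dock": StrategySpec(
        "SC_dock", ("nip",), ("nip",), ("nip",), target_fraction=0.25
    ),
}


@dataclass
class Patch:
    strategy: str
    seed: frozenset[ResidueId]
    extension: frozenset[ResidueId] = frozenset()
    outer: frozenset[ResidueId] = frozenset()
    iteration: int = 0

    @property
    def residues(self) -> frozenset[ResidueId]:
        return self.seed | self.extension | self.outer


@dataclass
class ConsensusPatch:
    strategy: str
    residues: frozenset[ResidueId]
    hits: dict[ResidueId, int] = field(default_factory=dict)


@dataclass
class PredictionResult:
    strategy: str
    patches: list[ConsensusPatch]
    seeds: list[frozenset[ResidueId]]
    iterations: list[list[Patch]]

    @property
    def predicted(self) -> frozenset[ResidueId]:
        out: set[ResidueId] = set()
        for p in self.patches:
            out |= p.residues
        return frozenset(out)


def _canonical(rid: ResidueId) -> tuple:
    return (rid.chain, rid.number, rid.icode)


def residue_contact_graph(
    structure: Structure,
    rids: list[ResidueId],
    cutoff: float = CONTACT_CUTOFF,
) -> dict[ResidueId, set[ResidueId]]:
    """Adjacency (strict < cutoff, any-atom) among the given residues."""
    coords = []
    owner = []
    wanted = set(rids)
    for res in structure.residues():
        if res.rid in wanted:
            for atom in res.heavy_atoms():
                coords.append(atom.coord)
                owner.append(res.rid)
    adj: dict[ResidueId, set[ResidueId]] = {rid: set() for rid in rids}
    if not coords:
        return adj
    coords = np.array(coords)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        if owner[i] != owner[j] and np.linalg.norm(coords[i] - coords[j]) < cutoff:
            adj[owner[i]].add(owner[j])
            adj[owner[j]].add(owner[i])
    return adj


def _components(
    members: set[ResidueId], adj: dict[ResidueId, set[ResidueId]]
) -> list[set[ResidueId]]:
    seen: set[ResidueId] = set()
    comps: list[set[ResidueId]] = []
    for start in sorted(members, key=_canonical):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nb in adj.get(node, ()):
                if nb in members and nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        comps.append(comp)
    return comps


def _layer_score(table: pd.DataFrame, cols: tuple[str, ...]) -> pd.Series:
    for col in cols:
        if col not in table.columns or table[col].isna().all():
            raise ValueError(
                f"score column {col!r} is required by this strategy but absent"
            )
    return table[list(cols)].mean(axis=1)


def detect_seeds(
    table: pd.DataFrame,
    spec: StrategySpec,
    structure: Structure,
    adjacency: dict[ResidueId, set[ResidueId]] | None = None,
) -> list[frozenset[ResidueId]]:
    """Clusters of residues strictly above the seed quantile (>= 3 residues,
    5 A connectivity; clusters closer than 5 A are part of one component)."""
    score = _layer_score(table, spec.seed_cols)
    threshold = float(np.nanquantile(score, spec.seed_quantile))
    floor = float(np.nanmin(score))
    # >= quantile but strictly above the global floor: a saturated top
    # score still seeds, a flat score distribution never does
    passing = {
        ResidueId.parse(idx)
        for idx, s in score.items()
        if s >= threshold and s > floor
    }
    if not passing:
        return []
    if adjacency is None:
        all_rids = [ResidueId.parse(i) for i in table.index]
        adjacency = residue_contact_graph(structure, all_rids)
    comps = [
        c for c in _components(passing, adjacency) if len(c) >= MIN_SEED_SIZE
    ]
    comps.sort(key=lambda c: min(_canonical(r) for r in c))
    return [frozenset(c) for c in comps]


def grow_patch(
    seed: frozenset[ResidueId],
    table: pd.DataFrame,
    spec: StrategySpec,
    structure: Structure,
    adjacency: dict[ResidueId, set[ResidueId]] | None = None,
    target_size: int | None = None,
    iteration: int = 0,
) -> Patch:
    """Extend a seed by contacting high-scoring residues, then add the outer
    layer once."""
    all_rids = [ResidueId.parse(i) for i in table.index]
    if adjacency is None:
        adjacency = residue_contact_graph(structure, all_rids)
    if target_size is None:
        target_size = max(
            MIN_SEED_SIZE, int(round(spec.target_fraction * len(all_rids)))
        )
    if target_size < len(seed):
        warnings.warn(
            f"target patch size {target_size} below seed size {len(seed)}; "
            "patch will be seed + outer layer only"
        )

    ext_score = _layer_score(table, spec.ext_cols)
    ext_threshold = float(np.nanquantile(ext_score, spec.ext_quantile))
    ext_floor = float(np.nanmin(ext_score))
    patch: set[ResidueId] = set(seed)
    extension: set[ResidueId] = set()
    while len(patch) < target_size:
        frontier = {
            nb
            for rid in patch
            for nb in adjacency.get(rid, ())
            if nb not in patch
            and ext_score.get(str(nb), -np.inf) >= ext_threshold
            and ext_score.get(str(nb), -np.inf) > ext_floor
        }
        if not frontier:
            break
        # tie-break: highest score, then canonical (chain, resnum, icode)
        top_score = max(ext_score[str(r)] for r in frontier)
        tied = sorted(
            (r for r in frontier if ext_score[str(r)] == top_score),
            key=_canonical,
        )
        best = tied[0]
        patch.add(best)
        extension.add(best)

    outer_score = _layer_score(table, spec.outer_cols)
    outer_threshold = float(np.nanquantile(outer_score, spec.outer_quantile))
    outer_floor = float(np.nanmin(outer_score))
    outer = {
        nb
        for rid in patch
        for nb in adjacency.get(rid, ())
        if nb not in patch
        and outer_score.get(str(nb), -np.inf) >= outer_threshold
        and outer_score.get(str(nb), -np.inf) > outer_floor
    }
    return Patch(
        strategy=spec.name,
        seed=frozenset(seed),
        extension=frozenset(extension),
        outer=frozenset(outer),
        iteration=iteration,
    )


def _patches_in_contact(
    a: Patch, b: Patch, adjacency: dict[ResidueId, set[ResidueId]]
) -> bool:
    ra, rb = a.residues, b.residues
    if ra & rb:
        return True
    return any(nb in rb for rid in ra for nb in adjacency.get(rid, ()))


def _merge_patch_pair(a: Patch, b: Patch) -> Patch:
    seed = a.seed | b.seed
    ext = (a.extension | b.extension) - seed
    outer = (a.outer | b.outer) - seed - ext
    return Patch(a.strategy, seed, ext, outer, a.iteration)


def merge_contacting_patches(
    patches: list[Patch], adjacency: dict[ResidueId, set[ResidueId]]
) -> list[Patch]:
    """Merge patches closer than the contact cutoff, to a fixpoint."""
    out = list(patches)
    changed = True
    while changed:
        changed = False
        out.sort(key=lambda p: min(_canonical(r) for r in p.residues))
        for i, j in itertools.combinations(range(len(out)), 2):
            if _patches_in_contact(out[i], out[j], adjacency):
                merged = _merge_patch_pair(out[i], out[j])
                out = [p for k, p in enumerate(out) if k not in (i, j)]
                out.append(merged)
                changed = True
                break
    return out


def predict_patches(
    table: pd.DataFrame,
    strategy: str | StrategySpec,
    structure: Structure,
    n_iter: int = 10,
    min_hits: int = 2,
    rng_seed: int = 0,
    rescore=None,
) -> PredictionResult:
    """Iterative consensus prediction for one strategy.

    ``rescore(iteration, rng) -> pd.DataFrame`` supplies a per-iteration
    score table (used to re-sample the conservation trees for T_JET-based
    strategies); without it every iteration sees the same table and the
    consensus reduces to a single deterministic run.
    """
    spec = STRATEGIES[strategy] if isinstance(strategy, str) else strategy
    rng = np.random.default_rng(rng_seed)
    all_rids = [ResidueId.parse(i) for i in table.index]
    adjacency = residue_contact_graph(structure, all_rids)
    target = max(
        MIN_SEED_SIZE, int(round(spec.target_fraction * len(all_rids)))
    )

    hits: dict[ResidueId, int] = {}
    iterations: list[list[Patch]] = []
    seeds: list[frozenset[ResidueId]] = []
    for it in range(n_iter):
        tbl = rescore(it, rng) if rescore is not None else table
        iter_seeds = detect_seeds(tbl, spec, structure, adjacency)
        grown = [
            grow_patch(s, tbl, spec, structure, adjacency, target, it)
            for s in iter_seeds
        ]
        grown = merge_contacting_patches(grown, adjacency)
        iterations.append(grown)
        for p in grown:
            if p.seed not in seeds:
                seeds.append(p.seed)
            for rid in p.residues:
                hits[rid] = hits.get(rid, 0) + 1

    consensus = {rid for rid, h in hits.items() if h >= min_hits}
    final: list[ConsensusPatch] = []
    for comp in _components(consensus, adjacency):
        final.append(
            ConsensusPatch(
                strategy=spec.name,
                residues=frozenset(comp),
                hits={rid: hits[rid] for rid in comp},
            )
        )
    final.sort(key=lambda p: min(_canonical(r) for r in p.residues))
    return PredictionResult(
        strategy=spec.name, patches=final, seeds=seeds, iterations=iterations
    )


def patches_to_frame(result: PredictionResult) -> pd.DataFrame:
    """Flatten a prediction into a (strategy, patch, layer, residue) table."""
    rows = []
    for pid, patch in enumerate(result.patches):
        for rid in sorted(patch.residues, key=_canonical):
            rows.append(
                {
                    "strategy": result.strategy,
                    "patch_id": pid,
                    "chain": rid.chain,
                    "resnum": rid.number,
                    "icode": rid.icode,
                    "hits": patch.hits.get(rid, 0),
                }
            )
    return pd.DataFrame(rows)
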