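"""Interface detection and support/core/rim layer assignment.

A residue of the query chain is interfacial when any of its atoms lies
strictly closer than the cutoff (default 5 A) to any atom of a partner chain.
Interfaces contain surface residues only (rasa >= 5% on the monomer). Layers
follow the buried/exposed dichotomy at 25% relative accessibility computed
with and without the partner: support stays buried, core becomes buried on
binding, rim stays exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.spatial import cKDTree

from .sasa import SurfaceMap, compute_rasa
from .structure import ResidueId, Structure

__all__ = [
    "InterfaceLayers",
    "detect_interface",
    "interface_layers",
    "classify_layers",
]

CONTACT_CUTOFF = 5.0
BURIAL_RASA_THRESHOLD = 0.25


@dataclass
class InterfaceLayers:
    support: frozenset[ResidueId]
    core: frozenset[ResidueId]
    rim: frozenset[ResidueId]

    @property
    def interface(self) -> frozenset[ResidueId]:
        return self.support | self.core | self.rim


def _contact_residues(
    structure: Structure,
    side_a: list[str],
    side_b: list[str],
    cutoff: float,
) -> tuple[set[ResidueId], set[ResidueId]]:
    coords_a, index_a = structure.atom_array(chains=side_a)
    coords_b, index_b = structure.atom_array(chains=side_b)
    out_a: set[ResidueId] = set()
    out_b: set[ResidueId] = set()
    if len(coords_a) == 0 or len(coords_b) == 0:
        return out_a, out_b
    tree_b = cKDTree(coords_b)
    pairs = cKDTree(coords_a).query_ball_tree(tree_b, cutoff)
    for i, hits in enumerate(pairs):
        for j in hits:
            # query_ball_tree uses <=; the contact rule is strict <
            d = ((coords_a[i] - coords_b[j]) ** 2).sum() ** 0.5
            if d < cutoff:
                out_a.add(index_a[i][0])
                out_b.add(index_b[j][0])
    return out_a, out_b


def detect_interface(
    structure: Structure,
    chain_a: str,
    partner_chains: set[str] | list[str],
    cutoff: float = CONTACT_CUTOFF,
    surface_a: SurfaceMap | None = None,
    surface_b: SurfaceMap | None = None,
    restrict_to_surface: bool = True,
) -> tuple[set[ResidueId], set[ResidueId]]:
    """Residues of ``chain_a`` and of the partner side in atomic contact.

    Returns ``(side_a, side_partner)``. Surface maps are computed on each
    side alone (monomer context) when not supplied.
    """
    partners = sorted(set(partner_chains))
    if chain_a in partners:
        raise ValueError(f"chain {chain_a!r} cannot be its own partner")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    side_a, side_b = _contact_residues(structure, [chain_a], partners, cutoff)
    if restrict_to_surface:
        if surface_a is None:
            surface_a = compute_rasa(structure, context=[chain_a])
        if surface_b is None:
            surface_b = compute_rasa(structure, context=partners)
        surf_a = set(surface_a.surface_residues())
        surf_b = set(surface_b.surface_residues())
        side_a &= surf_a
        side_b &= surf_b
    return side_a, side_b


def interface_layers(
    structure: Structure,
    chain_a: str,
    partner_chains: set[str] | list[str],
    cutoff: float = CONTACT_CUTOFF,
    burial_threshold: float = BURIAL_RASA_THRESHOLD,
    n_points: int = 960,
) -> InterfaceLayers:
    """Partition the chain-A interface into support, core and rim."""
    partners = sorted(set(partner_chains))
    alone = compute_rasa(structure, context=[chain_a], n_points=n_points)
    complexed = compute_rasa(
        structure,
        context=[chain_a] + partners,
        chains=[chain_a],
        n_points=n_points,
    )
    iface, _ = detect_interface(
        structure, chain_a, partners, cutoff=cutoff, surface_a=alone
    )
    if not iface:
        raise ValueError("interface is empty; no layers to assign")
    return classify_layers(
        iface,
        {rid: alone.rasa_of(rid) for rid in iface},
        {rid: complexed.rasa_of(rid) for rid in iface},
        burial_threshold,
    )


def classify_layers(
    interface_residues: set[ResidueId],
    rasa_free: dict[ResidueId, float],
    rasa_bound: dict[ResidueId, float],
    burial_threshold: float = BURIAL_RASA_THRESHOLD,
) -> InterfaceLayers:
    """Layer assignment from relative accessibilities with and without the
    partner: support stays buried, core becomes buried, rim stays exposed."""
    support: set[ResidueId] = set()
    core: set[ResidueId] = set()
    rim: set[ResidueId] = set()
    for rid in interface_residues:
        free = rasa_free[rid]
        bound = rasa_bound[rid]
        if free < burial_threshold:
            support.add(rid)
        elif bound < burial_threshold:
            core.add(rid)
        else:
            rim.add(rid)
    return InterfaceLayers(frozenset(support), frozenset(core), frozenset(rim))
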