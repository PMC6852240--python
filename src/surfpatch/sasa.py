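"""Solvent accessibility: Shrake-Rupley sphere sampling and relative ASA.

The accessible surface area of each atom is estimated by placing a fixed,
deterministic set of points (a golden-spiral lattice, default 960 points) on a
sphere of radius r_vdw + r_probe and counting the points not occluded by any
neighbouring atom's probe-expanded sphere. Relative accessibility (rasa) is
the residue ASA divided by a per-residue-type reference maximum (Tien et al.
2013 theoretical values), so rasa can slightly exceed 1 for exposed residues
in extended conformations. A residue is a surface residue when rasa >= 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import ResidueId, Structure

__all__ = ["SurfaceMap", "compute_rasa", "shrake_rupley", "MAX_ASA", "VDW_RADII"]

#: Theoretical maximum ASA per residue type (A^2), Tien et al. 2013.
MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Van der Waals radii (A) by element; unknown elements fall back to 1.80.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90,
}
_DEFAULT_RADIUS = 1.80

SURFACE_RASA_THRESHOLD = 0.05


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` unit vectors."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible surface area (A^2) for one coordinate set."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    if n_atoms == 0:
        return np.zeros(0)
    points = sphere_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = expanded.max()
    asa = np.zeros(n_atoms)
    for i in range(n_atoms):
        r_i = expanded[i]
        neighbours = tree.query_ball_point(coords[i], r_i + max_reach)
        neighbours = [j for j in neighbours if j != i]
        test = coords[i] + r_i * points
        accessible = np.ones(len(points), dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(test - coords[j], axis=1)
            accessible &= d >= expanded[j]
            if not accessible.any():
                break
        asa[i] = 4.0 * np.pi * r_i**2 * accessible.sum() / len(points)
    return asa


@dataclass
class SurfaceMap:
    """Per-residue relative accessibility and surface flags for one chain set.

    ``table`` is indexed by residue id string with columns ``chain``,
    ``resnum``, ``icode``, ``restype``, ``asa``, ``rasa``, ``surface``.
    """

    table: pd.DataFrame
    context: tuple[str, ...]

    @property
    def rasa(self) -> pd.Series:
        return self.table["rasa"]

    def rasa_of(self, rid: ResidueId) -> float:
        return float(self.table.loc[str(rid), "rasa"])

    def is_surface(self, rid: ResidueId) -> bool:
        return bool(self.table.loc[str(rid), "surface"])

    def surface_residues(self) -> list[ResidueId]:
        return [
            ResidueId.parse(i) for i in self.table.index[self.table["surface"]]
        ]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="residue")


def compute_rasa(
    structure: Structure,
    context: list[str] | None = None,
    chains: list[str] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
    surface_threshold: float = SURFACE_RASA_THRESHOLD,
) -> SurfaceMap:
    """Relative accessibility of residues of ``chains`` within ``context``.

    ``context`` names the chains whose atoms occlude (default: all chains in
    the structure); ``chains`` restricts the reported residues (default: the
    context chains). Residue types without a reference value are excluded
    from the surface with a warning.
    """
    if context is None:
        context = structure.chain_ids()
    if chains is None:
        chains = list(context)
    if not set(chains) <= set(context):
        raise ValueError("reported chains must be part of the context")

    coords, index = structure.atom_array(chains=context)
    radii = np.array(
        [VDW_RADII.get(a.element, _DEFAULT_RADIUS) for _, a in index]
    )
    asa = shrake_rupley(coords, radii, probe_radius, n_points)

    per_res: dict[ResidueId, float] = {}
    for (rid, _), area in zip(index, asa):
        per_res[rid] = per_res.get(rid, 0.0) + area

    rows = []
    for res in structure.residues(chains):
        ref = MAX_ASA.get(res.name)
        total = per_res.get(res.rid, 0.0)
        if ref is None:
            warnings.warn(
                f"residue type {res.name} ({res.rid}) has no reference ASA; "
                "excluded from surface"
            )
            rasa = np.nan
            surface = False
        else:
            rasa = total / ref
            surface = rasa >= surface_threshold
        rows.append(
            {
                "residue": str(res.rid),
                "chain": res.chain_id,
                "resnum": res.number,
                "icode": res.icode,
                "restype": res.name,
                "asa": total,
                "rasa": rasa,
                "surface": surface,
            }
        )
    table = pd.DataFrame(rows).set_index("residue")
    return SurfaceMap(table=table, context=tuple(context))
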