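"""Per-residue surface descriptors and the assembled score table.

Circular variance (CV) measures the density of protein around an atom:

    CV_i = 1 - || sum_j r_ij / ||r_ij|| || / n_i

over the n_i neighbouring atoms within r_c. The resultant of the unit
vectors vanishes for an atom surrounded isotropically (CV -> 1, buried) and
is maximal for a protruding atom whose neighbours all lie on one side
(CV -> 0). Residue CV averages the atomic values (heavy atoms by default)
and is then min-max rescaled over the surface residues.

PC is an amino-acid interface propensity scaled by its published maximum
2.21 to land in [0, 1]. The bundled table is a synthetic stand-in (see
``PC_PROPENSITIES_SYNTHETIC``) and can be overridden from file.

The score table joins T_JET, PC, CV and NIP on (chain, resnum, icode) for
the surface residues; NIP keeps its native scale plus a [0, 1] min-max copy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sasa import SurfaceMap
from .structure import ResidueId, Structure

__all__ = [
    "compute_cv",
    "pc_scores",
    "assemble_score_table",
    "load_pc_table",
    "PC_PROPENSITIES_SYNTHETIC",
    "PC_MAX",
]

CV_RADIUS = 100.0  # effectively global density
PC_MAX = 2.21

#: Synthetic stand-in interface-propensity table, scaled to [0, 2.21].
#: Ordering follows the well-established enrichment of aromatic and large
#: hydrophobic residues at protein-protein interfaces (Trp highest) and the
#: depletion of charged/small polar residues; the specific numbers are NOT
#: the published ones and carry no provenance beyond this file.
PC_PROPENSITIES_SYNTHETIC: dict[str, float] = {
    "TRP": 2.21, "PHE": 1.80, "MET": 1.77, "TYR": 1.66, "ILE": 1.44,
    "LEU": 1.30, "CYS": 1.25, "HIS": 1.09, "VAL": 1.00, "ARG": 0.93,
    "PRO": 0.76, "ASN": 0.70, "THR": 0.64, "GLN": 0.61, "ALA": 0.57,
    "GLY": 0.54, "SER": 0.52, "ASP": 0.48, "GLU": 0.37, "LYS": 0.26,
}


def load_pc_table(path=None) -> dict[str, float]:
    """Load an interface-propensity table (TSV: restype, value) or the bundled
    synthetic stand-in."""
    if path is None:
        return dict(PC_PROPENSITIES_SYNTHETIC)
    df = pd.read_csv(path, sep="\t", header=None, names=["restype", "value"],
                     comment="#")
    table = {str(r.restype).upper(): float(r.value) for r in df.itertuples()}
    if len(table) < 20:
        raise ValueError("propensity table must cover the 20 standard residues")
    return table


def compute_cv(
    structure: Structure,
    chains: list[str] | None = None,
    r_c: float = CV_RADIUS,
    heavy_only: bool = True,
    surface: SurfaceMap | None = None,
) -> pd.DataFrame:
    """Residue circular variance; raw values plus a surface-rescaled copy.

    Returns a frame indexed by residue id with columns ``cv_raw`` and ``cv``
    (min-max rescaled over surface residues when a surface map is given,
    else over all residues).
    """
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    coords, index = structure.atom_array(chains=chains, heavy_only=heavy_only)
    n = len(coords)
    tree = cKDTree(coords)
    atomic = np.zeros(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(coords[i], r_c) if j != i]
        # query_ball_point is <=; the neighbourhood rule is strict <
        neigh = [
            j for j in neigh
            if np.linalg.norm(coords[j] - coords[i]) < r_c
        ]
        if not neigh:
            warnings.warn(
                f"atom {index[i][1].name} of {index[i][0]} has no neighbour "
                f"within {r_c} A; CV set to 0"
            )
            atomic[i] = 0.0
            continue
        vecs = coords[neigh] - coords[i]
        unit = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        atomic[i] = 1.0 - np.linalg.norm(unit.sum(axis=0)) / len(neigh)

    per_res: dict[ResidueId, list[float]] = {}
    for (rid, _), value in zip(index, atomic):
        per_res.setdefault(rid, []).append(value)
    raw = pd.Series(
        {str(rid): float(np.mean(v)) for rid, v in per_res.items()},
        name="cv_raw",
    )
    if surface is not None:
        pool = raw.loc[[str(r) for r in surface.surface_residues()
                        if str(r) in raw.index]]
    else:
        pool = raw
    lo, hi = float(pool.min()), float(pool.max())
    scaled = (raw - lo) / (hi - lo) if hi > lo else raw * 0.0
    scaled = scaled.clip(0.0, 1.0)
    return pd.DataFrame({"cv_raw": raw, "cv": scaled.rename("cv")})


def pc_scores(
    restypes: pd.Series, table: dict[str, float] | None = None
) -> pd.Series:
    """Scale residue-type propensities by the published maximum (2.21)."""
    if table is None:
        table = load_pc_table()
    out = {}
    for rid, name in restypes.items():
        raw = table.get(str(name).upper())
        if raw is None:
            warnings.warn(f"no propensity for residue type {name} ({rid}); 0")
            raw = 0.0
        out[rid] = raw / PC_MAX
    return pd.Series(out, name="pc")


def assemble_score_table(
    surface: SurfaceMap,
    pc: pd.Series,
    cv: pd.Series,
    tjet: pd.Series | None = None,
    nip: pd.Series | None = None,
) -> pd.DataFrame:
    """Join the per-residue scores over the surface residues.

    Index: residue id strings of surface residues. Columns: ``chain``,
    ``resnum``, ``icode``, ``restype``, then ``pc``, ``cv`` and the optional
    ``tjet``, ``nip`` and ``nip01`` (min-max rescale of NIP). A score series
    overlapping the surface on fewer than half of its residues raises, since
    that almost always signals a residue-numbering mismatch.
    """
    base = surface.table[surface.table["surface"]][
        ["chain", "resnum", "icode", "restype"]
    ].copy()

    def attach(series: pd.Series | None, name: str) -> None:
        if series is None:
            return
        overlap = base.index.intersection(series.index)
        if len(overlap) < 0.5 * len(base):
            raise ValueError(
                f"score {name!r} overlaps only {len(overlap)}/{len(base)} "
                "surface residues; residue numbering likely mismatched"
            )
        missing = base.index.difference(series.index)
        if len(missing):
            warnings.warn(
                f"score {name!r} missing for {len(missing)} surface residues"
            )
        base[name] = series.reindex(base.index)

    attach(tjet, "tjet")
    attach(pc, "pc")
    attach(cv, "cv")
    attach(nip, "nip")
    if "nip" in base.columns:
        col = base["nip"]
        lo, hi = float(col.min()), float(col.max())
        base["nip01"] = (col - lo) / (hi - lo) if hi > lo else col * 0.0
    return base
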