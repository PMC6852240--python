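"""Evaluation of predicted patches against experimental interfaces.

Residue-level precision, recall and F1 compare a predicted residue set with
an experimental site or region on the same chain numbering. Per region, the
best-matching patch or union of patches is searched exhaustively over patch
subsets (up to 2^k for k <= 12 patches, greedy beyond); surface coverage is
the fraction of surface residues used by a set union. Conformational
variability of a region is its mean backbone RMSD between the query
structure and each homolog carrying the region, after least-squares (Kabsch)
superposition on the region residues.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .structure import BACKBONE_ATOMS, ResidueId, Structure

__all__ = [
    "MatchReport",
    "prf",
    "best_match",
    "coverage",
    "kabsch_rmsd",
    "ir_rmsd",
]


@dataclass
class MatchReport:
    precision: float
    recall: float
    f1: float
    tp: frozenset[ResidueId] = frozenset()
    fp: frozenset[ResidueId] = frozenset()
    fn: frozenset[ResidueId] = frozenset()
    matched_by: tuple[int, ...] = ()  # indices of the patches in the union
    missed: bool = False


def prf(
    predicted: frozenset[ResidueId] | set[ResidueId],
    truth: frozenset[ResidueId] | set[ResidueId],
) -> MatchReport:
    """Residue-level precision/recall/F1; empty prediction scores 0."""
    predicted, truth = frozenset(predicted), frozenset(truth)
    tp = predicted & truth
    p = len(tp) / len(predicted) if predicted else 0.0
    r = len(tp) / len(truth) if truth else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return MatchReport(
        precision=p,
        recall=r,
        f1=f1,
        tp=tp,
        fp=predicted - truth,
        fn=truth - predicted,
        missed=len(tp) == 0,
    )


def best_match(
    patches: list[frozenset[ResidueId]],
    truth: frozenset[ResidueId],
    max_exhaustive: int = 12,
) -> MatchReport:
    """Best F1 over unions of patch subsets; ties prefer the smaller union.

    Exhaustive for up to ``max_exhaustive`` patches; greedy (add the patch
    improving F1 the most until no improvement) beyond that, with a warning.
    """
    overlapping = [
        (i, p) for i, p in enumerate(patches) if p & truth
    ]
    if not overlapping:
        return MatchReport(0.0, 0.0, 0.0, fn=frozenset(truth), missed=True)

    def score(indices: tuple[int, ...]) -> tuple[float, int]:
        union: set[ResidueId] = set()
        for i in indices:
            union |= patches[i]
        rep = prf(union, truth)
        return rep.f1, -len(union)

    if len(overlapping) <= max_exhaustive:
        best_idx: tuple[int, ...] = ()
        best_key = (-1.0, 0)
        for k in range(1, len(overlapping) + 1):
            for combo in itertools.combinations((i for i, _ in overlapping), k):
                key = score(combo)
                if key > best_key:
                    best_key, best_idx = key, combo
    else:
        warnings.warn(
            f"{len(overlapping)} candidate patches; falling back to greedy "
            "subset search"
        )
        chosen: list[int] = []
        best_key = (-1.0, 0)
        improved = True
        while improved:
            improved = False
            for i, _ in overlapping:
                if i in chosen:
                    continue
                key = score(tuple(chosen + [i]))
                if key > best_key:
                    best_key = key
                    chosen.append(i)
                    improved = True
        best_idx = tuple(chosen)

    union: set[ResidueId] = set()
    for i in best_idx:
        union |= patches[i]
    report = prf(union, truth)
    report.matched_by = best_idx
    return report


def coverage(
    sets: list[frozenset[ResidueId]], surface: set[ResidueId]
) -> float:
    """Fraction of the surface used by the union of the given residue sets."""
    if not surface:
        raise ValueError("empty surface")
    union: set[ResidueId] = set()
    for s in sets:
        if not set(s) <= set(surface):
            raise ValueError("sets must be subsets of the surface")
        union |= s
    return len(union) / len(surface)


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD of Q onto P after optimal least-squares superposition."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    diff = Pc - Qc @ R.T
    return float(np.sqrt((diff**2).sum() / len(P)))


def _region_backbone(
    structure: Structure, residues: list[ResidueId]
) -> tuple[np.ndarray, list[tuple[ResidueId, str]]]:
    coords, labels = [], []
    for rid in residues:
        res = structure.get_residue(rid)
        for name in BACKBONE_ATOMS:
            atom = res.get_atom(name)
            if atom is not None:
                coords.append(atom.coord)
                labels.append((rid, name))
    return np.array(coords), labels


def ir_rmsd(
    ir_residues: frozenset[ResidueId],
    query: Structure,
    homologs: list[tuple[Structure, dict[ResidueId, ResidueId]]],
    ca_only_fallback: bool = True,
) -> float:
    """Mean backbone RMSD of a region between query and homolog structures.

    Each homolog comes with a map from query residue ids to its own residue
    ids; only region residues present on that homolog enter its
    superposition. Homologs with fewer than three mappable residues are
    skipped with a warning. Uses N/CA/C/O atoms shared by both sides, or CA
    only when the full backbone cannot be paired.
    """
    values = []
    for hstruct, res_map in homologs:
        mappable = sorted(
            (rid for rid in ir_residues if rid in res_map),
            key=lambda r: (r.chain, r.number, r.icode),
        )
        if len(mappable) < 3:
            warnings.warn(
                f"homolog {hstruct.id}: only {len(mappable)} mappable region "
                "residues; skipped"
            )
            continue
        P, Q = [], []
        for rid in mappable:
            qres = query.get_residue(rid)
            hres = hstruct.get_residue(res_map[rid])
            for name in BACKBONE_ATOMS:
                qa, ha = qres.get_atom(name), hres.get_atom(name)
                if qa is not None and ha is not None:
                    P.append(qa.coord)
                    Q.append(ha.coord)
        if len(P) < 3 and ca_only_fallback:
            P, Q = [], []
            for rid in mappable:
                qa = query.get_residue(rid).get_atom("CA")
                ha = hstruct.get_residue(res_map[rid]).get_atom("CA")
                if qa is not None and ha is not None:
                    P.append(qa.coord)
                    Q.append(ha.coord)
        if len(P) < 3:
            warnings.warn(f"homolog {hstruct.id}: too few paired atoms; skipped")
            continue
        values.append(kabsch_rmsd(np.array(P), np.array(Q)))
    if not values:
        raise ValueError("no homolog could be superposed")
    return float(np.mean(values))
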