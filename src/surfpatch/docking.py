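"""Cross-docking pose statistics: interface propensity (IP) and its
per-protein normalisation (NIP).

Pose records are the input (docking itself is upstream): each pose carries a
partner id, an energy, and the set of query residues at the docked interface.
Per partner, only poses within an energy window of that partner's best pose
are retained (default 2.7 kcal/mol, strict). Then

    IP(i)  = N_int(i) / N_pos        (poses placing residue i at the interface)
    NIP(i) = (IP(i) - <IP>) / (max IP - <IP>)

with mean and max over the residues considered (optionally surface residues
only). NIP is 1 at the most-docked residue, 0 at the mean, negative for
disfavoured residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .structure import ResidueId

__all__ = [
    "DockingPose",
    "DockingPoseSet",
    "filter_poses",
    "compute_ip",
    "compute_nip",
    "read_pose_tsv",
    "write_pose_tsv",
]

ENERGY_WINDOW = 2.7  # kcal/mol


@dataclass
class DockingPose:
    pose_id: str
    partner_id: str
    energy: float
    interface: frozenset[ResidueId]

    def __post_init__(self) -> None:
        self.interface = frozenset(self.interface)
        if not pd.notna(self.energy) or self.energy in (float("inf"), float("-inf")):
            raise ValueError(f"pose {self.pose_id}: non-finite energy")


@dataclass
class DockingPoseSet:
    protein_id: str
    poses: list[DockingPose] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.poses)

    def partners(self) -> list[str]:
        return sorted({p.partner_id for p in self.poses})


def filter_poses(
    pose_set: DockingPoseSet, window: float = ENERGY_WINDOW
) -> DockingPoseSet:
    """Keep, per partner, the poses with E - E_min strictly below ``window``.

    The best-scored pose of each partner is always retained.
    """
    if not pose_set.poses:
        raise ValueError("empty pose set")
    best: dict[str, float] = {}
    for pose in pose_set.poses:
        best[pose.partner_id] = min(
            best.get(pose.partner_id, float("inf")), pose.energy
        )
    kept = [
        p for p in pose_set.poses if p.energy - best[p.partner_id] < window
    ]
    return DockingPoseSet(pose_set.protein_id, kept)


def compute_ip(
    pose_set: DockingPoseSet, residues: list[ResidueId]
) -> pd.Series:
    """IP(i) = fraction of poses (pooled over partners) docking residue i."""
    n_pos = len(pose_set)
    if n_pos < 1:
        raise ValueError("need at least one pose")
    counts = {rid: 0 for rid in residues}
    for pose in pose_set.poses:
        for rid in pose.interface:
            if rid in counts:
                counts[rid] += 1
    return pd.Series(
        {str(rid): counts[rid] / n_pos for rid in residues}, name="ip"
    )


def compute_nip(ip: pd.Series) -> pd.Series:
    """Normalise IP to NIP; constant IP maps to all zeros with a warning."""
    if len(ip) == 0:
        raise ValueError("empty IP table")
    if len(ip) < 2:
        raise ValueError("need at least two residues to normalise")
    mean, top = float(ip.mean()), float(ip.max())
    if top == mean:
        warnings.warn("constant IP distribution; all NIP set to 0")
        return pd.Series(0.0, index=ip.index, name="nip")
    return ((ip - mean) / (top - mean)).rename("nip")


def write_pose_tsv(pose_set: DockingPoseSet, path) -> None:
    """pose_id, partner_id, energy, semicolon-joined residue ids."""
    rows = [
        {
            "pose_id": p.pose_id,
            "partner_id": p.partner_id,
            "energy": p.energy,
            "interface": ";".join(sorted(str(r) for r in p.interface)),
        }
        for p in pose_set.poses
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pose_tsv(path, protein_id: str = "query") -> DockingPoseSet:
    df = pd.read_csv(path, sep="\t", dtype={"pose_id": str, "partner_id": str})
    poses = [
        DockingPose(
            pose_id=row.pose_id,
            partner_id=row.partner_id,
            energy=float(row.energy),
            interface=frozenset(
                ResidueId.parse(tok)
                for tok in str(row.interface).split(";")
                if tok and tok != "nan"
            ),
        )
        for row in df.itertuples()
    ]
    return DockingPoseSet(protein_id, poses)
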