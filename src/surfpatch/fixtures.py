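"""Synthetic structures, homolog pools and docking poses with planted truth.

Every stage of the pipeline is testable without downloads: complexes are
built from ideal alpha-helices (approximate backbone plus a radial
pseudo-side-chain giving realistic contact reach), homolog pools are
generated by random substitutions that respect a designated set of conserved
columns, and docking pose sets sample interface residues with a controllable
bias towards a planted hot region. Geometry is idealised, not physical: the
fixtures plant signals, they do not emulate folding or energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conservation import HomologPool
from .docking import DockingPose, DockingPoseSet
from .interface import detect_interface
from .sasa import SurfaceMap, compute_rasa
from .structure import THREE_TO_ONE, Atom, Chain, Residue, ResidueId, Structure

__all__ = [
    "SyntheticComplexSpec",
    "make_complex",
    "make_helix_chain",
    "make_homolog_pool",
    "make_poses",
]

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

HELIX_RADIUS = 2.3  # A, C-alpha ring
HELIX_RISE = 1.5  # A per residue
HELIX_TURN = math.radians(100.0)
CLASH_TOLERANCE = 2.0  # A, minimal allowed inter-chain atom distance


@dataclass
class SyntheticComplexSpec:
    """A synthetic complex with a contact face by construction.

    Two geometries are available. ``"lattice"`` (default) stacks slab-like
    chains: each chain is a grid of pseudo-residues, the partner chain is a
    smaller slab placed over the first so the overlap area is a contiguous
    planted interface. ``"helix"`` builds ideal alpha-helices side by side;
    the contact face is then the sparse stripe of facing side-chain arms.
    """

    n_chains: int = 2
    # partner slab sized so the planted interface covers about half the
    # query surface, the coverage scale reported for experimentally
    # derived interacting regions
    n_residues: tuple[int, ...] = (40, 20)
    geometry: str = "lattice"  # "lattice" | "helix"
    separation: float = 13.0  # helix axis distance / lattice plane gap + 6
    noise_sigma: float = 0.0  # isotropic coordinate noise (A)
    rng_seed: int = 0
    sequences: tuple[str, ...] | None = None
    antiparallel: bool = True  # helix geometry only

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if len(self.n_residues) != self.n_chains:
            raise ValueError("one residue count per chain required")
        if self.geometry not in ("lattice", "helix"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    letters = sorted(ONE_TO_THREE)
    return "".join(rng.choice(letters, size=n))


def make_helix_chain(
    chain_id: str,
    sequence: str,
    origin: np.ndarray,
    reverse: bool = False,
    phase: float = 0.0,
) -> Chain:
    """Ideal helix along z with N/CA/C/O backbone and a radial CB/CG arm."""
    residues = []
    n = len(sequence)
    for i in range(n):
        t = (n - 1 - i) if reverse else i
        theta = phase + t * HELIX_TURN
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        ca = origin + HELIX_RADIUS * radial + np.array([0, 0, t * HELIX_RISE])
        axis = np.array([0.0, 0.0, -1.0 if reverse else 1.0])
        atoms = [
            Atom("N", "N", ca - 0.8 * axis * HELIX_RISE - 0.4 * radial),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + 0.8 * axis * HELIX_RISE - 0.4 * radial),
            Atom("O", "O", ca + 0.8 * axis * HELIX_RISE + 0.8 * radial),
        ]
        aa3 = ONE_TO_THREE.get(sequence[i], "ALA")
        if aa3 != "GLY":
            atoms.append(Atom("CB", "C", ca + 1.5 * radial))
            atoms.append(Atom("CG", "C", ca + 2.9 * radial))
        residues.append(Residue(chain_id, i + 1, "", aa3, atoms))
    return Chain(chain_id, residues)


def make_lattice_chain(
    chain_id: str,
    sequence: str,
    origin: np.ndarray,
    width: int = 5,
    spacing: float = 4.0,
    flip: bool = False,
) -> Chain:
    """Slab chain: residues on a planar grid with a perpendicular CB arm.

    The CB arm points +y (or -y when ``flip``); facing slabs therefore touch
    through their arms while their backbones stay apart. Every residue gets
    a CB regardless of type so the contact geometry is type-independent.
    """
    residues = []
    arm = -1.5 if flip else 1.5
    for i, letter in enumerate(sequence):
        row, col = divmod(i, width)
        ca = origin + np.array([col * spacing, 0.0, row * spacing])
        atoms = [
            Atom("N", "N", ca + np.array([-1.2, 0.0, -0.5])),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + np.array([1.2, 0.0, 0.5])),
            Atom("O", "O", ca + np.array([1.2, 0.0, 1.7])),
            Atom("CB", "C", ca + np.array([0.0, arm, 0.0])),
        ]
        residues.append(
            Residue(chain_id, i + 1, "", ONE_TO_THREE.get(letter, "ALA"), atoms)
        )
    return Chain(chain_id, residues)


def make_complex(
    spec: SyntheticComplexSpec,
) -> tuple[Structure, dict[str, set[ResidueId]]]:
    """Build the complex and its ground-truth interface per chain.

    The truth is, by construction, exactly what interface detection reports
    on the noise-free coordinates; noisy coordinates are produced by adding
    isotropic Gaussian displacement afterwards. Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.sequences is None:
        sequences = tuple(
            _random_sequence(n, rng) for n in spec.n_residues
        )
    else:
        sequences = spec.sequences
    chain_ids = [chr(ord("A") + k) for k in range(spec.n_chains)]
    chains = []
    for k, (cid, seq) in enumerate(zip(chain_ids, sequences)):
        if spec.geometry == "helix":
            origin = np.array([k * spec.separation, 0.0, 0.0])
            # facing phase: point the side-chain arms of neighbouring
            # chains at each other so a contact face exists by construction
            phase = 0.0 if k % 2 == 0 else math.pi
            reverse = spec.antiparallel and k % 2 == 1
            chains.append(make_helix_chain(cid, seq, origin, reverse, phase))
        else:
            width = max(2, min(5, int(math.ceil(math.sqrt(len(seq))))))
            gap = spec.separation - 6.0  # plane-to-plane distance
            if k == 0:
                origin = np.array([0.0, 0.0, 0.0])
            else:
                # centre the slab over the previous chain's grid
                prev_len = len(sequences[k - 1])
                prev_w = max(2, min(5, int(math.ceil(math.sqrt(prev_len)))))
                prev_rows = math.ceil(prev_len / prev_w)
                rows = math.ceil(len(seq) / width)
                origin = np.array(
                    [
                        4.0 * ((prev_w - width) // 2),
                        k * gap,
                        4.0 * ((prev_rows - rows) // 2),
                    ]
                )
            chains.append(
                make_lattice_chain(cid, seq, origin, width, flip=(k % 2 == 1))
            )
    structure = Structure("synthetic_complex", chains)

    if spec.n_chains > 1:
        min_d = _min_interchain_distance(structure)
        if min_d < CLASH_TOLERANCE:
            raise ValueError(
                f"infeasible geometry: chains clash (min distance {min_d:.2f} A)"
            )

    truth: dict[str, set[ResidueId]] = {}
    for cid in chain_ids:
        partners = [c for c in chain_ids if c != cid]
        if partners:
            side, _ = detect_interface(structure, cid, partners)
            truth[cid] = side
        else:
            truth[cid] = set()

    if spec.noise_sigma > 0:
        for res in structure.residues():
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(
                    0.0, spec.noise_sigma, size=3
                )
    return structure, truth


def _min_interchain_distance(structure: Structure) -> float:
    from scipy.spatial import cKDTree

    best = math.inf
    ids = structure.chain_ids()
    for i, a in enumerate(ids):
        ca, _ = structure.atom_array(chains=[a])
        for b in ids[i + 1:]:
            cb, _ = structure.atom_array(chains=[b])
            d, _ = cKDTree(cb).query(ca)
            best = min(best, float(d.min()))
    return best


def make_homolog_pool(
    query_seq: str,
    bin_occupancies: dict[float, int] | None = None,
    conserved_columns: set[int] | None = None,
    rng_seed: int = 0,
    query_id: str = "query",
) -> HomologPool:
    """Homologs at controlled identity levels with planted conserved columns.

    ``bin_occupancies`` maps a target percent identity to the number of
    homologs to generate at that level (realised identity within +-2%);
    default: six homologs in each of the four sampling bins. Columns in
    ``conserved_columns`` (1-based query positions) are never mutated.
    """
    if bin_occupancies is None:
        bin_occupancies = {30.0: 6, 50.0: 6, 70.0: 6, 89.0: 6}
    if any(v < 0 for v in bin_occupancies.values()):
        raise ValueError("occupancies must be >= 0")
    conserved0 = {c - 1 for c in (conserved_columns or set())}
    rng = np.random.default_rng(rng_seed)
    L = len(query_seq)
    mutable = sorted(set(range(L)) - conserved0)
    letters = sorted(ONE_TO_THREE)

    ids: list[str] = []
    seqs: list[str] = []
    count = 0
    for target in sorted(bin_occupancies):
        for _ in range(bin_occupancies[target]):
            n_mut = int(round(L * (1.0 - target / 100.0)))
            n_mut = min(n_mut, len(mutable))
            positions = rng.choice(mutable, size=n_mut, replace=False)
            seq = list(query_seq)
            for p in positions:
                alternatives = [a for a in letters if a != query_seq[p]]
                seq[p] = alternatives[rng.integers(len(alternatives))]
            count += 1
            ids.append(f"hom{count:03d}_id{int(target)}")
            seqs.append("".join(seq))
    return HomologPool(
        query_id=query_id,
        query_aligned=query_seq,
        homolog_ids=ids,
        homologs_aligned=seqs,
    )


def make_poses(
    structure: Structure,
    chain: str,
    hot_region: set[ResidueId],
    bias: float = 1.0,
    n_poses: int = 500,
    pose_interface_size: int = 10,
    n_partners: int = 4,
    rng_seed: int = 0,
    surface: SurfaceMap | None = None,
) -> DockingPoseSet:
    """Docking pose records biased towards a planted hot region.

    Each pose picks a contact centre with weight ``bias`` inside the hot
    region and 1 outside, and its docked interface is the spatially
    contiguous neighbourhood (the ``pose_interface_size`` nearest surface
    residues) of that centre -- docked interfaces are patches, not random
    residue sets. For ``bias > 1`` pose energies decrease with the fraction
    of the pose inside the hot region, so energy filtering enriches the
    signal; at ``bias = 1`` energies are independent of the region (null
    case).
    """
    if bias < 1:
        raise ValueError("bias must be >= 1")
    if surface is None:
        surface = compute_rasa(structure, context=[chain])
    surf = surface.surface_residues()
    if not set(hot_region) <= set(surf):
        raise ValueError("hot region must be part of the chain surface")
    rng = np.random.default_rng(rng_seed)
    weights = np.array([bias if r in hot_region else 1.0 for r in surf])
    probs = weights / weights.sum()
    size = min(pose_interface_size, len(surf))
    coupling = 4.0 if bias > 1 else 0.0
    centroids = np.array(
        [structure.get_residue(r).coords(heavy_only=True).mean(axis=0)
         for r in surf]
    )
    poses = []
    for i in range(n_poses):
        centre = rng.choice(len(surf), p=probs)
        dists = np.linalg.norm(centroids - centroids[centre], axis=1)
        picked = np.argsort(dists, kind="stable")[:size]
        iface = frozenset(surf[j] for j in picked)
        frac_hot = len(iface & hot_region) / size
        energy = -8.0 - coupling * frac_hot + rng.normal(0.0, 1.0)
        poses.append(
            DockingPose(
                pose_id=f"pose{i:05d}",
                partner_id=f"partner{i % n_partners}",
                energy=float(energy),
                interface=iface,
            )
        )
    return DockingPoseSet(protein_id=structure.id, poses=poses)
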