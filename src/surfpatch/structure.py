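"""Lightweight protein structure model.

Structures are parsed from PDB-format text (via gemmi) into a minimal
chain/residue/atom hierarchy keyed by author residue numbering. Only what the
surface/interface machinery needs is kept: names, elements and coordinates.
Heteroatoms are excluded by default (waters always); alternate locations are
resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ResidueId",
    "StructureFormatError",
    "read_structure",
    "write_pdb",
]

#: Backbone atom names used for superposition.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureFormatError(ValueError):
    """Raised when PDB input cannot be parsed into at least one chain."""


class ResidueId(NamedTuple):
    """Author residue identifier: chain id, residue number, insertion code."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # "A:42" or "A:42B"
        return f"{self.chain}:{self.number}{self.icode}"

    @classmethod
    def parse(cls, text: str) -> "ResidueId":
        chain, _, rest = text.partition(":")
        if not rest:
            raise ValueError(f"malformed residue id {text!r}")
        num = rest.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
        return cls(chain, int(num), rest[len(num):])


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: bad coordinates {self.coord}")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str  # 3-letter type
    atoms: list[Atom] = field(default_factory=list)

    @property
    def rid(self) -> ResidueId:
        return ResidueId(self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def heavy_atoms(self) -> Iterator[Atom]:
        return (a for a in self.atoms if a.element != "H")

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = list(self.heavy_atoms()) if heavy_only else self.atoms
        return np.array([a.coord for a in atoms], dtype=float)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[ResidueId] = set()
        for res in self.residues():
            if res.rid in seen:
                raise ValueError(f"duplicate residue id {res.rid}")
            seen.add(res.rid)
            if not res.atoms:
                raise ValueError(f"residue {res.rid} has no atoms")

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def residues(self, chains: Iterable[str] | None = None) -> Iterator[Residue]:
        wanted = set(chains) if chains is not None else None
        for c in self.chains:
            if wanted is None or c.id in wanted:
                yield from c.residues

    def get_residue(self, rid: ResidueId) -> Residue:
        for res in self.get_chain(rid.chain):
            if res.number == rid.number and res.icode == rid.icode:
                return res
        raise KeyError(f"no residue {rid}")

    def atom_array(
        self, chains: Iterable[str] | None = None, heavy_only: bool = False
    ) -> tuple[np.ndarray, list[tuple[ResidueId, Atom]]]:
        """Flat coordinate array plus parallel (residue id, atom) index."""
        coords: list[np.ndarray] = []
        index: list[tuple[ResidueId, Atom]] = []
        for res in self.residues(chains):
            atoms = res.heavy_atoms() if heavy_only else res.atoms
            for a in atoms:
                coords.append(a.coord)
                index.append((res.rid, a))
        if not coords:
            return np.empty((0, 3)), index
        return np.array(coords), index

    def subset(self, chains: Iterable[str]) -> "Structure":
        wanted = list(chains)
        return Structure(self.id, [c for c in self.chains if c.id in wanted])


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, then altloc order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ or (
            atom.occ == prev.occ and atom.altloc < prev.altloc
        ):
            best[atom.name] = atom
    # preserve file order of first appearance
    order = []
    seen = set()
    for atom in res:
        if atom.name not in seen:
            seen.add(atom.name)
            order.append(atom.name)
    return [best[name] for name in order]


def read_structure(
    pdb_source: str | os.PathLike,
    model_policy: str = "first",
    model_index: int = 0,
    include_het: bool = False,
) -> Structure:
    """Parse PDB-format input into a :class:`Structure`.

    ``pdb_source`` is a path, or PDB text itself if it contains a newline.
    ``model_policy`` is ``"first"`` or ``"index"`` (with ``model_index``).
    Waters are always dropped; other heteroatoms are dropped unless
    ``include_het``. Alternate locations resolve to the highest occupancy.
    """
    try:
        if isinstance(pdb_source, str) and "\n" in pdb_source:
            st = gemmi.read_pdb_string(pdb_source)
        else:
            st = gemmi.read_structure(os.fspath(pdb_source), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureFormatError(f"unparsable PDB input: {exc}") from exc

    if len(st) == 0:
        raise StructureFormatError("PDB input contains no model")
    if model_policy == "first":
        model = st[0]
    elif model_policy == "index":
        if model_index >= len(st):
            raise StructureFormatError(
                f"model index {model_index} out of range ({len(st)} models)"
            )
        model = st[model_index]
    else:
        raise ValueError(f"unknown model_policy {model_policy!r}")

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.is_water():
                continue
            if gres.het_flag == "H" and not include_het:
                continue
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name.upper(),
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                )
                for a in _resolve_altlocs(gres)
            ]
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(gchain.name, gres.seqid.num, icode, gres.name.strip(), atoms)
            )
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise StructureFormatError("PDB input contains no protein chain")
    name = st.name if st.name else "structure"
    return Structure(name, chains)


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resnum:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_pdb(structure: Structure, path: str | os.PathLike | None = None) -> str:
    """Serialize a :class:`Structure` to PDB-format text (and optionally a file)."""
    lines: list[str] = []
    serial = 1
    for chain in structure.chains:
        for res in chain:
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    _PDB_ATOM.format(
                        serial=serial,
                        name=name,
                        altloc=" ",
                        resname=res.name,
                        chain=chain.id[:1] or "A",
                        resnum=res.number,
                        icode=res.icode[:1] or " ",
                        x=atom.coord[0],
                        y=atom.coord[1],
                        z=atom.coord[2],
                        occ=atom.occupancy,
                        b=0.0,
                        element=atom.element[:2],
                    )
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.id[:1]}{chain.residues[-1].number:>4d}\n")
        serial += 1
    lines.append("END\n")
    text = "".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
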