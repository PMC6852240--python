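"""Interacting sites (IS) and interacting regions (IR).

An IS is the set of query-chain residues within 5 A of one partner group in
one complex structure; partners in mutual contact (< 5 A) form a single
group, so a site may represent a multi-partner interaction. Sites detected
on homolog structures are mapped back onto the query numbering through a
global pairwise alignment (BLOSUM62, gap open -10 / extend -0.5). Sites are
then merged into regions: two sites (or a site and an accumulated region)
merge when their maximum mutual overlap,

    max(|A & B| / |A|, |A & B| / |B|),

exceeds 60% (strict), relaxed for very small sites (<= 5 residues) to
sharing at least one residue. Merging iterates to a fixpoint; regions of
five residues or fewer are dropped at the end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .interface import detect_interface
from .sasa import SurfaceMap
from .structure import ResidueId, Structure

__all__ = [
    "InteractingSite",
    "InteractingRegion",
    "partner_grouping",
    "map_site",
    "overlap_fraction",
    "merge_regions",
    "global_alignment_identity",
]

OVERLAP_THRESHOLD = 0.60
SMALL_SITE_SIZE = 5
MIN_REGION_SIZE = 5  # strictly more than 5 residues are retained


@dataclass(frozen=True)
class InteractingSite:
    query_chain: str
    residues: frozenset[ResidueId]
    source: str = ""  # e.g. PDB id of the complex
    partner_chains: tuple[str, ...] = ()

    @property
    def multi_partner(self) -> bool:
        return len(self.partner_chains) > 1

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class InteractingRegion:
    residues: frozenset[ResidueId]
    members: list[InteractingSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


def partner_grouping(
    complex_structure: Structure,
    query_chain: str,
    cutoff: float = 5.0,
    source: str = "",
    surface: SurfaceMap | None = None,
) -> list[InteractingSite]:
    """One IS per transitive contact group of partner chains.

    Partners of the query that touch each other (< cutoff) belong to one
    group and produce one multi-partner site; disconnected partners give
    separate single-partner sites.
    """
    partner_ids = [c for c in complex_structure.chain_ids() if c != query_chain]
    if not partner_ids:
        raise ValueError("complex must contain at least one partner chain")
    contact = nx.Graph()
    contact.add_nodes_from(partner_ids)
    for i, a in enumerate(partner_ids):
        for b in partner_ids[i + 1:]:
            side_a, _ = detect_interface(
                complex_structure, a, [b], cutoff=cutoff,
                restrict_to_surface=False,
            )
            if side_a:
                contact.add_edge(a, b)
    sites: list[InteractingSite] = []
    for group in sorted(nx.connected_components(contact), key=sorted):
        group = sorted(group)
        res, _ = detect_interface(
            complex_structure, query_chain, group, cutoff=cutoff,
            surface_a=surface,
        )
        if res:
            sites.append(
                InteractingSite(
                    query_chain=query_chain,
                    residues=frozenset(res),
                    source=source or complex_structure.id,
                    partner_chains=tuple(group),
                )
            )
    return sites


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _position_map(seq_a: str, seq_b: str) -> tuple[dict[int, int], float]:
    """0-based position map a->b from the best global alignment, plus the
    percent identity over the aligned length."""
    alignment = _aligner().align(seq_a, seq_b)[0]
    mapping: dict[int, int] = {}
    matches = 0
    length = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for off in range(a1 - a0):
            mapping[a0 + off] = b0 + off
            length += 1
            if seq_a[a0 + off] == seq_b[b0 + off]:
                matches += 1
    aligned_len = max(len(seq_a), len(seq_b))
    identity = 100.0 * matches / aligned_len if aligned_len else 0.0
    return mapping, identity


def global_alignment_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the global alignment, over the longer sequence."""
    _, identity = _position_map(seq_a, seq_b)
    return identity


def map_site(
    site: InteractingSite,
    homolog_residues: list[ResidueId],
    homolog_seq: str,
    query_residues: list[ResidueId],
    query_seq: str,
    query_chain: str | None = None,
    identity_warning: float = 90.0,
) -> InteractingSite:
    """Map a site from homolog numbering onto the query chain numbering.

    ``homolog_residues``/``query_residues`` list the residue ids in sequence
    order. Site residues aligned to gaps are dropped. A pair below the
    homolog-identity criterion (default 90%) is still mapped, with a warning.
    """
    if len(homolog_residues) != len(homolog_seq):
        raise ValueError("homolog residue list and sequence length differ")
    if len(query_residues) != len(query_seq):
        raise ValueError("query residue list and sequence length differ")
    mapping, identity = _position_map(homolog_seq, query_seq)
    if identity < identity_warning:
        warnings.warn(
            f"mapped pair identity {identity:.1f}% below "
            f"{identity_warning:.0f}%; outside the close-homolog criterion"
        )
    pos_of = {rid: i for i, rid in enumerate(homolog_residues)}
    mapped: set[ResidueId] = set()
    for rid in site.residues:
        i = pos_of.get(rid)
        if i is None or i not in mapping:
            continue  # unmapped or aligned to a gap: dropped
        mapped.add(query_residues[mapping[i]])
    return InteractingSite(
        query_chain=query_chain or (query_residues[0].chain if query_residues else ""),
        residues=frozenset(mapped),
        source=site.source,
        partner_chains=site.partner_chains,
    )


def overlap_fraction(a: frozenset, b: frozenset) -> float:
    """max(|A & B|/|A|, |A & B|/|B|)."""
    if not a or not b:
        raise ValueError("overlap of an empty site is undefined")
    inter = len(a & b)
    return max(inter / len(a), inter / len(b))


def _mergeable(
    a: frozenset,
    b: frozenset,
    threshold: float,
    small_size: int,
) -> bool:
    if min(len(a), len(b)) <= small_size:
        return len(a & b) >= 1
    return overlap_fraction(a, b) > threshold


def _canonical_key(residues: frozenset[ResidueId]) -> tuple:
    return (-len(residues), sorted((r.chain, r.number, r.icode) for r in residues))


def merge_regions(
    sites: list[InteractingSite],
    overlap_threshold: float = OVERLAP_THRESHOLD,
    small_site_size: int = SMALL_SITE_SIZE,
    min_region_size: int = MIN_REGION_SIZE,
) -> list[InteractingRegion]:
    """Agglomerative closure of the site-merging rule.

    Regions accumulate member sites; overlap tests after a merge use the
    region union. Processing order is canonical (size descending, then
    lexicographically smallest residue) so the result does not depend on the
    input permutation. Regions with ``min_region_size`` residues or fewer
    are dropped after the fixpoint.
    """
    regions = [
        InteractingRegion(residues=s.residues, members=[s]) for s in sites
    ]
    changed = True
    while changed:
        changed = False
        regions.sort(key=lambda r: _canonical_key(r.residues))
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if _mergeable(
                    regions[i].residues,
                    regions[j].residues,
                    overlap_threshold,
                    small_site_size,
                ):
                    merged = InteractingRegion(
                        residues=regions[i].residues | regions[j].residues,
                        members=regions[i].members + regions[j].members,
                    )
                    regions = [
                        r for k, r in enumerate(regions) if k not in (i, j)
                    ]
                    regions.append(merged)
                    changed = True
                    break
            if changed:
                break
    kept = [r for r in regions if len(r) > min_region_size]
    kept.sort(key=lambda r: _canonical_key(r.residues))
    return kept
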