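"""Desk-scale worked examples on real PDB entries (network required).

Two small demonstrations of interacting-site extraction and region merging
on experimental structures:

* trypsin: the query chain 1ezx_C binds serpin (1ezx), another trypsin copy
  (5gxp) and eglin C (4b2b); the three interacting sites, mapped onto the
  1ezx_C numbering, merge into two interacting regions.
* natriuretic peptide receptor: within the 1yk1 assembly the monomer
  1yk1_A carries two interacting sites (the dimerisation partner B and the
  peptide substrate E).

Run:  python scripts/worked_examples.py [--pdb-dir DIR]

Files are looked up as <DIR>/<code>.pdb and downloaded from the RCSB when
absent (requires network access).
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

from surfpatch.regions import map_site, merge_regions, partner_grouping
from surfpatch.structure import read_structure

RCSB_URL = "https://files.rcsb.org/download/{code}.pdb"

TRYPSIN_COMPLEXES = (
    # (pdb code, query chain carrying trypsin, partner chains)
    ("1ezx", "C", ("A", "B")),
    ("5gxp", "A", ("B",)),
    ("4b2b", "A", ("B",)),
)
RECEPTOR_CODE = "1yk1"
RECEPTOR_CHAIN = "A"


def fetch_pdb(code: str, pdb_dir: Path, timeout: float = 10.0) -> Path:
    path = pdb_dir / f"{code}.pdb"
    if path.exists():
        return path
    pdb_dir.mkdir(parents=True, exist_ok=True)
    url = RCSB_URL.format(code=code.upper())
    with urllib.request.urlopen(url, timeout=timeout) as response:
        path.write_bytes(response.read())
    return path


def _chain_sequence(structure, chain_id):
    chain = structure.get_chain(chain_id)
    return chain.sequence(), [r.rid for r in chain]


def trypsin_interacting_regions(pdb_dir: Path):
    """Interacting sites of trypsin from its three complexes, mapped onto
    1ezx_C and merged into regions."""
    query_structure = read_structure(fetch_pdb("1ezx", pdb_dir))
    query_seq, query_rids = _chain_sequence(query_structure, "C")
    sites = []
    for code, chain, partners in TRYPSIN_COMPLEXES:
        structure = read_structure(fetch_pdb(code, pdb_dir))
        keep = [chain] + [p for p in partners if p in structure.chain_ids()]
        complex_structure = structure.subset(keep)
        for site in partner_grouping(complex_structure, chain, source=code):
            if code == "1ezx":
                sites.append(site)
            else:
                hom_seq, hom_rids = _chain_sequence(structure, chain)
                sites.append(
                    map_site(site, hom_rids, hom_seq, query_rids, query_seq,
                             query_chain="C")
                )
    regions = merge_regions(sites)
    return sites, regions


def receptor_interacting_sites(pdb_dir: Path):
    """Interacting sites on the natriuretic peptide receptor monomer within
    its assembly."""
    structure = read_structure(fetch_pdb(RECEPTOR_CODE, pdb_dir))
    return partner_grouping(structure, RECEPTOR_CHAIN)


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb-dir", type=Path,
                        default=Path("scratch/worked_examples"))
    args = parser.parse_args(argv)

    sites, regions = trypsin_interacting_regions(args.pdb_dir)
    print(f"trypsin (1ezx_C): {len(sites)} interacting sites "
          f"-> {len(regions)} interacting regions")
    for i, region in enumerate(regions):
        members = ", ".join(s.source for s in region.members)
        print(f"  region {i}: {len(region)} residues (from {members})")

    receptor_sites = receptor_interacting_sites(args.pdb_dir)
    print(f"receptor ({RECEPTOR_CODE}_{RECEPTOR_CHAIN}): "
          f"{len(receptor_sites)} interacting sites")
    for site in receptor_sites:
        print(f"  partners {site.partner_chains}: {len(site)} residues")
    return 0


if __name__ == "__main__":
    sys.exit(main())
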