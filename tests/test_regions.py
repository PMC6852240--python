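import numpy as np
import pytest

from surfpatch.fixtures import make_lattice_chain
from surfpatch.regions import (
    InteractingSite,
    map_site,
    merge_regions,
    overlap_fraction,
    partner_grouping,
)
from surfpatch.interface import detect_interface
from surfpatch.structure import Chain, ResidueId, Structure


def _site(numbers, chain="A", source="s"):
    return InteractingSite(
        query_chain=chain,
        residues=frozenset(ResidueId(chain, n, "") for n in numbers),
        source=source,
    )


class TestOverlapFraction:
    def test_mutual_maximum_convention(self):
        a = _site(range(1, 11)).residues
        b = _site(range(4, 14)).residues
        assert overlap_fraction(a, b) == pytest.approx(0.7)

    def test_disjoint_sites(self):
        assert overlap_fraction(_site([1, 2]).residues, _site([5]).residues) == 0.0

    def test_contained_site_overlaps_fully(self):
        big = _site(range(1, 21)).residues
        small = _site(range(5, 10)).residues
        assert overlap_fraction(big, small) == 1.0

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction(frozenset(), _site([1]).residues)


def _grouping_structure(partner_c_rows):
    """Slab A (5x8) with two 3x3 partner slabs above it; the z placement of
    partner C controls whether B and C touch each other."""
    rng_seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
    a = make_lattice_chain("A", rng_seq[:40], np.array([0.0, 0.0, 0.0]))
    b = make_lattice_chain(
        "B", "AAAAAAAAA", np.array([0.0, 7.0, 0.0]), width=3, flip=True
    )
    c = make_lattice_chain(
        "C", "AAAAAAAAA", np.array([0.0, 7.0, partner_c_rows * 4.0]),
        width=3, flip=True,
    )
    return Structure("grouping", [Chain("A", a.residues),
                                  Chain("B", b.residues),
                                  Chain("C", c.residues)])


class TestPartnerGrouping:
    def test_separated_partners_give_two_single_partner_sites(self):
        st = _grouping_structure(partner_c_rows=5)  # B-C gap 8 A
        sites = partner_grouping(st, "A")
        assert len(sites) == 2
        assert all(not s.multi_partner for s in sites)
        assert {s.partner_chains for s in sites} == {("B",), ("C",)}

    def test_touching_partners_give_one_multi_partner_site(self):
        st = _grouping_structure(partner_c_rows=3)  # B-C gap 4 A
        sites = partner_grouping(st, "A")
        assert len(sites) == 1
        assert sites[0].multi_partner
        assert sites[0].partner_chains == ("B", "C")

    def test_single_partner_reduces_to_interface_detection(
        self, lattice_complex, lattice_surface_a
    ):
        structure, _ = lattice_complex
        (site,) = partner_grouping(
            structure, "A", surface=lattice_surface_a
        )
        expected, _ = detect_interface(
            structure, "A", ["B"], surface_a=lattice_surface_a
        )
        assert site.residues == expected


QUERY = "ACDEFGHIKLMNPQRSTVWY"


def _rids(chain, n):
    return [ResidueId(chain, i + 1, "") for i in range(n)]


class TestSiteMapping:
    def test_identical_sequences_map_identically(self):
        site = _site([3, 4, 5], chain="H")
        mapped = map_site(
            site, _rids("H", 20), QUERY, _rids("A", 20), QUERY,
            query_chain="A",
        )
        assert mapped.residues == frozenset(
            ResidueId("A", n, "") for n in (3, 4, 5)
        )

    def test_insertion_before_site_shifts_mapping(self):
        homolog = QUERY[:4] + "GG" + QUERY[4:]  # insertion after position 4
        site = _site([10, 11, 12], chain="H")  # homolog numbering
        mapped = map_site(
            site, _rids("H", len(homolog)), homolog, _rids("A", 20), QUERY,
            query_chain="A",
        )
        assert mapped.residues == frozenset(
            ResidueId("A", n, "") for n in (8, 9, 10)
        )

    def test_site_residues_aligned_to_gaps_are_dropped(self):
        # homolog has one extra residue at position 11: it aligns to a gap
        # in the query, so a site containing it loses that residue
        homolog = QUERY[:10] + "W" + QUERY[10:]
        site = _site([10, 11, 12], chain="H")
        mapped = map_site(
            site, _rids("H", len(homolog)), homolog, _rids("A", 20),
            QUERY, query_chain="A",
        )
        assert mapped.residues == frozenset(
            ResidueId("A", n, "") for n in (10, 11)
        )


from oracles import closure_oracle  # noqa: E402


class TestMergeRegions:
    def test_seven_of_ten_overlap_merges(self):
        regions = merge_regions([_site(range(1, 11)), _site(range(4, 14))])
        assert len(regions) == 1
        assert len(regions[0]) == 13

    def test_exactly_sixty_percent_does_not_merge(self):
        a = _site(range(1, 11))
        b = _site(list(range(5, 11)) + [20, 21, 22, 23])  # overlap 6/10
        regions = merge_regions([a, b])
        assert len(regions) == 2

    def test_small_site_merges_on_single_shared_residue(self):
        small = _site([5, 6, 7, 8])  # four residues
        big = _site(range(8, 28))
        regions = merge_regions([small, big])
        assert len(regions) == 1
        assert regions[0].residues == small.residues | big.residues

    def test_small_regions_dropped_after_fixpoint(self):
        regions = merge_regions([_site([1, 2, 3]), _site([10, 11, 12, 13, 14])])
        assert regions == []

    def test_region_is_union_of_members(self):
        sites = [_site(range(1, 11)), _site(range(4, 14)), _site([30, 31, 32,
                                                                  33, 34, 35])]
        for region in merge_regions(sites):
            assert region.residues == frozenset().union(
                *(m.residues for m in region.members)
            )
            assert len(region.members) >= 1

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        sites = [
            _site(rng.choice(30, size=rng.integers(2, 13), replace=False) + 1)
            for _ in range(10)
        ]
        once = merge_regions(sites)
        again = merge_regions(
            [InteractingSite("A", r.residues) for r in once]
        )
        assert [r.residues for r in again] == [r.residues for r in once]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        sites = [
            _site(rng.choice(25, size=rng.integers(2, 12), replace=False) + 1)
            for _ in range(9)
        ]
        expected = [r.residues for r in merge_regions(sites)]
        for _ in range(5):
            perm = [sites[k] for k in rng.permutation(len(sites))]
            assert [r.residues for r in merge_regions(perm)] == expected

    def test_matches_brute_force_closure_on_random_instances(self):
        rng = np.random.default_rng(2023)
        for _ in range(200):
            n_sites = int(rng.integers(2, 13))
            sites = [
                _site(
                    rng.choice(28, size=int(rng.integers(1, 13)),
                               replace=False) + 1
                )
                for _ in range(n_sites)
            ]
            got = [r.residues for r in merge_regions(sites)]
            assert sorted(got, key=lambda s: (-len(s), sorted(s))) == \
                closure_oracle([s.residues for s in sites])
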