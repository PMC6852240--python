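import networkx as nx
import numpy as np
import pytest

from surfpatch.conservation import (
    HomologPool,
    TraceTree,
    compute_conservation,
    compute_tjet,
    distance_matrix,
    midpoint_root,
    nj_tree,
    sample_subsets,
    trace_levels,
)


def _pool(identities, length=24):
    seqs = ["A" * length for _ in identities]
    return HomologPool(
        query_id="Q",
        query_aligned="A" * length,
        homolog_ids=[f"h{i}" for i in range(len(identities))],
        homologs_aligned=seqs,
        identities=list(identities),
    )


class TestSubsetSampling:
    def test_equal_quarters_when_every_bin_is_ample(self):
        identities = [30.0] * 10 + [50.0] * 10 + [70.0] * 10 + [90.0] * 10
        pool = _pool(identities)
        subsets = sample_subsets(pool, n_subsets=5, subset_size=8, rng_seed=1)
        for subset in subsets:
            assert len(subset) == 8
            bins = [sum(1 for i in subset if lo <= pool.identities[i] < hi)
                    for lo, hi in ((20, 40), (40, 60), (60, 80), (80, 98.01))]
            assert bins == [2, 2, 2, 2]

    def test_deficit_redistributed_to_other_bins(self):
        identities = [30.0] * 1 + [50.0] * 20 + [70.0] * 20 + [90.0] * 20
        pool = _pool(identities)
        (subset,) = sample_subsets(pool, n_subsets=1, subset_size=12, rng_seed=0)
        assert len(subset) == 12
        assert sum(1 for i in subset if pool.identities[i] < 40) == 1

    def test_single_bin_pool_draws_from_that_bin_only(self):
        pool = _pool([30.0] * 12)
        (subset,) = sample_subsets(pool, n_subsets=1, subset_size=6, rng_seed=0)
        assert len(subset) == 6

    def test_sequences_outside_identity_range_excluded(self):
        pool = _pool([10.0, 99.5, 30.0, 30.0, 30.0, 30.0, 30.0])
        with pytest.warns(UserWarning):
            (subset,) = sample_subsets(pool, subset_size=10, rng_seed=0)
        assert 0 not in subset and 1 not in subset

    def test_small_pool_returns_whole_pool_with_warning(self):
        pool = _pool([30.0, 50.0, 70.0])
        with pytest.warns(UserWarning, match="whole pool"):
            subsets = sample_subsets(pool, n_subsets=3, subset_size=10)
        assert subsets == [[0, 1, 2]]

    def test_same_seed_identical_subsets(self):
        identities = [30.0] * 8 + [50.0] * 8 + [70.0] * 8 + [90.0] * 8
        pool = _pool(identities)
        a = sample_subsets(pool, 4, 8, rng_seed=42)
        b = sample_subsets(pool, 4, 8, rng_seed=42)
        assert a == b


class TestDistanceMatrix:
    def test_identical_sequences_have_zero_distance(self):
        d = distance_matrix(["ACGT", "ACGT"])
        assert d[0, 1] == 0.0

    def test_single_mismatch_fraction(self):
        d = distance_matrix(["AAAA", "AATA"])
        assert d[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded(self):
        d = distance_matrix(["A-CG", "AACG"])
        assert d[0, 1] == 0.0  # 0 mismatches over 3 comparable columns

    def test_no_comparable_columns_raises(self):
        with pytest.raises(ValueError, match="gap-free"):
            distance_matrix(["A--", "-AA"])


from oracles import random_additive_tree as _random_additive_tree  # noqa: E402
from oracles import tree_splits as _splits  # noqa: E402


class TestNeighborJoining:
    def test_two_taxa_single_edge_halved_by_midpoint(self):
        tree = nj_tree(np.array([[0.0, 0.8], [0.8, 0.0]]), ["a", "b"])
        assert tree["a"]["b"]["length"] == pytest.approx(0.8)
        root, rooted = midpoint_root(tree)
        assert set(rooted.successors(root)) == {"a", "b"}
        assert rooted[root]["a"]["length"] == pytest.approx(0.4)

    def test_three_taxa_closed_form_branch_lengths(self):
        # d_ab=0.4, d_ac=0.6, d_bc=0.8 -> la=(dab+dac-dbc)/2=0.1,
        # lb=dab-la=0.3, lc=dac-la=0.5
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(d, ["a", "b", "c"])
        (hub,) = [n for n in tree if tree.degree(n) == 3]
        assert tree["a"][hub]["length"] == pytest.approx(0.1)
        assert tree["b"][hub]["length"] == pytest.approx(0.3)
        assert tree["c"][hub]["length"] == pytest.approx(0.5)

    def test_four_taxa_additive_matrix_recovers_topology(self):
        rng = np.random.default_rng(5)
        names, d, splits = _random_additive_tree(rng, 4)
        assert _splits(nj_tree(d, names)) == splits

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            names, d, splits = _random_additive_tree(rng, n)
            assert _splits(nj_tree(d, names)) == splits

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(np.array([[0.0, 1.0], [0.5, 0.0]]), ["a", "b"])


def _quartet_tree():
    # ((A,B),(C,D)) with the root on the central edge by midpoint
    g = nx.Graph()
    g.add_edge("A", "u", length=1.0)
    g.add_edge("B", "u", length=1.0)
    g.add_edge("C", "v", length=1.0)
    g.add_edge("D", "v", length=1.0)
    g.add_edge("u", "v", length=2.0)
    return g


class TestTraceLevels:
    def test_fully_conserved_column_traces_to_root(self):
        aligned = {"A": "W", "B": "W", "C": "W", "D": "W"}
        trace = trace_levels(_quartet_tree(), aligned, "A")
        assert trace.levels[1] == 0

    def test_query_only_column_has_no_trace(self):
        aligned = {"A": "W", "B": "F", "C": "F", "D": "F"}
        trace = trace_levels(_quartet_tree(), aligned, "A")
        assert trace.levels[1] is None

    def test_clade_conservation_matches_exhaustive_node_search(self):
        aligned = {"A": "W", "B": "W", "C": "F", "D": "F"}
        tree = _quartet_tree()
        trace = trace_levels(tree, aligned, "A")
        # oracle: shallowest ancestor of A whose leaf set is all-W
        root, rooted = midpoint_root(tree)
        depth = nx.shortest_path_length(rooted, root)
        best = None
        for node in rooted:
            if not list(rooted.successors(node)):
                continue
            below = {
                leaf for leaf in nx.descendants(rooted, node)
                if not list(rooted.successors(leaf))
            }
            on_query_path = node in nx.shortest_path(rooted, root, "A")
            if on_query_path and all(aligned[l] == "W" for l in below):
                if best is None or depth[node] < best:
                    best = depth[node]
        assert trace.levels[1] == best == 1

    def test_missing_query_leaf_raises(self):
        with pytest.raises(ValueError, match="query"):
            trace_levels(_quartet_tree(), {"A": "W"}, "Z")


def _trace(max_level, level):
    return TraceTree(root=None, rooted=nx.DiGraph(), max_level=max_level,
                     levels={1: level})


class TestTjet:
    def test_root_level_in_all_trees_scores_one(self):
        df = compute_tjet([_trace(3, 0), _trace(5, 0)])
        assert df.loc[1, "tjet"] == pytest.approx(1.0)

    def test_max_level_in_all_trees_scores_zero(self):
        df = compute_tjet([_trace(3, 3), _trace(5, 5)])
        assert df.loc[1, "tjet"] == pytest.approx(0.0)

    def test_mixed_tree_average(self):
        df = compute_tjet([_trace(4, 2), _trace(2, 1)])
        assert df.loc[1, "tjet"] == pytest.approx(0.5)
        assert df.loc[1, "m"] == 2

    def test_no_trace_trees_excluded_from_average(self):
        df = compute_tjet([_trace(4, 0), _trace(4, None)])
        assert df.loc[1, "tjet"] == pytest.approx(1.0)
        assert df.loc[1, "m"] == 1

    def test_all_no_trace_scores_zero(self):
        df = compute_tjet([_trace(4, None)])
        assert df.loc[1, "tjet"] == 0.0
        assert df.loc[1, "m"] == 0


def test_pipeline_bounds_and_determinism():
    from surfpatch.fixtures import make_homolog_pool

    pool = make_homolog_pool(
        "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY",
        conserved_columns={5, 6, 7, 8},
        rng_seed=3,
    )
    a = compute_conservation(pool, rng_seed=11)
    b = compute_conservation(pool, rng_seed=11)
    assert a.equals(b)
    assert ((a["tjet"] >= 0) & (a["tjet"] <= 1)).all()
    # planted conserved columns dominate the score
    planted = a.loc[[5, 6, 7, 8], "tjet"]
    assert planted.min() >= a["tjet"].drop([5, 6, 7, 8]).mean()
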