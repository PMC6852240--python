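import numpy as np
import pandas as pd
import pytest

from surfpatch.patches import (
    STRATEGIES,
    StrategySpec,
    detect_seeds,
    grow_patch,
    predict_patches,
    residue_contact_graph,
)
from surfpatch.structure import ResidueId


def _score_table(surface_map, **columns):
    idx = surface_map.table.index[surface_map.table["surface"]]
    base = surface_map.table.loc[idx, ["chain", "resnum", "icode", "restype"]]
    for name, values in columns.items():
        base[name] = pd.Series(values).reindex(idx)
    return base.copy()


@pytest.fixture()
def gradient_table(lattice_complex, lattice_surface_a):
    """All four scores decay smoothly with distance from residue A:18."""
    structure, _ = lattice_complex
    centre = structure.get_residue(ResidueId("A", 18, "")).coords().mean(axis=0)
    scores = {}
    for res in structure.get_chain("A"):
        d = np.linalg.norm(res.coords().mean(axis=0) - centre)
        scores[str(res.rid)] = float(np.exp(-d / 6.0))
    return _score_table(
        lattice_surface_a, tjet=scores, pc=scores, cv=scores, nip=scores
    )


class TestSeedDetection:
    def _table(self, lattice_surface_a, high):
        idx = lattice_surface_a.table.index
        tjet = {i: (0.95 if i in high else 0.05) for i in idx}
        flat = {i: 0.5 for i in idx}
        return _score_table(
            lattice_surface_a, tjet=tjet, pc=flat, cv=flat, nip=flat
        )

    def test_planted_contiguous_cluster_found(
        self, lattice_complex, lattice_surface_a
    ):
        structure, _ = lattice_complex
        high = {"A:12", "A:13", "A:14", "A:17", "A:18"}
        table = self._table(lattice_surface_a, high)
        seeds = detect_seeds(table, STRATEGIES["SC_cons"], structure)
        assert len(seeds) == 1
        assert {str(r) for r in seeds[0]} == high

    def test_clusters_within_contact_distance_merge(
        self, lattice_complex, lattice_surface_a
    ):
        structure, _ = lattice_complex
        # columns 0-1 and column 2 of the grid: 4 A apart -> one seed
        close = {"A:1", "A:2", "A:6", "A:7", "A:3", "A:8"}
        table = self._table(lattice_surface_a, close)
        assert len(detect_seeds(table, STRATEGIES["SC_cons"], structure)) == 1
        # columns 0-1 and column 3: 8 A apart -> two seeds
        apart = {"A:1", "A:2", "A:6", "A:7", "A:4", "A:9", "A:5", "A:10"}
        table = self._table(lattice_surface_a, apart)
        assert len(detect_seeds(table, STRATEGIES["SC_cons"], structure)) == 2

    def test_clusters_below_three_residues_discarded(
        self, lattice_complex, lattice_surface_a
    ):
        structure, _ = lattice_complex
        table = self._table(lattice_surface_a, {"A:1", "A:2", "A:40"})
        seeds = detect_seeds(table, STRATEGIES["SC_cons"], structure)
        assert seeds == []

    def test_uniform_scores_give_no_seed(
        self, lattice_complex, lattice_surface_a
    ):
        structure, _ = lattice_complex
        table = self._table(lattice_surface_a, set())
        table["tjet"] = 0.4
        assert detect_seeds(table, STRATEGIES["SC_cons"], structure) == []


class TestPatchGrowth:
    def test_gradient_patch_is_connected_neighbourhood_of_centre(
        self, lattice_complex, gradient_table
    ):
        structure, _ = lattice_complex
        spec = STRATEGIES["SC_cons"]
        (seed,) = detect_seeds(gradient_table, spec, structure)
        patch = grow_patch(seed, gradient_table, spec, structure)
        assert ResidueId("A", 18, "") in patch.residues
        rids = [ResidueId.parse(i) for i in gradient_table.index]
        adj = residue_contact_graph(structure, rids)
        # connectivity: breadth-first reachability inside the patch
        members = set(patch.seed | patch.extension)
        start = next(iter(members))
        reached, stack = {start}, [start]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb in members and nb not in reached:
                    reached.add(nb)
                    stack.append(nb)
        assert reached == members

    def test_signal_fades_from_seed_to_outer(
        self, lattice_complex, gradient_table
    ):
        structure, _ = lattice_complex
        spec = STRATEGIES["SC_cons"]
        (seed,) = detect_seeds(gradient_table, spec, structure)
        patch = grow_patch(seed, gradient_table, spec, structure)
        score = gradient_table["tjet"]

        def mean_of(layer):
            return np.mean([score[str(r)] for r in layer]) if layer else 0.0

        assert mean_of(patch.seed) >= mean_of(patch.extension)
        if patch.outer:
            assert mean_of(patch.extension) >= mean_of(patch.outer)

    def test_target_below_seed_size_warns(self, lattice_complex, gradient_table):
        structure, _ = lattice_complex
        spec = STRATEGIES["SC_cons"]
        (seed,) = detect_seeds(gradient_table, spec, structure)
        with pytest.warns(UserWarning, match="target patch size"):
            patch = grow_patch(
                seed, gradient_table, spec, structure, target_size=1
            )
        assert patch.extension == frozenset()

    def test_quantile_ordering_enforced_at_spec_construction(self):
        with pytest.raises(ValueError, match="seed > extension > outer"):
            StrategySpec("bad", ("tjet",), ("tjet",), ("tjet",),
                         seed_quantile=0.5, ext_quantile=0.6)


class TestIterativeConsensus:
    def test_hit_threshold(self, lattice_complex, gradient_table):
        structure, _ = lattice_complex
        extra = ResidueId("A", 36, "")  # far corner residue

        def rescore(iteration, rng):
            table = gradient_table.copy()
            if iteration == 0:  # plant a one-iteration-only cluster
                for rid in ("A:36", "A:37", "A:31", "A:32"):
                    table.loc[rid, "tjet"] = 0.99
            return table

        result = predict_patches(
            gradient_table, "SC_cons", structure, n_iter=10, min_hits=2,
            rng_seed=0, rescore=rescore,
        )
        assert extra not in result.predicted  # detected once: excluded
        assert ResidueId("A", 18, "") in result.predicted  # detected 10x

    def test_two_hits_suffice(self, lattice_complex, gradient_table):
        structure, _ = lattice_complex

        def rescore(iteration, rng):
            table = gradient_table.copy()
            if iteration in (0, 5):
                for rid in ("A:36", "A:37", "A:31", "A:32"):
                    table.loc[rid, "tjet"] = 0.99
            return table

        result = predict_patches(
            gradient_table, "SC_cons", structure, n_iter=10, min_hits=2,
            rng_seed=0, rescore=rescore,
        )
        assert ResidueId("A", 36, "") in result.predicted

    def test_fixed_seed_reproducible(self, lattice_complex, gradient_table):
        structure, _ = lattice_complex
        a = predict_patches(gradient_table, "SC_dock", structure, rng_seed=7)
        b = predict_patches(gradient_table, "SC_dock", structure, rng_seed=7)
        assert [p.residues for p in a.patches] == [p.residues for p in b.patches]
        assert [p.hits for p in a.patches] == [p.hits for p in b.patches]

    def test_all_predicted_residues_are_surface_residues(
        self, lattice_complex, gradient_table, lattice_surface_a
    ):
        structure, _ = lattice_complex
        result = predict_patches(gradient_table, "SC_geom", structure)
        surface = set(lattice_surface_a.surface_residues())
        assert result.predicted <= surface


class TestStrategyIsolation:
    def _poison(self, table, columns, seed=9):
        rng = np.random.default_rng(seed)
        out = table.copy()
        for col in columns:
            out[col] = rng.uniform(0, 1, size=len(out))
        return out

    def test_geometry_strategy_ignores_conservation_and_docking(
        self, lattice_complex, gradient_table
    ):
        structure, _ = lattice_complex
        clean = predict_patches(gradient_table, "SC_geom", structure)
        poisoned = predict_patches(
            self._poison(gradient_table, ["tjet", "nip"]), "SC_geom", structure
        )
        assert [p.residues for p in clean.patches] == [
            p.residues for p in poisoned.patches
        ]

    def test_docking_strategy_ignores_all_other_scores(
        self, lattice_complex, gradient_table
    ):
        structure, _ = lattice_complex
        clean = predict_patches(gradient_table, "SC_dock", structure)
        poisoned = predict_patches(
            self._poison(gradient_table, ["tjet", "pc", "cv"]),
            "SC_dock", structure,
        )
        assert [p.residues for p in clean.patches] == [
            p.residues for p in poisoned.patches
        ]
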