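"""Richness, redundancy, Faith's PD and RPD against independent oracles."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

from cwr_phylospace.errors import DataError
from cwr_phylospace.occurrences import GridDomain, PresenceMatrix, build_presence_matrix
from cwr_phylospace.phylotree import build_tip_path_index, comparison_tree, parse_newick
from cwr_phylospace.spatial_phylo import (
    compute_all_cells,
    faith_pd,
    redundancy,
    richness,
    rpd,
)
from cwr_phylospace.synthetic_data import SyntheticConfig, make_tree


def brute_force_pd(tree, species) -> float:
    """Independent PD oracle: walk each tip to the root collecting edge
    objects, then sum the lengths of the union."""
    if not species:
        return 0.0
    dtree = tree.dendropy_tree
    edges = {}
    for leaf in dtree.leaf_node_iter():
        if str(leaf.taxon.label) not in species:
            continue
        node = leaf
        while node.parent_node is not None:
            edges[id(node.edge)] = node.edge.length
            node = node.parent_node
    return float(sum(edges.values()))


def all_subsets(items):
    return chain.from_iterable(combinations(items, k) for k in range(len(items) + 1))


class TestRichnessRedundancy:
    def test_richness_counts_unique(self):
        assert richness(["A", "A", "B"]) == 2
        assert richness(np.array([1, 0, 1, 1])) == 3
        assert richness(set()) == 0

    def test_redundancy_values(self):
        assert redundancy(5, 5) == 0.0  # every sample a new species
        assert redundancy(1, 10) == pytest.approx(0.9)

    def test_redundancy_requires_samples(self):
        with pytest.raises(DataError):
            redundancy(0, 0)

    def test_redundancy_bounds_and_monotonicity(self):
        # in [0, 1], decreasing in SR at fixed N
        for n in (1, 3, 10, 50):
            values = [redundancy(sr, n) for sr in range(1, n + 1)]
            assert all(0.0 <= v <= 1.0 for v in values)
            assert values == sorted(values, reverse=True)


class TestFaithPD:
    def test_hand_worked_four_tip_values(self, four_tip_tree):
        index = build_tip_path_index(four_tip_tree)
        # ((A:1,B:1):2,(C:3,D:1):1): {A,B} spans A, B and their stem
        assert faith_pd({"A", "B"}, index) == 4.0
        # {A,C} spans both stems and both tip branches
        assert faith_pd({"A", "C"}, index) == 7.0

    def test_empty_set_and_full_union(self, four_tip_tree):
        index = build_tip_path_index(four_tip_tree)
        assert faith_pd(set(), index) == 0.0
        assert faith_pd({"A", "B", "C", "D"}, index) == four_tip_tree.total_length

    def test_unknown_species_rejected(self, four_tip_tree):
        with pytest.raises(DataError):
            faith_pd({"A", "Z"}, build_tip_path_index(four_tip_tree))

    @pytest.mark.parametrize("n_tips,seed", [(4, 0), (6, 1), (8, 2)])
    def test_exhaustive_subset_oracle(self, n_tips, seed):
        """PD over every subset of a random tree equals the brute-force
        path-union enumeration exactly."""
        tree = make_tree(SyntheticConfig(seed=seed, n_species=n_tips))
        index = build_tip_path_index(tree)
        for subset in all_subsets(tree.tip_labels):
            assert faith_pd(set(subset), index) == pytest.approx(
                brute_force_pd(tree, set(subset)), abs=1e-12
            )

    def test_monotone_in_species(self):
        tree = make_tree(SyntheticConfig(seed=5, n_species=12))
        index = build_tip_path_index(tree)
        tips = tree.tip_labels
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(1, len(tips)))
            subset = set(rng.choice(tips, size=k, replace=False))
            extra = set(rng.choice(tips, size=min(k + 2, len(tips)), replace=False))
            assert faith_pd(subset | extra, index) >= faith_pd(subset, index) - 1e-12


class TestRPD:
    def test_hand_worked_value(self, four_tip_tree):
        index = build_tip_path_index(four_tip_tree)
        comp_index = build_tip_path_index(comparison_tree(four_tip_tree))
        # non-zero mean = 9/6 = 1.5; {A,B} spans 3 branches -> 4 / 4.5
        assert rpd({"A", "B"}, index, comp_index) == pytest.approx(8 / 9)

    def test_equal_branch_tree_gives_unity(self):
        tree = parse_newick("((A:2,B:2):2,C:2);")
        index = build_tip_path_index(tree)
        comp_index = build_tip_path_index(comparison_tree(tree))
        for subset in [{"A"}, {"A", "B"}, {"A", "B", "C"}]:
            assert rpd(subset, index, comp_index) == pytest.approx(1.0)

    def test_scale_invariance(self, four_tip_tree):
        scaled = parse_newick("((A:3,B:3):6,(C:9,D:3):3);")  # every length x3
        for subset in [{"A", "B"}, {"A", "C"}, {"B", "C", "D"}]:
            r1 = rpd(
                subset,
                build_tip_path_index(four_tip_tree),
                build_tip_path_index(comparison_tree(four_tip_tree)),
            )
            r2 = rpd(
                subset,
                build_tip_path_index(scaled),
                build_tip_path_index(comparison_tree(scaled)),
            )
            assert r1 == pytest.approx(r2)

    def test_empty_set_rejected(self, four_tip_tree):
        index = build_tip_path_index(four_tip_tree)
        with pytest.raises(DataError):
            rpd(set(), index, index)


class TestComputeAllCells:
    def _matrix(self, grid, incidence, species, n_samples):
        incidence = np.asarray(incidence, dtype=np.uint8)
        return PresenceMatrix(
            grid=grid,
            cell_ids=np.arange(incidence.shape[0]),
            species=list(species),
            incidence=incidence,
            n_samples=np.asarray(n_samples),
        )

    def test_single_cell_with_all_species(self, small_grid, four_tip_tree):
        pm = self._matrix(small_grid, [[1, 1, 1, 1]], "ABCD", [6])
        out = compute_all_cells(pm, four_tip_tree)
        assert out.loc[0, "PD_frac"] == pytest.approx(1.0)
        assert out.loc[0, "PD_obs"] == pytest.approx(four_tip_tree.total_length)
        assert out.loc[0, "SR"] == 4

    def test_nested_cells_monotone(self, small_grid, four_tip_tree):
        pm = self._matrix(small_grid, [[1, 1, 0, 0], [1, 1, 1, 0]], "ABCD", [2, 3])
        out = compute_all_cells(pm, four_tip_tree)
        assert out.loc[1, "PD_obs"] >= out.loc[0, "PD_obs"]
        assert out.loc[1, "SR"] >= out.loc[0, "SR"]

    def test_synthetic_landscape_matches_oracle(self, small_bundle):
        from cwr_phylospace.occurrences import clean_records

        cleaned, _ = clean_records(small_bundle.records, small_bundle.grid)
        pm = build_presence_matrix(cleaned, small_bundle.grid)
        out = compute_all_cells(pm, small_bundle.tree)
        comp = comparison_tree(small_bundle.tree)
        for i in range(0, pm.n_cells, 7):  # every 7th cell against brute force
            present = {s for s, inc in zip(pm.species, pm.incidence[i]) if inc}
            assert out.loc[i, "PD_obs"] == pytest.approx(brute_force_pd(small_bundle.tree, present))
            assert out.loc[i, "PD_comp"] == pytest.approx(brute_force_pd(comp, present))
        assert (out["PD_frac"] <= 1.0 + 1e-12).all()
        assert (out["PD_obs"] > 0).all()
        assert out["redundancy"].between(0, 1).all()

    def test_unmatched_species_dropped_with_warning(self, small_grid, four_tip_tree):
        pm = self._matrix(small_grid, [[1, 1, 1]], ["A", "B", "NotInTree"], [3])
        with pytest.warns(UserWarning, match="not found among tree tips"):
            out = compute_all_cells(pm, four_tip_tree)
        assert out.loc[0, "SR"] == 2
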