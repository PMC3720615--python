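"""Root distances, species matching, MRD and quartile decomposition."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from latgrad import (build_grid, generate_tree, match_species,
                     mean_root_distance, quartile_split, rasterize,
                     read_newick, root_distances, richness)
from latgrad.grid import PresenceMatrix, RangeSet
from latgrad.phylo import NewickFormatError, normalize_name


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def _brute_force_rd(tree) -> dict:
    """Independent oracle: walk parent links from each tip, counting nodes."""
    out = {}
    for leaf in tree.leaf_node_iter():
        count = 0
        node = leaf.parent_node
        while node is not None:
            count += 1
            node = node.parent_node
        out[leaf.taxon.label] = count
    return out


class TestReadNewick:
    def test_basic_topology(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A,B),C);\n")
        tree = read_newick(p)
        assert len(tree.leaf_nodes()) == 3
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 2

    def test_branch_lengths_do_not_change_rd(self, tmp_path):
        p1 = tmp_path / "a.nwk"; p1.write_text("((A,B),C);\n")
        p2 = tmp_path / "b.nwk"; p2.write_text("((A:1,B:2):3,C:4);\n")
        assert root_distances(read_newick(p1)).equals(
            root_distances(read_newick(p2)))

    def test_root_polytomy_accepted(self, tmp_path):
        p = tmp_path / "p.nwk"
        p.write_text("((A,B),(C,D),E);\n")
        tree = read_newick(p)
        assert len(tree.seed_node.child_nodes()) == 3

    @pytest.mark.parametrize("bad", [
        "not a tree at all ((", "((A,B),C); ((D,E),F);", "((A,A),B);",
    ])
    def test_malformed_input_rejected(self, tmp_path, bad):
        p = tmp_path / "bad.nwk"
        p.write_text(bad + "\n")
        with pytest.raises(NewickFormatError):
            read_newick(p)


class TestRootDistances:
    @pytest.mark.parametrize("newick,expected", [
        ("(A,B);", {"A": 1, "B": 1}),
        ("((A,B),C);", {"A": 2, "B": 2, "C": 1}),
        ("((A,B),(C,D),E);", {"A": 2, "B": 2, "C": 2, "D": 2, "E": 1}),
    ])
    def test_counting_convention(self, newick, expected):
        assert root_distances(_tree(newick)).to_dict() == expected

    def test_matches_bruteforce_on_random_trees(self):
        for seed in range(25):
            tree = generate_tree(40, polytomy_prob=0.25 * (seed % 2), seed=seed)
            assert root_distances(tree).to_dict() == _brute_force_rd(tree)

    def test_single_tip_rejected(self):
        with pytest.raises(ValueError):
            root_distances(_tree("(A);"))

    def test_collapsing_an_edge_lowers_descendant_rd_by_one(self):
        tree = generate_tree(30, polytomy_prob=0.0, seed=4)
        rd_before = root_distances(tree)
        # collapse the first non-root internal node with an internal parent
        target = next(
            nd for nd in tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        )
        below = {lf.taxon.label for lf in target.leaf_iter()}
        parent = target.parent_node
        for child in list(target.child_nodes()):
            target.remove_child(child)
            parent.add_child(child)
        parent.remove_child(target)
        rd_after = root_distances(tree)
        for sp in rd_before.index:
            assert rd_after[sp] == rd_before[sp] - (1 if sp in below else 0)


class TestMatchSpecies:
    def test_normalization_rules(self):
        rd = pd.Series({"A_b": 3, "c_D": 5})
        matched, report = match_species(rd, ["a b", "C d"])
        assert matched.to_dict() == {"a b": 3, "C d": 5}
        assert report.n_matrix_only == 0 and report.n_tree_only == 0

    def test_disjoint_sets_all_reported(self):
        rd = pd.Series({"x": 1, "y": 2})
        matched, report = match_species(rd, ["a", "b", "c"])
        assert len(matched) == 0
        assert report.matrix_only == ["a", "b", "c"]
        assert report.tree_only == ["x", "y"]

    def test_synthetic_fixture_has_zero_drops(self, small_run, small_presence):
        tree, _, _ = small_run
        matched, report = match_species(root_distances(tree),
                                        small_presence.species)
        assert report.n_matrix_only == 0 and report.n_tree_only == 0
        assert len(matched) == len(small_presence.species)

    def test_idempotent_separators(self):
        assert normalize_name("Myotis  nigricans") == normalize_name("myotis_Nigricans")


def _pm_from_matrix(matrix, species):
    grid = build_grid((0, len(matrix) * 1.0, 0, 1.0), cell_km=100)
    m = np.zeros((grid.n_cells, len(species)), dtype=bool)
    m[: len(matrix)] = matrix
    return PresenceMatrix(grid=grid, species=species, matrix=m)


class TestMeanRootDistance:
    def test_cell_mean_of_rds(self):
        pm = _pm_from_matrix(np.array([[1, 1], [1, 0]], dtype=bool), ["a", "b"])
        rd = pd.Series({"a": 2, "b": 4})
        mrd = mean_root_distance(pm, rd)
        assert mrd[0] == pytest.approx(3.0)
        assert mrd[1] == pytest.approx(2.0)

    def test_constant_when_all_species_everywhere(self):
        pm = _pm_from_matrix(np.ones((3, 3), dtype=bool), ["a", "b", "c"])
        rd = pd.Series({"a": 1, "b": 2, "c": 6})
        mrd = mean_root_distance(pm, rd)
        np.testing.assert_allclose(mrd[:3], 3.0)

    def test_empty_cells_are_nan(self):
        pm = _pm_from_matrix(np.array([[1], [0]], dtype=bool), ["a"])
        mrd = mean_root_distance(pm, pd.Series({"a": 5}))
        assert mrd[0] == 5.0 and np.isnan(mrd[1])

    def test_shift_invariance(self, small_presence, small_run):
        tree, _, _ = small_run
        rd, _ = match_species(root_distances(tree), small_presence.species)
        base = mean_root_distance(small_presence, rd)
        shifted = mean_root_distance(small_presence, rd + 7)
        defined = np.isfinite(base)
        np.testing.assert_allclose(shifted[defined], base[defined] + 7.0)

    def test_mrd_bounded_by_rd_range(self, small_presence, small_run):
        tree, _, _ = small_run
        rd, _ = match_species(root_distances(tree), small_presence.species)
        mrd = mean_root_distance(small_presence, rd)
        defined = np.isfinite(mrd)
        assert (mrd[defined] >= rd.min() - 1e-12).all()
        assert (mrd[defined] <= rd.max() + 1e-12).all()


class TestQuartileSplit:
    def test_four_distinct_values(self):
        rd = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4})
        basal, derived = quartile_split(rd)
        assert basal == {"a"} and derived == {"d"}

    def test_interpolated_quantiles_with_ties(self):
        rd = pd.Series(dict(zip("abcdefgh", [1, 1, 2, 3, 4, 5, 6, 8])))
        basal, derived = quartile_split(rd)
        assert basal == {"a", "b"}
        assert derived == {"g", "h"}

    def test_all_ties_select_everything(self):
        rd = pd.Series({"a": 3, "b": 3, "c": 3, "d": 3})
        basal, derived = quartile_split(rd)
        assert basal == derived == {"a", "b", "c", "d"}

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            quartile_split(pd.Series({"a": 1, "b": 2, "c": 3}))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=12), min_size=4, max_size=40))
    def test_coverage_and_disjointness(self, values):
        rd = pd.Series(dict((f"s{i}", v) for i, v in enumerate(values)))
        basal, derived = quartile_split(rd)
        n = len(rd)
        assert len(basal) >= int(np.ceil(0.25 * n))
        assert len(derived) >= int(np.ceil(0.25 * n))
        q1 = np.quantile(values, 0.25)
        q3 = np.quantile(values, 0.75)
        if q1 < q3:
            assert not (basal & derived)
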