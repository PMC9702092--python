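"""Branch counting, Strahler ordering, Sholl profiles, coverage, organelles."""

import numpy as np
import pandas as pd
import pytest

from dendroquant import errors
from dendroquant.morphometry import (
    branch_density,
    branch_points,
    branches,
    branchpoint_occupancy,
    count_branches,
    internal_coverage,
    organelle_density,
    sholl_profile,
    strahler_orders,
    total_dendritic_length,
)

from conftest import make_arbor, random_tree
from oracles import (
    branch_count_degree_census,
    coverage_bruteforce,
    sholl_crossings,
    strahler_recursive,
)


def radial_arbor(lengths, step=5.0):
    """Straight radial dendrites of the given lengths, evenly spread in angle."""
    rows = [(1, 1, 0.0, 0.0, 0.0, 2.0, -1)]
    nid = 2
    for k, total in enumerate(lengths):
        angle = 2 * np.pi * k / len(lengths)
        parent = 1
        r = 0.0
        while r < total:
            r = min(r + step, total)
            rows.append(
                (nid, 3, r * np.cos(angle), r * np.sin(angle), 0.0, 0.5, parent)
            )
            parent = nid
            nid += 1
    return make_arbor(rows)


class TestLengthAndBranches:
    def test_total_length_sums_dendrites_only(self, chain_arbor):
        assert total_dendritic_length(chain_arbor) == pytest.approx(20.0)

    def test_axon_only_arbor_warns_and_returns_zero(self):
        arbor = make_arbor(
            [(1, 1, 0, 0, 0, 1.0, -1), (2, 2, 30, 0, 0, 1.0, 1)]
        )
        with pytest.warns(UserWarning, match="no dendritic"):
            assert total_dendritic_length(arbor) == 0.0

    def test_unbranched_dendrite_density(self):
        arbor = radial_arbor([100.0], step=10.0)
        assert count_branches(arbor) == 1
        assert branch_density(arbor) == pytest.approx(0.01)

    def test_stem_plus_bifurcation_has_three_branches(self, bifurcation_arbor):
        assert count_branches(bifurcation_arbor) == 3

    @pytest.mark.parametrize("seed", range(15))
    def test_branch_count_equals_degree_census(self, seed):
        rng = np.random.default_rng(seed)
        arbor = random_tree(rng, int(rng.integers(4, 80)))
        assert count_branches(arbor) == branch_count_degree_census(arbor)


class TestStrahler:
    def test_bare_bifurcation(self, bifurcation_arbor):
        orders, hist = strahler_orders(bifurcation_arbor)
        assert orders.loc[3] == 1 and orders.loc[4] == 1
        assert orders.loc[2] == 2  # the stem
        assert hist == {1: 2, 2: 1}

    def test_caterpillar_side_branches_order_one(self, caterpillar_arbor):
        orders, hist = strahler_orders(caterpillar_arbor)
        for side in (6, 7, 8):
            assert orders.loc[side] == 1
        # proximal stem compartments carry order 2; the distal tip run is 1
        assert orders.loc[2] == 2 and orders.loc[3] == 2 and orders.loc[4] == 2
        assert orders.loc[5] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_recursive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        arbor = random_tree(rng, int(rng.integers(5, 50)))
        orders, _ = strahler_orders(arbor)
        assert orders.to_dict() == strahler_recursive(arbor)

    def test_order_never_decreases_toward_root(self):
        rng = np.random.default_rng(42)
        arbor = random_tree(rng, 60)
        orders, hist = strahler_orders(arbor)
        comp = arbor.nodes.set_index("node_id")["parent_id"]
        root = arbor.root_id
        for child in orders.index:
            pid = int(comp.loc[child])
            if pid != root:
                assert orders.loc[pid] >= orders.loc[child]
        # maximal order sits on a root-adjacent branch
        root_children = [b for b in branches(arbor) if comp.loc[b.node_ids[0]] == root]
        assert max(b.order for b in root_children) == max(hist)

    def test_branches_share_one_order(self):
        rng = np.random.default_rng(3)
        arbor = random_tree(rng, 70)
        orders, _ = strahler_orders(arbor)
        for b in branches(arbor):
            assert len(set(int(orders.loc[n]) for n in b.node_ids)) == 1


class TestSholl:
    def test_straight_radial_dendrite(self):
        arbor = radial_arbor([95.0])
        prof = sholl_profile(arbor, 10.0)
        assert list(prof.radii) == [10 * k for k in range(1, 10)]
        assert all(prof.intersections == 1)

    def test_two_opposite_radial_dendrites(self):
        arbor = radial_arbor([95.0, 95.0])
        prof = sholl_profile(arbor, 10.0)
        assert all(prof.intersections == 2)

    @pytest.mark.parametrize("seed,step", [(0, 5.0), (1, 10.0), (2, 20.0)])
    def test_matches_crossing_parity_oracle(self, seed, step):
        rng = np.random.default_rng(seed)
        arbor = random_tree(rng, 40)
        prof = sholl_profile(arbor, step)
        for r, n in zip(prof.radii, prof.intersections):
            assert n == sholl_crossings(arbor, r)

    def test_small_step_limit_recovers_radial_extent(self):
        # for a purely radial arbor, sum(crossings) * step -> total cable
        arbor = radial_arbor([80.0, 60.0, 40.0])
        step = 0.25
        prof = sholl_profile(arbor, step)
        approx = float(prof.intersections.sum()) * step
        assert approx == pytest.approx(180.0, rel=0.02)

    def test_peak_statistics(self):
        arbor = radial_arbor([95.0, 50.0])
        prof = sholl_profile(arbor, 10.0)
        assert prof.peak_intersections == 2
        assert prof.peak_radius == 10.0  # proximal tie-break

    def test_step_beyond_extent_warns(self, chain_arbor):
        with pytest.warns(UserWarning, match="extent"):
            prof = sholl_profile(chain_arbor, 500.0)
        assert len(prof.radii) == 1


class TestCoverage:
    def test_single_horizontal_dendrite_covers_one_row(self):
        # 40 x 20 bounding box, 10 um boxes: the dendrite runs along y=0
        rows = [
            (1, 1, 0.0, 0.0, 0.0, 1.0, -1),
            (2, 3, 40.0, 0.0, 0.0, 0.5, 1),
            (3, 3, 0.0, 20.0, 0.0, 0.5, 1),  # a lone node to open the box height
            (4, 3, 0.1, 20.0, 0.0, 0.5, 3),
        ]
        arbor = make_arbor(rows)
        grid = internal_coverage(arbor, 10.0)
        assert grid.n_boxes_total == 8
        # bottom row fully crossed (4 boxes) + 1 box for the short top segment
        assert grid.n_boxes_occupied == 5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_line_clipping_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        arbor = random_tree(rng, 30)
        grid = internal_coverage(arbor, 8.0)
        occ, total = coverage_bruteforce(arbor, 8.0)
        assert (grid.n_boxes_occupied, grid.n_boxes_total) == (occ, total)

    def test_proportion_never_rises_under_grid_refinement(self):
        from dendroquant.synthetic import ci_like_spec, generate_arbor

        for seed in range(5):
            arbor = generate_arbor(ci_like_spec(), seed=seed)
            props = [
                internal_coverage(arbor, b).proportion_covered for b in (40.0, 20.0, 10.0)
            ]
            assert props[0] >= props[1] >= props[2]

    def test_space_filling_civ_preset_is_dense(self):
        from dendroquant.synthetic import civ_like_spec, generate_arbor

        arbor = generate_arbor(civ_like_spec(), seed=0)
        assert internal_coverage(arbor, 10.0).proportion_covered >= 0.9


class TestOrganelles:
    def test_density_per_100um(self):
        arbor = radial_arbor([250.0], step=10.0)
        positions = pd.DataFrame(
            {"path_um": [10, 50, 90, 130, 170], "branch_id": 0, "at_branch_point": False}
        )
        assert organelle_density(positions, arbor) == pytest.approx(2.0)

    def test_positions_beyond_extent_rejected(self):
        arbor = radial_arbor([100.0], step=10.0)
        positions = pd.DataFrame(
            {"path_um": [50.0, 500.0], "branch_id": 0, "at_branch_point": False}
        )
        with pytest.warns(UserWarning, match="beyond"):
            assert organelle_density(positions, arbor) == pytest.approx(1.0)

    def test_branchpoint_occupancy_fraction(self):
        rng = np.random.default_rng(9)
        arbor = random_tree(rng, 60)
        bps = branch_points(arbor)
        assert len(bps) >= 4
        brs = branches(arbor)
        # flag organelles on two branches whose distal node is a branch point
        chosen = [b for b in brs if b.node_ids[-1] in bps][:2]
        positions = pd.DataFrame(
            {
                "path_um": [1.0, 1.0],
                "branch_id": [b.branch_id for b in chosen],
                "at_branch_point": True,
            }
        )
        expected = 100.0 * 2 / len(bps)
        assert branchpoint_occupancy(positions, arbor) == pytest.approx(expected)

    def test_poisson_placement_recovers_rate(self):
        arbor = radial_arbor([200.0, 200.0], step=10.0)
        total = total_dendritic_length(arbor)
        lam = 0.03  # organelles per um
        rng = np.random.default_rng(123)
        est = []
        for _ in range(20):
            n = rng.poisson(lam * total)
            pos = pd.DataFrame(
                {
                    "path_um": rng.uniform(0, 200.0, n),
                    "branch_id": 0,
                    "at_branch_point": False,
                }
            )
            est.append(organelle_density(pos, arbor))
        se = 100.0 * np.sqrt(lam / total) / np.sqrt(20)
        assert abs(np.mean(est) - 100.0 * lam) < 3 * se


def test_branch_density_error_on_zero_length():
    arbor = make_arbor([(1, 1, 0, 0, 0, 1.0, -1), (2, 2, 9, 0, 0, 1.0, 1)])
    with pytest.warns(UserWarning):
        with pytest.raises(errors.ParameterError):
            branch_density(arbor)
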