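"""Cubical persistence: union-find pairs, duality, oracle, Betti counts."""

import numpy as np
import pytest

from asymtopo.cubical import (
    ORACLE_MAX_VOXELS,
    PersistencePair,
    betti_at_threshold,
    compute_persistence,
    oracle_diagram,
    sublevel_two_cycles,
    sublevel_zero_cycles,
)
from asymtopo.grid import VoxelGrid


def test_pair_rejects_death_before_birth():
    with pytest.raises(ValueError, match="exceeds"):
        PersistencePair(0, 1.0, 0.0)


class TestZeroCycles:
    def test_hand_run_three_voxel_line(self):
        # values [-3, 5, -2]: the -2 well dies when 5 merges it into the
        # elder -3 component; the -3 component is essential, paired min-max
        g = VoxelGrid(np.array([-3.0, 5.0, -2.0]).reshape(1, 1, 3))
        pairs = sublevel_zero_cycles(g)
        triples = sorted((p.birth_value, p.death_value, p.essential) for p in pairs)
        assert triples == [(-3.0, 5.0, True), (-2.0, 5.0, False)]
        ess = next(p for p in pairs if p.essential)
        assert ess.birth_voxel == (0, 0, 0)
        assert ess.death_voxel == (0, 0, 1)

    def test_constant_grid_single_essential(self):
        g = VoxelGrid(np.full((4, 4, 4), 2.5))
        pairs = sublevel_zero_cycles(g)
        assert len(pairs) == 1
        (p,) = pairs
        assert p.essential and p.birth_value == p.death_value == 2.5

    def test_increasing_ramp_single_pair(self):
        g = VoxelGrid(np.arange(24, dtype=float).reshape(1, 1, 24))
        pairs = sublevel_zero_cycles(g)
        assert len(pairs) == 1
        assert (pairs[0].birth_value, pairs[0].death_value) == (0.0, 23.0)

    def test_pair_count_equals_local_minima_without_ties(self, rng):
        # tie-free grid: every dim-0 pair is born at a distinct local minimum
        for _ in range(10):
            vals = rng.normal(size=(6, 6, 6))
            g = VoxelGrid(vals)
            pairs = sublevel_zero_cycles(g)
            n_min = 0
            for idx in np.ndindex(vals.shape):
                v = vals[idx]
                lower = False
                for ax in range(3):
                    for d in (-1, 1):
                        j = list(idx)
                        j[ax] += d
                        if 0 <= j[ax] < vals.shape[ax] and vals[tuple(j)] < v:
                            lower = True
                if not lower:
                    n_min += 1
            assert len(pairs) == n_min
            for p in pairs:
                assert p.birth_value <= p.death_value

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sublevel_zero_cycles(VoxelGrid(np.zeros((0, 2, 2))))


class TestTwoCycles:
    def test_single_interior_bump_is_one_cavity(self, make_bump_grid):
        g = make_bump_grid((10, 10, 10), [((5, 5, 5), 1.2, 2.0)])
        pairs = [p for p in sublevel_two_cycles(g) if p.lifespan > 0.1]
        assert len(pairs) == 1
        assert pairs[0].death_value == pytest.approx(2.0)
        assert pairs[0].death_voxel == (5, 5, 5)

    def test_monotone_field_has_no_cavities(self):
        g = VoxelGrid(-np.arange(64, dtype=float).reshape(4, 4, 4))
        assert sublevel_two_cycles(g) == []

    def test_two_bumps_cavity_splits_into_two(self, make_bump_grid):
        # two nearby bumps on a flat background: one cavity appears when the
        # background encloses both, splits at the saddle, and each piece dies
        # at its own peak
        g = make_bump_grid((14, 14, 14),
                           [((4, 7, 7), 1.3, 1.0), ((9, 7, 7), 1.3, 1.5)])
        pairs = sorted(
            (p for p in sublevel_two_cycles(g) if p.lifespan > 0.05),
            key=lambda p: -p.lifespan,
        )
        assert len(pairs) == 2
        # overlapping tails shift each peak slightly above its amplitude
        assert pairs[0].death_value == pytest.approx(1.5, abs=0.01)
        assert pairs[1].death_value == pytest.approx(1.0, abs=0.01)
        # the cavity count reaches two during the filtration
        saddle = (pairs[1].birth_value + pairs[1].death_value) / 2
        assert betti_at_threshold(g, saddle)[1] == 2

    def test_one_voxel_grid(self):
        g = VoxelGrid(np.array([[[1.5]]]))
        diagram = compute_persistence(g)
        assert len(diagram.of_dim(2)) == 0
        zero = diagram.of_dim(0).pairs
        assert len(zero) == 1 and zero[0].essential


class TestOracleAgreement:
    def test_matches_union_find_on_random_integer_grids(self, random_int_grid):
        for _ in range(30):
            g = random_int_grid()
            assert (
                compute_persistence(g).nonzero().multiset()
                == oracle_diagram(g).multiset()
            )

    def test_matches_on_tie_free_grids(self, rng):
        for _ in range(10):
            g = VoxelGrid(rng.normal(size=(5, 5, 5)))
            assert (
                compute_persistence(g).nonzero().multiset()
                == oracle_diagram(g).multiset()
            )

    def test_all_equal_grid(self):
        g = VoxelGrid(np.zeros((3, 3, 3)))
        assert compute_persistence(g).nonzero().multiset() == oracle_diagram(g).multiset()

    def test_oracle_refuses_large_grids(self):
        g = VoxelGrid(np.zeros((13, 13, 13)))
        assert g.values.size > ORACLE_MAX_VOXELS
        with pytest.raises(ValueError, match="refuses"):
            oracle_diagram(g)


class TestDuality:
    def test_two_cycles_equal_padded_dual_zero_cycles(self, random_int_grid):
        # pairs(dim 2, f) = {(-d, -b)} of the dim-0 pairs of -f under the
        # dual connectivity with the outside introduced last, outside excluded
        for _ in range(20):
            g = random_int_grid()
            two = sorted((p.birth_value, p.death_value)
                         for p in sublevel_two_cycles(g))
            padded = np.pad(-g.values, 1, constant_values=-1e18)
            dual = sublevel_zero_cycles(VoxelGrid(padded), connectivity=26)
            mapped = sorted(
                (-p.death_value, -p.birth_value)
                for p in dual
                if not p.essential
            )
            assert mapped == two

    def test_negation_swaps_dims_for_interior_structures(self, make_bump_grid):
        # for planted structures away from the boundary, negating the image
        # exchanges wells and bumps: (b, d) -> (-d, -b) across dimensions
        g = make_bump_grid((12, 12, 12),
                           [((3, 3, 3), 1.0, -1.0), ((8, 8, 8), 1.0, -0.6)])
        neg = VoxelGrid(-g.values)
        d_pos = compute_persistence(g)
        d_neg = compute_persistence(neg)
        zero = np.array(sorted(
            (p.birth_value, p.death_value)
            for p in d_pos.of_dim(0).nonzero().pairs if p.lifespan > 0.05
        ))
        mapped_two = np.array(sorted(
            (-p.death_value, -p.birth_value)
            for p in d_neg.of_dim(2).pairs if p.lifespan > 0.05
        ))
        # births (well depths <-> bump peaks) match exactly; deaths match up
        # to the min-max convention for the essential 0-pair, all near zero
        assert zero.shape == mapped_two.shape == (2, 2)
        np.testing.assert_allclose(zero[:, 0], mapped_two[:, 0], atol=1e-9)
        np.testing.assert_allclose(zero[:, 1], mapped_two[:, 1], atol=0.02)


class TestBetti:
    def test_below_min_and_above_max(self, random_int_grid):
        g = random_int_grid()
        assert betti_at_threshold(g, g.values.min() - 1) == (0, 0)
        assert betti_at_threshold(g, g.values.max()) == (1, 0)

    def test_consistent_with_diagram(self, random_int_grid, rng):
        for _ in range(10):
            g = random_int_grid()
            diagram = compute_persistence(g)
            for t in rng.uniform(-6, 6, size=10):
                b0, b2 = betti_at_threshold(g, t)
                c0 = sum(
                    1 for p in diagram.of_dim(0).pairs
                    if (p.essential and p.birth_value <= t)
                    or (not p.essential and p.birth_value <= t < p.death_value)
                )
                c2 = sum(
                    1 for p in diagram.of_dim(2).pairs
                    if p.birth_value <= t < p.death_value
                )
                assert (b0, b2) == (c0, c2)


def test_stability_under_small_perturbation(make_bump_grid, rng):
    # well-separated critical values: an eps-perturbation moves every
    # matched birth/death by at most eps
    g = make_bump_grid((10, 10, 10),
                       [((3, 3, 3), 1.1, -2.0), ((7, 7, 7), 1.1, -1.0)])
    eps = 0.01
    pert = VoxelGrid(g.values + rng.uniform(-eps, eps, size=g.values.shape))
    for dim in (0, 2):
        a = [p for p in compute_persistence(g).of_dim(dim).pairs if p.lifespan > 0.1]
        b = [p for p in compute_persistence(pert).of_dim(dim).pairs if p.lifespan > 0.1]
        assert len(a) == len(b)
        for pa, pb in zip(
            sorted(a, key=lambda p: p.birth_value),
            sorted(b, key=lambda p: p.birth_value),
        ):
            assert abs(pa.birth_value - pb.birth_value) <= eps + 1e-12
            assert abs(pa.death_value - pb.death_value) <= eps + 1e-12


def test_diagram_dataframe_round_trip(tmp_path, random_int_grid):
    from asymtopo.io import read_diagram_csv, write_diagram_csv

    diagram = compute_persistence(random_int_grid(), source_id="x")
    path = tmp_path / "d.csv"
    write_diagram_csv(diagram, path)
    back = read_diagram_csv(path, source_id="x")
    assert back.multiset() == diagram.multiset()
    assert [p.birth_voxel for p in back.pairs] == [p.birth_voxel for p in diagram.pairs]
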