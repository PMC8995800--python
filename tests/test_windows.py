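"""Window construction, distance algebra, solvers, and export."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from szlab.errors import (
    DomainError,
    InvalidWindowError,
    ResourceError,
    SolverError,
)
from szlab.windows import (
    NodeGeometry,
    achievable_retained_counts,
    centered_window,
    diagonal_window,
    distance_field,
    full_window,
    gaussian_window,
    node_distance,
    random_window,
    reduction_ratio,
    retained_fraction,
    solve_diagonal_threshold,
    solve_gaussian_sigma,
    solve_window,
    stripe_window,
    window_from_csv,
    window_to_csv,
)

geometries = st.tuples(st.integers(1, 64), st.integers(1, 64)).map(
    lambda t: NodeGeometry(*t)
)


class TestDistances:
    @pytest.mark.parametrize(
        "i,j,n_in,n_out,expected",
        [
            (3, 3, 5, 5, 0.0),
            (2, 4, 5, 5, 2 / math.sqrt(2)),
            (1, 21, 3, 64, abs(64 / 3 - 21) / math.sqrt((64 / 3) ** 2 + 1)),
            (0, 0, 7, 13, 0.0),
        ],
    )
    def test_point_to_diagonal_distance(self, i, j, n_in, n_out, expected):
        assert node_distance(i, j, NodeGeometry(n_in, n_out)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_out_of_range_index_names_offender(self):
        with pytest.raises(DomainError, match="i=5"):
            node_distance(5, 0, NodeGeometry(5, 5))
        with pytest.raises(DomainError, match="j=-1"):
            node_distance(0, -1, NodeGeometry(5, 5))

    def test_field_matches_elementwise_distance(self):
        geom = NodeGeometry(4, 7)
        field = distance_field(geom).values
        for i in range(4):
            for j in range(7):
                assert field[i, j] == pytest.approx(node_distance(i, j, geom))

    def test_trivial_and_two_by_two_fields(self):
        assert distance_field(NodeGeometry(1, 1)).values.item() == 0.0
        f = distance_field(NodeGeometry(2, 2)).values
        assert np.allclose(f, [[0, 1 / math.sqrt(2)], [1 / math.sqrt(2), 0]])

    @given(n=st.integers(1, 40))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_square_field_is_symmetric(self, n):
        f = distance_field(NodeGeometry(n, n)).values
        assert np.allclose(f, f.T)


class TestDiagonalWindow:
    def test_tridiagonal_five_by_five(self):
        w = diagonal_window(NodeGeometry(5, 5), 0.8)
        assert w.values.sum() == 13
        assert w.retained_fraction == pytest.approx(0.52)
        assert np.array_equal(w.values, np.tril(np.triu(np.ones((5, 5)), -1), 1))

    def test_threshold_above_max_distance_gives_full_window(self):
        geom = NodeGeometry(6, 11)
        w = diagonal_window(geom, distance_field(geom).values.max())
        assert w.retained_fraction == 1.0

    def test_channel_geometry_reproduces_printed_elimination_ratio(self):
        # 3-in/64-out channel window: 112 of 192 retained, 80/192 = 41.7% gone
        w = diagonal_window(NodeGeometry(3, 64), 68 / math.sqrt(4105))
        assert w.values.sum() == 112
        assert reduction_ratio(w) * 100 == pytest.approx(41.7, abs=0.05)

    def test_all_zero_threshold_on_offset_geometry_raises(self):
        # no cell of a 2x3 matrix lies exactly on the diagonal except (0, 0)
        w = diagonal_window(NodeGeometry(5, 5), 0.0)
        assert w.values.sum() == 5  # the exact diagonal survives inclusively
        with pytest.raises(DomainError):
            diagonal_window(NodeGeometry(5, 5), -0.1)


class TestGaussianWindow:
    def test_unit_value_on_diagonal(self):
        w = gaussian_window(NodeGeometry(5, 5), 0.7)
        assert np.diag(w.values) == pytest.approx(np.ones(5))

    def test_off_diagonal_value(self):
        w = gaussian_window(NodeGeometry(5, 5), 1 / math.sqrt(2))
        assert w.values[0, 1] == pytest.approx(math.exp(-0.5))

    def test_sigma_must_be_positive(self):
        with pytest.raises(DomainError):
            gaussian_window(NodeGeometry(3, 3), 0.0)

    def test_retained_fraction_increases_with_sigma(self):
        geom = NodeGeometry(8, 12)
        fracs = [gaussian_window(geom, s).retained_fraction for s in (0.3, 0.8, 2.0, 5.0)]
        assert all(a < b for a, b in zip(fracs, fracs[1:]))

    def test_small_sigma_limit_keeps_only_diagonal_cells(self):
        geom = NodeGeometry(6, 6)
        w = gaussian_window(geom, 1e-3)
        big = w.values > 0.5
        assert np.array_equal(big, distance_field(geom).values == 0)


class TestStripeWindow:
    def test_single_band_equals_diagonal_window(self):
        geom = NodeGeometry(9, 9)
        s = stripe_window(geom, 1, 0.9)
        d = diagonal_window(geom, 0.9)
        assert np.array_equal(s.values, d.values)

    def test_two_bands_eight_by_eight(self):
        # brute-force membership: distance to main diagonal or the band
        # wrapped 4 columns away
        geom = NodeGeometry(8, 8)
        w = stripe_window(geom, 2, 0.4)
        expected = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                d = min(
                    abs(i + s - j) / math.sqrt(2) for s in (0, 4, -4)
                )
                expected[i, j] = d <= 0.4
        assert np.array_equal(w.values, expected)

    def test_stripe_is_superset_of_diagonal_at_equal_threshold(self):
        geom = NodeGeometry(10, 14)
        s = stripe_window(geom, 3, 0.6)
        d = diagonal_window(geom, 0.6)
        assert np.all(s.values >= d.values)
        assert s.retained_fraction >= d.retained_fraction


class TestCenteredWindow:
    def test_five_by_five_quarter_radius_keeps_plus_shape(self):
        w = centered_window(NodeGeometry(5, 5), 0.25)
        expected = np.zeros((5, 5))
        expected[2, 2] = 1
        expected[1, 2] = expected[3, 2] = expected[2, 1] = expected[2, 3] = 1
        assert np.array_equal(w.values, expected)

    def test_large_radius_gives_all_ones(self):
        w = centered_window(NodeGeometry(7, 4), math.sqrt(2) / 2)
        assert w.retained_fraction == 1.0

    def test_rotational_symmetry(self):
        w = centered_window(NodeGeometry(9, 6), 0.4)
        assert np.array_equal(w.values, np.rot90(w.values, 2))


class TestRandomWindow:
    def test_full_retention_regardless_of_seed(self):
        for seed in (0, 99):
            assert random_window(NodeGeometry(4, 4), 1.0, seed).retained_fraction == 1.0

    def test_exact_count_and_reproducibility(self):
        w1 = random_window(NodeGeometry(10, 10), 0.3, seed=7)
        w2 = random_window(NodeGeometry(10, 10), 0.3, seed=7)
        assert w1.values.sum() == 30
        assert np.array_equal(w1.values, w2.values)

    def test_different_seeds_overlap_near_hypergeometric_expectation(self):
        # E[overlap] = 30 * 30 / 100 = 9 for two independent 30-cell masks
        overlaps = [
            (
                random_window(NodeGeometry(10, 10), 0.3, seed=2 * k).values
                * random_window(NodeGeometry(10, 10), 0.3, seed=2 * k + 1).values
            ).sum()
            for k in range(40)
        ]
        assert 7.0 < np.mean(overlaps) < 11.0

    def test_zero_rounded_count_raises(self):
        with pytest.raises(InvalidWindowError):
            random_window(NodeGeometry(10, 10), 0.001, seed=0)


class TestAchievableCountsAndSolvers:
    def test_one_by_one(self):
        assert achievable_retained_counts(NodeGeometry(1, 1)) == [0, 1]

    def test_five_by_five_contains_known_counts(self):
        counts = achievable_retained_counts(NodeGeometry(5, 5))
        assert {5, 13, 25} <= set(counts)
        assert counts == sorted(counts)
        assert counts[-1] == 25

    def test_channel_geometry_contains_fig_ratio_count(self):
        assert 112 in achievable_retained_counts(NodeGeometry(3, 64))

    def test_size_cap(self):
        with pytest.raises(ResourceError):
            achievable_retained_counts(NodeGeometry(2000, 2000), size_cap=10**6)

    def test_solve_diagonal_full_target(self):
        geom = NodeGeometry(6, 9)
        t, achieved = solve_diagonal_threshold(geom, 1.0)
        assert achieved == 1.0
        assert t == pytest.approx(distance_field(geom).values.max())

    def test_solve_diagonal_exact_membership(self):
        geom = NodeGeometry(3, 64)
        _, achieved = solve_diagonal_threshold(geom, 112 / 192)
        assert achieved == pytest.approx(112 / 192)

    @given(geom=geometries, target=st.floats(0.05, 1.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_solved_threshold_snaps_to_achievable_grid(self, geom, target):
        try:
            threshold, achieved = solve_diagonal_threshold(geom, target)
        except InvalidWindowError:
            # legitimate when the nearest achievable count is the empty window
            counts = np.asarray(achievable_retained_counts(geom))
            assert counts[np.abs(counts - target * geom.size).argmin()] == 0
            return
        counts = achievable_retained_counts(geom)
        n = geom.size
        assert round(achieved * n) in counts
        w = diagonal_window(geom, threshold)
        assert w.values.sum() == round(achieved * n)

    def test_gaussian_solver_hits_target(self):
        geom = NodeGeometry(5, 5)
        sigma = solve_gaussian_sigma(geom, 0.52)
        assert gaussian_window(geom, sigma).values.sum() == pytest.approx(13.0, abs=2.5e-5)

    def test_gaussian_solver_deterministic(self):
        geom = NodeGeometry(7, 11)
        s1 = solve_gaussian_sigma(geom, 0.33)
        s2 = solve_gaussian_sigma(geom, 0.33)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_gaussian_solver_high_target(self):
        geom = NodeGeometry(4, 4)
        sigma = solve_gaussian_sigma(geom, 0.999)
        assert gaussian_window(geom, sigma).retained_fraction == pytest.approx(
            0.999, abs=1e-6
        )

    def test_gaussian_solver_unreachable_target(self):
        # sigma -> 0 floor for a 2x2 geometry is 0.5 (two diagonal cells)
        with pytest.raises(SolverError):
            solve_gaussian_sigma(NodeGeometry(2, 2), 0.3)

    def test_diagonal_monotone_in_threshold(self):
        geom = NodeGeometry(12, 7)
        dmax = distance_field(geom).values.max()
        fracs = [
            diagonal_window(geom, t).retained_fraction
            for t in np.linspace(0, dmax, 9)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_solve_window_families(self):
        geom = NodeGeometry(16, 16)
        for family in ("diagonal", "gaussian", "stripe", "centered", "random"):
            w = solve_window(geom, family, 0.5, seed=3)
            assert w.family == family
            assert abs(w.reduction - 0.5) < 0.2  # snapped to the achievable grid
        assert solve_window(geom, "diagonal", 0.0).family == "full"


class TestWindowMatrixContracts:
    def test_retained_fraction_recomputable(self):
        w = gaussian_window(NodeGeometry(9, 5), 0.8)
        assert retained_fraction(w) == pytest.approx(
            w.values.sum() / w.values.size, abs=1e-12
        )

    def test_all_ones_retained_fraction(self):
        assert retained_fraction(full_window(NodeGeometry(5, 5))) == 1.0

    def test_binary_families_are_binary(self):
        geom = NodeGeometry(10, 10)
        for w in (
            diagonal_window(geom, 1.0),
            stripe_window(geom, 2, 0.5),
            centered_window(geom, 0.4),
            random_window(geom, 0.5, 1),
        ):
            assert set(np.unique(w.values)) <= {0.0, 1.0}

    @given(geom=geometries)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_square_binary_windows_are_symmetric(self, geom):
        if geom.n_in != geom.n_out:
            geom = NodeGeometry(geom.n_in, geom.n_in)
        w = diagonal_window(geom, float(np.median(distance_field(geom).values)))
        assert np.array_equal(w.values, w.values.T)

    def test_csv_round_trip(self, tmp_path):
        w = gaussian_window(NodeGeometry(6, 4), 0.9)
        path = tmp_path / "w.csv"
        window_to_csv(w, path)
        back = window_from_csv(path)
        assert back.family == "gaussian"
        assert back.params == w.params
        assert np.allclose(back.values, w.values, atol=1e-15)
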