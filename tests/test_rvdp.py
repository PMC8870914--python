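"""Reference degree-plot sampling: areas, bisection, rounding, balancing."""

import math
import time

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from randomplots.rvdp import (
    LineSpec,
    ReferencePlotPair,
    balance,
    clamped_line_area,
    discretize,
    generate_rvdp,
    sample_line_pair,
    solve_beta2,
)


class TestClampedLineArea:
    @pytest.mark.parametrize(
        "alpha, beta, n, expected",
        [
            (1e-9, 10.0, 10, 100.0),  # line pinned at the ceiling fills the square
            (math.pi / 4, 0.0, 10, 50.0),  # diagonal: half the square
            (math.pi / 4, 5.0, 10, 87.5),  # trapezoid + ceiling rectangle
            (1e-9, 0.0, 10, 0.0),  # line pinned at the floor
        ],
    )
    def test_known_areas(self, alpha, beta, n, expected):
        assert clamped_line_area(LineSpec(alpha, beta, n)) == pytest.approx(
            expected, abs=1e-6
        )

    def test_matches_numeric_quadrature(self, rng):
        """Analytic piecewise area equals brute-force quadrature of the clamp."""
        for _ in range(100):
            n = int(rng.integers(2, 50))
            alpha = rng.uniform(1e-6, math.pi / 2 - 1e-6)
            beta = rng.uniform(-n * math.tan(alpha), n)
            line = LineSpec(alpha, beta, n)
            slope = math.tan(alpha)
            numeric = 0.0
            # integrate piecewise between the clamp breakpoints to help quad
            pts = sorted(
                {0.0, n, min(max(-beta / slope, 0.0), n), min(max((n - beta) / slope, 0.0), n)}
            )
            for a, b in zip(pts, pts[1:]):
                numeric += quad(lambda x: min(max(x * slope + beta, 0.0), float(n)), a, b)[0]
            assert clamped_line_area(line) == pytest.approx(numeric, abs=1e-9 * n**2)


class TestLineProperties:
    @settings(derandomize=True, max_examples=200)
    @given(
        n=st.integers(2, 200),
        alpha=st.floats(1e-6, math.pi / 2 - 1e-6),
        frac=st.floats(0.0, 1.0),
    )
    def test_area_bounded_and_monotone_in_intercept(self, n, alpha, frac):
        """The clamped area lies in [0, N^2] and never decreases as the
        line is shifted upward."""
        slope = math.tan(alpha)
        beta = -n * slope + frac * (n + n * slope)
        area = clamped_line_area(LineSpec(alpha, beta, n))
        assert 0.0 <= area <= n**2
        higher = min(beta + 0.5 * n, float(n))
        if higher > beta:
            assert clamped_line_area(LineSpec(alpha, higher, n)) >= area - 1e-9

    @settings(derandomize=True, max_examples=200)
    @given(
        n=st.integers(2, 200),
        alpha=st.floats(1e-6, math.pi / 2 - 1e-6),
        frac=st.floats(0.0, 1.0),
    )
    def test_discretize_respects_contract(self, n, alpha, frac):
        slope = math.tan(alpha)
        beta = -n * slope + frac * (n + n * slope)
        values = discretize(LineSpec(alpha, beta, n))
        assert values.shape == (n,)
        assert np.all(np.diff(values) >= 0)
        assert values.min() >= 1 and values.max() <= n - 1


class TestSolveBeta2:
    def test_horizontal_line_at_mid_height(self):
        assert solve_beta2(1e-9, 50.0, 10, tol=1e-9) == pytest.approx(5.0, abs=1e-6)

    def test_self_consistency(self, rng):
        """Solving for the area of a known line recovers its intercept."""
        for _ in range(20):
            n = int(rng.integers(2, 40))
            alpha = rng.uniform(0.05, math.pi / 2 - 0.05)
            beta = rng.uniform(-n * math.tan(alpha) * 0.9, n * 0.9)
            area = clamped_line_area(LineSpec(alpha, beta, n))
            solved = solve_beta2(alpha, area, n, tol=1e-10)
            assert clamped_line_area(LineSpec(alpha, solved, n)) == pytest.approx(
                area, abs=1e-9 * n**2
            )

    def test_inverse_of_quadrature_example(self):
        assert solve_beta2(math.pi / 4, 87.5, 10, tol=1e-9) == pytest.approx(5.0, abs=1e-6)

    def test_rejects_out_of_range_area(self):
        with pytest.raises(ValueError):
            solve_beta2(math.pi / 4, 101.0, 10)
        with pytest.raises(ValueError):
            solve_beta2(math.pi / 4, -1.0, 10)


class TestDiscretize:
    def test_floor_clamp_below(self):
        # y(i) ~ 0 everywhere: lower clamp forces every entry to 1
        assert np.all(discretize(LineSpec(1e-9, 0.0, 10)) == 1)

    def test_ceiling_clamp(self):
        # y(i) far above N: upper clamp forces every entry to N-1
        line = LineSpec(math.pi / 2 - 1e-6, 10.0, 10)
        assert np.all(discretize(line) == 9)

    def test_round_half_up_mid_value(self):
        # flat line at 2.2: floor(2.2 + 0.5) = 2 for every vertex
        assert np.all(discretize(LineSpec(1e-9, 2.2, 10)) == 2)

    def test_output_nondecreasing(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 60))
            alpha = rng.uniform(1e-6, math.pi / 2 - 1e-6)
            beta = rng.uniform(-n * math.tan(alpha), n)
            values = discretize(LineSpec(alpha, beta, n))
            assert np.all(np.diff(values) >= 0)
            assert values.min() >= 1 and values.max() <= n - 1


class TestBalance:
    def test_equal_sums_returned_unchanged(self, rng):
        d = np.array([1, 2, 2, 3])
        pair = balance(d, d.copy(), rng)
        assert np.array_equal(pair.d_minus, d)
        assert np.array_equal(pair.d_plus, d)

    def test_single_unit_move(self, rng):
        """A gap of one is closed by exactly one unit change within bounds."""
        d_minus = np.array([1, 1, 2, 3])  # sum 7
        d_plus = np.array([1, 1, 2, 2])  # sum 6
        for seed in range(50):
            pair = balance(d_minus, d_plus, np.random.default_rng(seed))
            assert pair.d_minus.sum() == pair.d_plus.sum()
            assert pair.d_minus.min() >= 1 and pair.d_minus.max() <= 3
            assert pair.d_plus.min() >= 1 and pair.d_plus.max() <= 3
            changed = int(np.abs(np.sort(pair.d_minus) - d_minus).sum()) + int(
                np.abs(np.sort(pair.d_plus) - d_plus).sum()
            )
            assert changed == 1

    def test_large_gap_terminates(self, rng):
        n = 50
        d_minus = np.full(n, n - 1)
        d_plus = np.ones(n, dtype=int)
        pair = balance(d_minus, d_plus, rng)
        assert pair.d_minus.sum() == pair.d_plus.sum()


class TestGenerateRvdp:
    @pytest.mark.parametrize("n", [2, 3, 10, 100, 1000])
    def test_invariants_over_many_seeds(self, n, make_rng):
        draws = 1000 if n <= 100 else 200
        for seed in range(draws):
            pair = generate_rvdp(n, make_rng(seed))
            assert pair.d_minus.sum() == pair.d_plus.sum()
            for arr in (pair.d_minus, pair.d_plus):
                assert np.all(np.diff(arr) >= 0)
                assert arr.min() >= 1 and arr.max() <= n - 1

    def test_n2_is_forced(self, make_rng):
        """At N=2 the entry clamp [1, N-1] pins both plots to all-ones."""
        for seed in range(20):
            pair = generate_rvdp(2, make_rng(seed))
            assert pair.d_minus.tolist() == [1, 1]
            assert pair.d_plus.tolist() == [1, 1]

    def test_rejects_tiny_n(self, rng):
        with pytest.raises(ValueError):
            generate_rvdp(1, rng)

    def test_prebalance_gap_bound(self, make_rng):
        """Rounding two equal-area lines misaligns sums by at most 3N."""
        n = 100
        for seed in range(300):
            line1, line2 = sample_line_pair(n, make_rng(seed))
            gap = abs(int(discretize(line1).sum()) - int(discretize(line2).sum()))
            assert gap <= 3 * n

    def test_density_coverage(self, make_rng):
        """Sampled plot pairs reach sparse, intermediate and dense regimes."""
        densities = [generate_rvdp(100, make_rng(seed)).density for seed in range(1000)]
        densities = np.array(densities)
        assert (densities < 1 / 3).any()
        assert ((densities >= 1 / 3) & (densities < 2 / 3)).any()
        assert (densities >= 2 / 3).any()

    def test_near_linear_scaling(self):
        """Ten times the vertices should cost well under thirty times the time."""
        rng = np.random.default_rng(0)
        generate_rvdp(1000, rng)  # warm up
        t0 = time.perf_counter()
        for _ in range(20):
            generate_rvdp(1000, rng)
        t_small = time.perf_counter() - t0
        t0 = time.perf_counter()
        for _ in range(20):
            generate_rvdp(10_000, rng)
        t_large = time.perf_counter() - t0
        assert t_large < 30 * max(t_small, 1e-3)


class TestReferencePlotPair:
    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            ReferencePlotPair(3, np.array([2, 1, 2]), np.array([1, 2, 2]))

    def test_rejects_unequal_sums(self):
        with pytest.raises(ValueError):
            ReferencePlotPair(3, np.array([1, 1, 1]), np.array([1, 1, 2]))

    def test_rejects_out_of_range_entries(self):
        with pytest.raises(ValueError):
            ReferencePlotPair(3, np.array([0, 1, 2]), np.array([1, 1, 1]))

    def test_density_bounds(self, make_rng):
        for seed in range(50):
            pair = generate_rvdp(20, make_rng(seed))
            assert 20 <= pair.total_degree <= 20 * 19
            assert 0 < pair.density <= 1
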