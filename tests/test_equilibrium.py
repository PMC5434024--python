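"""Best response, Nash/ESS, Pareto and the auxiliary certificates."""

import math

import numpy as np
import pytest

from conftest import (
    REF,
    draw_regime_params,
    draw_valid_params,
    golden_section_max,
    regime_threshold,
)
from socialbandit import (
    ModelParams,
    StrategyProfile,
    auxiliary_points,
    best_response,
    best_response_unclamped,
    fitness_closed,
    fitness_ordering,
    fixed_point_cells,
    pareto_closed,
    response_map,
    solve,
    solve_nash_bisection,
    solve_nash_closed,
    solve_nash_fixed_point,
    verify_ess,
)
from socialbandit.equilibrium import g_unclamped


class TestBestResponse:
    def test_zero_when_copying_no_better(self):
        p = ModelParams(10, 0.2, 0.5, 0.4)
        for rbar in (0.0, 0.5, 0.9):
            assert best_response(p, rbar) == 0.0

    def test_zero_beyond_upper_crossing(self, ref_params):
        aux = auxiliary_points(ref_params)
        assert abs(best_response_unclamped(ref_params, aux.r_star_hi)) < 1e-12
        for rbar in np.linspace(aux.r_star_hi, 0.999, 10):
            assert best_response(ref_params, float(rbar)) == 0.0

    def test_non_increasing(self, ref_params):
        grid = np.linspace(0.0, 1.0, 200)
        vals = [best_response(ref_params, float(g)) for g in grid]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_matches_brute_force_argmax(self, ref_params):
        # dense grid + local golden refinement of r -> w(r, rbar)
        for rbar in (0.0, 0.2, 0.5, 0.7, 0.9):
            grid = np.linspace(0.0, 1.0 - 1e-9, 2001)
            vals = [fitness_closed(ref_params, float(r), rbar) for r in grid]
            i = int(np.argmax(vals))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            r_best = golden_section_max(
                lambda r: fitness_closed(ref_params, r, rbar), lo, hi, tol=1e-12
            )
            assert abs(best_response(ref_params, rbar) - r_best) < 1e-6

    def test_vanishes_as_advantage_closes(self):
        # f -> 0 as q_O approaches q_I from above
        prev = math.inf
        for k in range(1, 7):
            p = ModelParams(10, 0.2, 0.3, 0.3 + 10.0**-k)
            peak = max(best_response(p, float(g)) for g in np.linspace(0, 0.99, 50))
            assert peak <= prev + 1e-12
            prev = peak
        assert prev < 1e-3


class TestResponseMap:
    def test_nash_profile_is_fixed_point(self, ref_params):
        r_nash, _, _ = solve_nash_closed(ref_params)
        prof = StrategyProfile.homogeneous(r_nash, ref_params.N)
        out = response_map(ref_params, prof)
        assert np.max(np.abs(out - r_nash)) < 1e-8

    def test_zero_map_when_copying_no_better(self):
        p = ModelParams(6, 0.2, 0.6, 0.5)
        prof = StrategyProfile(np.linspace(0.0, 0.9, 6))
        assert np.all(response_map(p, prof) == 0.0)

    def test_permutation_equivariance(self, ref_params):
        rng = np.random.default_rng(2)
        r = rng.uniform(0, 0.95, ref_params.N)
        perm = rng.permutation(ref_params.N)
        out = response_map(ref_params, StrategyProfile(r))
        out_perm = response_map(ref_params, StrategyProfile(r[perm]))
        assert np.allclose(out_perm, out[perm], atol=1e-14)


class TestNashSolvers:
    def test_reference_value(self, ref_params):
        r_nash, eta, D1 = solve_nash_closed(ref_params)
        assert r_nash == pytest.approx(0.70883, abs=1e-5)
        assert eta == pytest.approx(1.0 - r_nash, abs=1e-12)
        assert D1 > 0

    def test_outside_regime_is_zero(self):
        # (q_O - q_I) N = 0.5 <= a + q_O ~ 1.004
        p = ModelParams(10, 0.2, 0.75, 0.8)
        assert solve_nash_closed(p)[0] == 0.0
        assert solve_nash_bisection(p) == 0.0

    def test_three_solvers_agree(self, ref_params):
        r_closed, _, _ = solve_nash_closed(ref_params)
        assert abs(solve_nash_bisection(ref_params) - r_closed) < 1e-8
        assert abs(solve_nash_fixed_point(ref_params) - r_closed) < 1e-8

    def test_agreement_over_regime_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p = draw_regime_params(rng)
            r_closed, _, _ = solve_nash_closed(p)
            assert abs(solve_nash_bisection(p) - r_closed) < 1e-8
            assert abs(solve_nash_fixed_point(p) - r_closed) < 1e-8

    def test_continuous_vanishing_at_boundary(self):
        # r_Nash -> 0 as the regime margin closes from above
        thr = regime_threshold(10, 0.2, 0.8)
        values = [
            solve_nash_closed(ModelParams(10, 0.2, thr - eps, 0.8))[0]
            for eps in (0.1, 0.03, 0.01, 0.003, 0.001)
        ]
        assert all(b < a for a, b in zip(values, values[1:]))
        assert values[-1] < 0.02

    def test_two_agent_grid_scan_single_fixed_point(self):
        p = ModelParams(2, 0.1, 0.1, 0.8)
        cells = fixed_point_cells(p, grid_size=201)
        assert len(cells) == 1
        r_nash, _, _ = solve_nash_closed(p)
        i, j = cells[0]
        step = 1.0 / 200
        assert abs(i * step - r_nash) < 1e-3 + step
        assert abs(j * step - r_nash) < 1e-3 + step


class TestPareto:
    def test_reference_value_against_golden_section(self, ref_params):
        r_closed, X, Y = pareto_closed(ref_params)
        r_golden = golden_section_max(
            lambda r: fitness_closed(ref_params, r, r), 0.0, 1.0 - 1e-9
        )
        assert r_closed == pytest.approx(0.4780494, abs=1e-6)
        assert abs(r_closed - r_golden) < 1e-8
        assert X > 0 and Y > 0

    def test_outside_regime_is_zero(self):
        assert pareto_closed(ModelParams(10, 0.2, 0.75, 0.8))[0] == 0.0

    def test_below_nash_over_regime_draws(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = draw_regime_params(rng)
            assert pareto_closed(p)[0] < solve_nash_closed(p)[0]

    def test_golden_agreement_over_regime_draws(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            p = draw_regime_params(rng)
            r_closed, _, _ = pareto_closed(p)
            r_golden = golden_section_max(
                lambda r: fitness_closed(p, r, r), 0.0, 1.0 - 1e-9
            )
            assert abs(r_closed - r_golden) < 1e-8

    def test_diagonal_grid_maximum_near_closed_form(self, ref_params):
        grid = np.linspace(0.0, 1.0 - 1e-9, 1001)
        vals = [fitness_closed(ref_params, float(r), float(r)) for r in grid]
        r_grid = grid[int(np.argmax(vals))]
        assert abs(r_grid - pareto_closed(ref_params)[0]) <= grid[1] - grid[0]

    def test_two_agent_welfare_peaks_on_diagonal(self):
        # total fitness over the (r_1, r_2) square is maximised at the
        # diagonal Pareto point
        p = ModelParams(2, 0.1, 0.1, 0.8)
        r_pareto, _, _ = pareto_closed(p)
        grid = np.linspace(0.0, 1.0 - 1e-9, 201)
        best, arg = -np.inf, None
        for r1 in grid:
            for r2 in grid:
                tot = fitness_closed(p, float(r1), float(r2)) + fitness_closed(
                    p, float(r2), float(r1)
                )
                if tot > best:
                    best, arg = tot, (r1, r2)
        step = grid[1] - grid[0]
        assert abs(arg[0] - r_pareto) <= step + 1e-12
        assert abs(arg[1] - r_pareto) <= step + 1e-12


class TestAuxiliaryCurves:
    def test_crossing_points_ordered(self, ref_params):
        aux = auxiliary_points(ref_params)
        assert aux.r_star_lo < aux.r_star_hi < 1.0
        # fbar crosses 1 at the lower point and 0 at the upper point
        assert abs(best_response_unclamped(ref_params, aux.r_star_lo) - 1.0) < 1e-9
        assert abs(best_response_unclamped(ref_params, aux.r_star_hi)) < 1e-12

    def test_individual_equivalent_point(self, ref_params):
        aux = auxiliary_points(ref_params)
        assert aux.r_I == pytest.approx(1.0 - 1.0040816 / 5.0, abs=1e-6)
        w_I = ref_params.q_I / (ref_params.a + ref_params.q_I)
        assert abs(fitness_closed(ref_params, aux.r_I, aux.r_I) - w_I) < 1e-12

    def test_quadratic_root_certificates(self, ref_params):
        aux = auxiliary_points(ref_params)
        r_nash, _, _ = solve_nash_closed(ref_params)
        r_pareto, _, _ = pareto_closed(ref_params)
        u_nash = 1.0 / (1.0 - r_nash)
        assert abs(aux.k(u_nash)) < 1e-8
        # larger of the two roots: k is positive beyond it
        assert aux.k(u_nash + 0.1) > 0
        assert aux.k(1.0) < 0
        assert aux.k(1.0 / (1.0 - aux.r_I)) > 0
        assert aux.k(1.0 / (1.0 - r_pareto)) < 0

    def test_certificates_over_regime_draws(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            p = draw_regime_params(rng)
            aux = auxiliary_points(p)
            r_nash, _, _ = solve_nash_closed(p)
            r_pareto, _, _ = pareto_closed(p)
            assert aux.r_star_lo < aux.r_star_hi < 1.0
            assert abs(aux.k(1.0 / (1.0 - r_nash))) < 1e-6 * max(
                1.0, abs(aux.k(0.0))
            )
            assert aux.k(1.0) < 0
            assert aux.k(1.0 / (1.0 - aux.r_I)) > 0
            assert aux.k(1.0 / (1.0 - r_pareto)) < 0
            assert r_pareto < r_nash < aux.r_I

    def test_self_consistency_map_slope_bounded(self, ref_params):
        # slope of g never exceeds 1/2 on the clamp-free band
        aux = auxiliary_points(ref_params)
        s = ref_params.N * solve_nash_closed(ref_params)[0]
        lo, hi = aux.g_domain(s)
        h = 1e-7
        for r in np.linspace(lo, hi, 400):
            d = (
                g_unclamped(ref_params, s, float(r) + h)
                - g_unclamped(ref_params, s, float(r) - h)
            ) / (2 * h)
            assert d >= -1e-9
            assert d <= 0.5 + 1e-3

    def test_undefined_without_copy_advantage(self):
        aux = auxiliary_points(ModelParams(10, 0.2, 0.6, 0.5))
        assert not aux.defined


class TestESSCertificate:
    def test_reference_parameters_pass(self, ref_params):
        cert = verify_ess(ref_params, grid_size=1001)
        assert cert.passed
        assert cert.worst_slack_nash > 1e-9
        assert cert.worst_slack_ess > 1e-9

    def test_slack_vanishes_at_equilibrium(self, ref_params):
        r_nash, _, _ = solve_nash_closed(ref_params)
        assert (
            fitness_closed(ref_params, r_nash, r_nash)
            - fitness_closed(ref_params, r_nash, r_nash)
            == 0.0
        )

    def test_zero_equilibrium_weak_inequality(self):
        # without a copy advantage the equilibrium is r = 0 and staying
        # asocial is weakly optimal against any deviant population
        p = ModelParams(10, 0.2, 0.6, 0.5)
        for r in np.linspace(0.0, 0.99, 101):
            assert fitness_closed(p, 0.0, float(r)) >= fitness_closed(
                p, float(r), float(r)
            ) - 1e-12


class TestFitnessOrdering:
    def test_reference_values(self, ref_params):
        w_P, w_N, w_I, regime = fitness_ordering(ref_params)
        assert regime
        assert w_I == pytest.approx(0.59514, abs=1e-5)
        assert w_N == pytest.approx(0.63718, abs=1e-5)
        assert w_P == pytest.approx(0.66603, abs=1e-5)
        assert w_P > w_N > w_I

    def test_collapse_outside_regime(self):
        p = ModelParams(10, 0.2, 0.75, 0.8)
        w_P, w_N, w_I, regime = fitness_ordering(p)
        assert not regime
        assert w_P == w_N == w_I == pytest.approx(p.q_I / (p.a + p.q_I))

    def test_strict_ordering_iff_regime(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            N = int(rng.integers(2, 11))
            q_C = float(rng.uniform(0.05, 0.8))
            q_O = float(rng.uniform(0.3, 1.0))
            thr = regime_threshold(N, q_C, q_O)
            if thr <= 0.02:
                continue
            # straddle the boundary
            side = rng.choice([-1.0, 1.0])
            q_I = float(np.clip(thr * (1.0 + 0.2 * side * rng.uniform(0.1, 1)), 1e-3, 1.0))
            p = ModelParams(N, q_C, q_I, q_O)
            w_P, w_N, w_I, regime = fitness_ordering(p)
            if regime:
                assert w_P > w_N > w_I
            else:
                assert w_P == w_N == w_I

    def test_full_solution_consistency(self, ref_params):
        sol = solve(ref_params)
        assert sol.regime
        assert sol.r_pareto < sol.r_nash < sol.r_I
        d = sol.to_dict()
        assert set(d) >= {"r_Nash", "eta", "D1", "r_Pareto", "X", "Y", "r_I", "regime"}
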