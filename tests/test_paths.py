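"""Path functionals, builders, reparameterization and 2D optimization."""

import numpy as np
import pytest

from alchemetric.fixtures import channel_field
from alchemetric.metrics import MetricEstimate
from alchemetric.paths import (
    LambdaPath,
    build_sequential_path,
    build_simultaneous_path,
    build_three_leg_path,
    improvement_factor,
    optimal_target,
    optimize_path_2d,
    path_diagnostics,
    path_length,
    reparameterize_path,
    variance_functional,
)


def line_path(n=201):
    lam = np.linspace(0, 1, n)
    return LambdaPath(lambdas=lam[:, None], s=lam)


def quadratic_metric(l):
    return (1.0 + l) ** 2


class TestPathLength:
    def test_constant_metric(self):
        assert path_length(line_path(), lambda l: 4.0) == pytest.approx(2.0, rel=1e-12)

    def test_quadratic_metric_closed_form(self):
        # integral of (1 + lambda) over [0, 1] = 3/2
        assert path_length(line_path(201), quadratic_metric) == pytest.approx(1.5, abs=1e-3)

    def test_concatenation_additivity(self):
        lam = np.linspace(0, 1, 101)
        full = path_length(line_path(101), quadratic_metric)
        left = LambdaPath(lambdas=lam[:51, None] * 2, s=np.linspace(0, 1, 51))   # 0 -> 1 over half
        # additivity over a split of the same polyline
        mid = 50
        p1 = LambdaPath(lambdas=lam[: mid + 1, None], s=np.linspace(0, 1, mid + 1))
        p2 = LambdaPath(lambdas=lam[mid:, None], s=np.linspace(0, 1, 101 - mid))
        assert path_length(p1, quadratic_metric) + path_length(p2, quadratic_metric) == \
            pytest.approx(full, rel=1e-12)

    def test_negative_metric_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            path_length(line_path(11), lambda l: -1.0)


class TestVarianceFunctional:
    def test_constant_metric_uniform_target(self):
        v, var = variance_functional(line_path(), lambda l: 3.0, total_time=10.0)
        assert v == pytest.approx(3.0, rel=1e-12)
        assert var == pytest.approx(2 * 3.0 / 10.0, rel=1e-12)

    def test_quadratic_metric_uniform_target(self):
        v, _ = variance_functional(line_path(201), quadratic_metric)
        assert v == pytest.approx(7.0 / 3.0, abs=1e-3)

    def test_equality_at_optimal_segment_target_is_exact(self):
        # per-segment masses p_i ~ l_i saturate the discrete bound identically
        path = line_path(101)
        v, _ = variance_functional(path, quadratic_metric, target="optimal")
        length = path_length(path, quadratic_metric)
        assert v == pytest.approx(length**2, rel=1e-12)

    def test_equality_at_optimal_point_density_within_discretization(self):
        path = line_path(101)
        pi = optimal_target(path, quadratic_metric)
        v, _ = variance_functional(path, quadratic_metric, target=pi)
        length = path_length(path, quadratic_metric)
        assert v == pytest.approx(length**2, rel=1e-6)

    def test_vanishing_target_rejected(self):
        pi = np.ones(201)
        pi[100:102] = 0.0   # a whole segment with zero mass
        with pytest.raises(ValueError, match="target"):
            variance_functional(line_path(201), quadratic_metric, target=pi)


class TestOptimalTarget:
    def test_constant_metric_gives_uniform(self):
        pi = optimal_target(line_path(51), lambda l: 2.0)
        np.testing.assert_allclose(pi, 1.0, rtol=1e-12)

    def test_quadratic_metric_closed_form(self):
        path = line_path(201)
        pi = optimal_target(path, quadratic_metric)
        expected = (1 + path.lambdas[:, 0]) / 1.5
        np.testing.assert_allclose(pi[1:-1], expected[1:-1], rtol=1e-3)

    def test_invariant_to_metric_scaling(self):
        path = line_path(51)
        pi1 = optimal_target(path, quadratic_metric)
        pi7 = optimal_target(path, lambda l: 7.0 * quadratic_metric(l))
        np.testing.assert_allclose(pi1, pi7, rtol=1e-12)


class TestImprovementFactor:
    def test_constant_metric_is_one(self):
        assert improvement_factor(line_path(), lambda l: 5.0) == pytest.approx(1.0, rel=1e-12)

    def test_quadratic_metric_closed_form(self):
        # L^2 / V_unif = 1.5^2 / (7/3) = 27/28
        assert improvement_factor(line_path(401), quadratic_metric) == \
            pytest.approx(27 / 28, abs=1e-3)

    def test_degenerate_metric_limit(self):
        # g = lambda^2 + eps, eps -> 0: L = 1/2, V = 1/3, IF -> 3/4
        assert improvement_factor(line_path(2001), lambda l: l**2 + 1e-12) == \
            pytest.approx(0.75, abs=2e-3)

    def test_bounded_by_one_for_random_profiles(self, rng):
        for _ in range(50):
            vals = rng.uniform(0.1, 5.0, size=31)
            metric = lambda l, v=vals: np.interp(l, np.linspace(0, 1, 31), v)
            assert improvement_factor(line_path(31), metric) <= 1.0 + 1e-12


class TestCauchySchwarz:
    def test_bound_and_equality_over_random_profiles(self):
        # V(pi) >= L^2 for any target; equality at pi ~ sqrt(g)
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 60)
            vals = rng.uniform(0.01, 10.0, size=n)
            path = line_path(n)
            metric = lambda l, v=vals, m=n: np.interp(l, np.linspace(0, 1, m), v)
            pi = rng.uniform(0.05, 1.0, size=n)
            v, _ = variance_functional(path, metric, target=pi)
            length = path_length(path, metric)
            assert v >= length**2 * (1 - 1e-6)
            v_opt, _ = variance_functional(path, metric, target="optimal")
            assert v_opt == pytest.approx(length**2, rel=1e-9)


class TestBuilders:
    def test_simultaneous_spacing(self):
        path = build_simultaneous_path(21, 2)
        assert path.n_points == 21
        np.testing.assert_allclose(np.diff(path.lambdas[:, 0]), 0.05)
        np.testing.assert_array_equal(path.lambdas[0], [0, 0])
        np.testing.assert_array_equal(path.lambdas[-1], [1, 1])

    def test_simultaneous_two_points(self):
        path = build_simultaneous_path(2, 3)
        np.testing.assert_array_equal(path.lambdas, [[0, 0, 0], [1, 1, 1]])

    def test_sequential_21_points_two_dims(self):
        # one leg per component with a shared corner: 11 + 11 - 1 points
        path = build_sequential_path(21, n_dims=2)
        assert path.n_points == 21
        corner = np.array([1.0, 0.0])
        assert any(np.allclose(l, corner) for l in path.lambdas)
        leg1 = path.lambdas[:11]
        np.testing.assert_allclose(leg1[:, 1], 0.0)
        np.testing.assert_allclose(np.diff(leg1[:, 0]), 0.1)

    def test_sequential_one_dim_equals_simultaneous(self):
        a = build_sequential_path(11, component_order=[0])
        b = build_simultaneous_path(11, 1)
        np.testing.assert_allclose(a.lambdas, b.lambdas)

    def test_three_leg_channel(self):
        path = build_three_leg_path(0.5, 21)
        assert path.n_points == 21
        # the middle leg sits on the channel line
        on_channel = np.isclose(path.lambdas[:, 0], 0.5)
        assert on_channel.sum() >= 8
        np.testing.assert_array_equal(path.lambdas[0], [0, 0])
        np.testing.assert_array_equal(path.lambdas[-1], [1, 1])

    def test_three_leg_degenerates_to_sequential_at_zero_channel(self):
        path = build_three_leg_path(0.0, 21)
        assert path.n_points == 21
        # no first leg: path moves along lambda_other first, then lambda_coulomb
        assert np.isclose(path.lambdas[0], [0, 0]).all()
        mask_first = path.lambdas[:, 0] == 0.0
        assert mask_first.sum() >= 10

    @pytest.mark.parametrize("n", [4, 7, 21, 41])
    def test_three_leg_point_count_exact(self, n):
        assert build_three_leg_path(0.5, n).n_points == n


class TestReparameterize:
    def test_constant_metric_unchanged(self):
        path = line_path(11)
        new = reparameterize_path(path, lambda l: 2.5)
        np.testing.assert_allclose(new.lambdas, path.lambdas, atol=1e-12)

    def test_quadratic_metric_closed_form_inversion(self):
        # cumulative length (l + l^2/2)/1.5 = u inverts to l = sqrt(1+3u) - 1
        path = line_path(2001)
        new = reparameterize_path(path, quadratic_metric)
        u = 0.5
        idx = np.argmin(np.abs(new.s - u))
        assert new.lambdas[idx, 0] == pytest.approx(np.sqrt(2.5) - 1.0, abs=1e-3)

    def test_endpoints_fixed(self):
        path = line_path(31)
        new = reparameterize_path(path, quadratic_metric)
        np.testing.assert_array_equal(new.lambdas[0], path.lambdas[0])
        np.testing.assert_array_equal(new.lambdas[-1], path.lambdas[-1])

    def test_equalizes_segment_lengths(self):
        from alchemetric.paths import segment_lengths

        path = line_path(101)
        new = reparameterize_path(path, quadratic_metric)
        ell = segment_lengths(new, quadratic_metric)
        assert ell.std() / ell.mean() < 0.02


# ---------------------------------------------------------------------------
# 2D shortest-path optimization with a brute-force oracle
# ---------------------------------------------------------------------------

def random_spd_field(rng, n1, n2):
    lams = np.array([(a, b) for a in np.linspace(0, 1, n1)
                     for b in np.linspace(0, 1, n2)])
    tensors = np.empty((n1 * n2, 2, 2))
    for i in range(n1 * n2):
        theta = rng.uniform(0, np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        eig = np.diag(rng.uniform(0.05, 4.0, size=2))
        tensors[i] = rot @ eig @ rot.T
    est = MetricEstimate(lambdas=lams, values=tensors,
                         stderr=np.full_like(tensors, np.nan), kind="friction")
    est.grid_shape = (n1, n2)
    return est


def brute_force_shortest(field, start=(0, 0), end=None):
    """Exhaustive DFS over all simple 8-connected paths with cost pruning."""
    n1, n2 = field.grid_shape
    end = end or (n1 - 1, n2 - 1)
    lams = field.lambdas.reshape(n1, n2, 2)
    tensors = field.values.reshape(n1, n2, 2, 2)
    moves = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]

    def edge(a, b):
        dl = lams[b] - lams[a]
        g = 0.5 * (tensors[a] + tensors[b])
        return float(np.sqrt(max(dl @ g @ dl, 0.0)))

    best = [np.inf]
    visited = {start}

    def dfs(node, cost):
        if cost >= best[0]:
            return
        if node == end:
            best[0] = cost
            return
        for di, dj in moves:
            nxt = (node[0] + di, node[1] + dj)
            if 0 <= nxt[0] < n1 and 0 <= nxt[1] < n2 and nxt not in visited:
                visited.add(nxt)
                dfs(nxt, cost + edge(node, nxt))
                visited.remove(nxt)

    dfs(start, 0.0)
    return best[0]


class TestOptimizePath2D:
    def test_uniform_isotropic_field_diagonal_cost(self, rng):
        n = 5
        lams = np.array([(a, b) for a in np.linspace(0, 1, n)
                         for b in np.linspace(0, 1, n)])
        c = 2.0
        tensors = np.tile(c * np.eye(2), (n * n, 1, 1))
        field = MetricEstimate(lambdas=lams, values=tensors,
                               stderr=np.full_like(tensors, np.nan), kind="friction")
        field.grid_shape = (n, n)
        path, cost = optimize_path_2d(field)
        assert cost == pytest.approx(np.sqrt(2 * c), rel=1e-9)

    def test_matches_brute_force_on_random_fields(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            field = random_spd_field(rng, 4, 4)
            _, cost = optimize_path_2d(field)
            oracle = brute_force_shortest(field)
            assert cost == pytest.approx(oracle, abs=1e-10)

    def test_scaling_field_scales_cost_not_path(self, rng):
        field = random_spd_field(rng, 5, 5)
        path1, cost1 = optimize_path_2d(field)
        scaled = MetricEstimate(lambdas=field.lambdas, values=7.0 * field.values,
                                stderr=field.stderr, kind="friction")
        scaled.grid_shape = field.grid_shape
        path2, cost2 = optimize_path_2d(scaled)
        assert cost2 == pytest.approx(np.sqrt(7.0) * cost1, rel=1e-9)
        np.testing.assert_allclose(path1.lambdas, path2.lambdas)

    def test_channel_field_beats_diagonal(self):
        field = channel_field(11, 11)
        path, cost = optimize_path_2d(field)
        diag = build_simultaneous_path(11, 2)
        diag_cost = path_length(diag, field)
        assert cost < diag_cost
        # the optimized path rides the low-metric channel row
        assert np.isclose(path.lambdas[:, 0], 0.5).sum() >= 5

    def test_two_lambda_toy_field_beats_diagonal(self):
        from alchemetric.fixtures import two_lambda_tensor_field

        field = two_lambda_tensor_field(11, 11)
        path, cost = optimize_path_2d(field)
        assert cost < path_length(build_simultaneous_path(11, 2), field)

    def test_band_constraint_disconnected_region_errors(self, rng):
        field = random_spd_field(rng, 5, 5)
        vals = field.values.reshape(5, 5, 2, 2)
        vals[2, :, :, :] = np.nan  # impassable wall
        field.values = vals.reshape(25, 2, 2)
        with pytest.raises(ValueError, match="disconnected"):
            optimize_path_2d(field)

    def test_optimized_cost_bounded_by_standard_paths(self):
        field = channel_field(11, 11)
        _, cost = optimize_path_2d(field)
        for candidate in (build_simultaneous_path(11, 2),
                          build_sequential_path(21, n_dims=2),
                          build_three_leg_path(0.5, 21)):
            assert cost <= path_length(candidate, field) + 1e-9


class TestGridRefinement:
    def test_smooth_field_length_stable_under_refinement(self):
        coarse = path_length(line_path(26), quadratic_metric)
        fine = path_length(line_path(51), quadratic_metric)
        assert abs(fine - coarse) / fine < 0.02


class TestDiagnostics:
    def test_bundle_consistency(self):
        path = line_path(101)
        diag = path_diagnostics(path, quadratic_metric, total_time=20.0)
        assert diag.improvement_factor == pytest.approx(
            diag.length**2 / diag.v_uniform, rel=1e-12)
        assert 0 < diag.improvement_factor <= 1
        assert diag.var_estimate == pytest.approx(2 * diag.v_target / 20.0)


def test_lambda_path_validation():
    with pytest.raises(ValueError, match="at least two"):
        LambdaPath(lambdas=np.array([[0.0]]))
    with pytest.raises(ValueError, match="increase strictly"):
        LambdaPath(lambdas=np.zeros((3, 1)), s=np.array([0.0, 0.7, 0.6]))
    with pytest.raises(ValueError, match="increase strictly"):
        LambdaPath(lambdas=np.zeros((2, 1)), s=np.array([0.1, 1.0]))
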