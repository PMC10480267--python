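"""Sampler behavior: Langevin stationary law, λ Gibbs moves, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from alchemetric.awh import init_bias
from alchemetric.metrics import integrated_correlation
from alchemetric.sampling import (
    ForceSeries,
    SamplerSettings,
    SimulationError,
    lambda_conditional_weights,
    lambda_gibbs_move,
    langevin_step,
    run_expanded_ensemble,
    run_fixed_lambda,
)
from alchemetric.systems import AlchemicalSystem


class FlatSystem(AlchemicalSystem):
    """Zero-gradient, λ-independent system (free particle on a table)."""

    n_lambda_dims = 1

    def energy(self, x, lam):
        return 0.0

    def dhdlambda(self, x, lam):
        return np.zeros(1)

    def gradient(self, x, lam):
        return np.zeros_like(x)

    def initial_configuration(self, rng):
        return rng.standard_normal(1)

    def energy_grid(self, x, lambda_grid):
        return np.zeros(len(lambda_grid))


class TabulatedSystem(AlchemicalSystem):
    """x-independent energies per λ point, for enumerable weight checks."""

    n_lambda_dims = 1

    def __init__(self, energies):
        self.energies = np.asarray(energies, dtype=float)

    def energy(self, x, lam):
        raise NotImplementedError

    def dhdlambda(self, x, lam):
        return np.zeros(1)

    def gradient(self, x, lam):
        return np.zeros_like(x)

    def initial_configuration(self, rng):
        return np.zeros(1)

    def energy_grid(self, x, lambda_grid):
        return self.energies.copy()


class _ZeroNoise:
    def standard_normal(self, shape):
        return np.zeros(shape)


class TestLangevinStep:
    def test_zero_gradient_zero_noise_keeps_position(self, thermo):
        system = FlatSystem()
        settings = SamplerSettings()
        x = np.array([0.7])
        out = langevin_step(x, system, 0.0, settings, thermo, _ZeroNoise())
        np.testing.assert_array_equal(out, x)

    def test_nonfinite_force_aborts(self, thermo):
        class BadSystem(FlatSystem):
            def gradient(self, x, lam):
                return np.array([np.nan])

        with pytest.raises(SimulationError, match="non-finite force"):
            langevin_step(np.zeros(1), BadSystem(), 0.0, SamplerSettings(), thermo,
                          np.random.default_rng(0))

    def test_harmonic_stationary_variance(self, harmonic, thermo):
        # long run at fixed lambda=0 (k=1): Var x -> 1/(beta k) within 3 SE
        settings = SamplerSettings(timestep=0.005, n_steps=400000, seed=4)
        rng = np.random.default_rng(4)
        noise = rng.standard_normal((settings.n_steps, 1)) * np.sqrt(
            2 * settings.timestep / (thermo.beta * settings.friction_gamma)
        )
        xs = harmonic.simulate_block(np.zeros(1), 0.0, noise, settings.timestep)
        x = xs[20000::10, 0]
        var = x.var()
        k = 1.0
        tau_steps = 0.5 * settings.friction_gamma / k / (0.005 * 10)  # x^2 corr time
        se = var * np.sqrt(2 * (2 * tau_steps + 1) / len(x))
        assert abs(var - 1.0 / (thermo.beta * k)) < 3 * se + 0.01

    def test_harmonic_autocorrelation_time(self, harmonic, thermo):
        # OU closed form: integrated autocorrelation of x equals gamma/k
        settings = SamplerSettings(timestep=0.005, n_steps=800000, seed=9)
        rng = np.random.default_rng(9)
        k, lam = 4.0, 1.0
        noise = rng.standard_normal((settings.n_steps, 1)) * np.sqrt(2 * settings.timestep)
        xs = harmonic.simulate_block(np.zeros(1), lam, noise, settings.timestep)
        x = xs[10000::2, 0]
        tau = integrated_correlation(x, x, dt=0.005 * 2) / x.var()
        assert tau == pytest.approx(settings.friction_gamma / k, rel=0.15)


class TestConditionalWeights:
    def test_uniform_for_lambda_independent_system(self, thermo):
        bias = init_bias(np.linspace(0, 1, 5), thermo=thermo)
        w = lambda_conditional_weights(np.zeros(1), FlatSystem(), bias, thermo)
        np.testing.assert_allclose(w, 0.2)

    def test_two_point_hand_value(self, thermo):
        system = TabulatedSystem([0.0, np.log(3.0)])
        bias = init_bias(np.array([0.0, 1.0]), thermo=thermo)
        w = lambda_conditional_weights(np.zeros(1), system, bias, thermo)
        np.testing.assert_allclose(w, [0.75, 0.25], rtol=1e-12)

    def test_normalization_for_random_inputs(self, thermo, rng):
        for _ in range(20):
            system = TabulatedSystem(rng.normal(0, 5, size=7))
            bias = init_bias(np.linspace(0, 1, 7), thermo=thermo)
            bias.f[:] = rng.normal(0, 3, size=7)
            w = lambda_conditional_weights(np.zeros(1), system, bias, thermo)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0)

    def test_gauge_invariance_under_constant_f_shift(self, thermo, rng):
        system = TabulatedSystem(rng.normal(0, 2, size=6))
        bias = init_bias(np.linspace(0, 1, 6), thermo=thermo)
        bias.f[:] = rng.normal(size=6)
        w1 = lambda_conditional_weights(np.zeros(1), system, bias, thermo)
        bias.f += 123.4
        w2 = lambda_conditional_weights(np.zeros(1), system, bias, thermo)
        np.testing.assert_allclose(w1, w2, rtol=1e-12)


class TestGibbsMove:
    def test_deterministic_when_one_weight_dominates(self, thermo):
        system = TabulatedSystem([0.0, 200.0, 300.0])
        bias = init_bias(np.linspace(0, 1, 3), thermo=thermo)
        rng = np.random.default_rng(0)
        idx = [lambda_gibbs_move(np.zeros(1), bias, system, thermo, rng) for _ in range(50)]
        assert set(idx) == {0}

    def test_seed_reproducibility(self, thermo):
        system = TabulatedSystem([0.0, 0.5, 1.0])
        bias = init_bias(np.linspace(0, 1, 3), thermo=thermo)
        seq1 = [lambda_gibbs_move(np.zeros(1), bias, system, thermo, np.random.default_rng(5))
                for _ in range(1)]
        seq2 = [lambda_gibbs_move(np.zeros(1), bias, system, thermo, np.random.default_rng(5))
                for _ in range(1)]
        assert seq1 == seq2

    def test_frozen_bias_visit_frequencies(self, thermo):
        # chi^2 of empirical visits against the exact conditional, 10 seeds pooled
        energies = np.array([0.0, 0.7, 1.5, 0.3])
        system = TabulatedSystem(energies)
        bias = init_bias(np.linspace(0, 1, 4), thermo=thermo)
        w = lambda_conditional_weights(np.zeros(1), system, bias, thermo)
        counts = np.zeros(4)
        n_draws = 500
        for seed in range(10):
            rng = np.random.default_rng(seed)
            for _ in range(n_draws):
                counts[lambda_gibbs_move(np.zeros(1), bias, system, thermo, rng)] += 1
        total = counts.sum()
        chi2 = float(np.sum((counts - total * w) ** 2 / (total * w)))
        p = 1.0 - stats.chi2.cdf(chi2, df=3)
        assert p > 0.01

    def test_detailed_balance_on_three_point_grid(self, thermo):
        # independence sampler from the exact conditional: T(i->j) = w_j,
        # stationary p = w, so p_i T(i->j) = w_i w_j = p_j T(j->i) identically
        system = TabulatedSystem([0.0, 1.1, 0.4])
        bias = init_bias(np.linspace(0, 1, 3), thermo=thermo)
        bias.f[:] = [0.0, 0.3, -0.2]
        w = lambda_conditional_weights(np.zeros(1), system, bias, thermo)
        transition = np.tile(w, (3, 1))
        stationary = w
        for i in range(3):
            for j in range(3):
                assert stationary[i] * transition[i, j] == pytest.approx(
                    stationary[j] * transition[j, i], rel=1e-12
                )


class TestRunFixedLambda:
    def test_empty_grid_errors(self, harmonic, thermo):
        with pytest.raises(ValueError, match="nonempty"):
            run_fixed_lambda(harmonic, np.empty((0, 1)), SamplerSettings(), thermo)

    def test_seed_reproducibility(self, harmonic, thermo):
        settings = SamplerSettings(n_steps=2000, sample_interval=10, seed=11)
        s1, d1 = run_fixed_lambda(harmonic, np.linspace(0, 1, 3), settings, thermo)
        s2, d2 = run_fixed_lambda(harmonic, np.linspace(0, 1, 3), settings, thermo)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.samples, b.samples)
        for a, b in zip(d1.reduced_energies, d2.reduced_energies):
            np.testing.assert_array_equal(a, b)

    def test_mean_gradient_matches_analytic(self, harmonic, thermo):
        grid = np.array([0.0, 0.5, 1.0])
        settings = SamplerSettings(timestep=0.0025, n_steps=200000, sample_interval=20, seed=2)
        series, _ = run_fixed_lambda(harmonic, grid, settings, thermo,
                                     record_cross_energies=False)
        for fs, lam in zip(series, grid):
            mean = fs.samples[:, 0].mean()
            blocks = np.array_split(fs.samples[:, 0], 10)
            se = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(10)
            expected = harmonic.analytic_mean_gradient(lam, thermo)
            assert abs(mean - expected) < 3 * se + 0.02 * expected

    def test_equilibration_discard_recorded(self, harmonic, thermo):
        settings = SamplerSettings(n_steps=5000, sample_interval=10,
                                   equilibration_fraction=0.2, seed=0)
        series, _ = run_fixed_lambda(harmonic, [0.0], settings, thermo,
                                     record_cross_energies=False)
        assert series[0].n_discarded == 100
        assert len(series[0].samples) == 400


class TestRunExpandedEnsemble:
    def test_lambda_independent_marginal_matches_target(self, thermo):
        # the stationary marginal over lambda must follow pi when H is flat
        system = FlatSystem()
        target = np.array([0.4, 0.3, 0.2, 0.1])
        bias = init_bias(np.linspace(0, 1, 4), target=target, thermo=thermo,
                         update_interval=10**9)  # frozen bias
        settings = SamplerSettings(n_steps=40000, lambda_move_interval=10, seed=8)
        traj, _ = run_expanded_ensemble(system, bias, settings, thermo)
        idx = traj.single.lambda_indices
        counts = np.bincount(idx, minlength=4)
        chi2 = float(np.sum((counts - len(idx) * target) ** 2 / (len(idx) * target)))
        p = 1.0 - stats.chi2.cdf(chi2, df=3)
        assert p > 0.01

    def test_single_point_grid_degenerates_to_fixed_lambda(self, harmonic, thermo):
        bias = init_bias(np.array([0.3]), thermo=thermo)
        settings = SamplerSettings(n_steps=2000, lambda_move_interval=10, seed=1)
        traj, _ = run_expanded_ensemble(harmonic, bias, settings, thermo)
        assert set(traj.single.lambda_indices) == {0}
        np.testing.assert_allclose(traj.single.weights, 1.0)

    def test_seed_reproducibility(self, harmonic, thermo):
        grid = np.linspace(0, 1, 5)
        out = []
        for _ in range(2):
            bias = init_bias(grid, thermo=thermo, update_interval=25)
            settings = SamplerSettings(n_steps=5000, lambda_move_interval=10, seed=21)
            traj, b = run_expanded_ensemble(harmonic, bias, settings, thermo)
            out.append((traj.single.forces.copy(), b.f.copy()))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        np.testing.assert_array_equal(out[0][1], out[1][1])

    def test_walkers_share_one_bias(self, harmonic, thermo):
        grid = np.linspace(0, 1, 5)
        bias = init_bias(grid, thermo=thermo, update_interval=25)
        settings = SamplerSettings(n_steps=3000, lambda_move_interval=10, seed=2,
                                   n_walkers=3)
        traj, b = run_expanded_ensemble(harmonic, bias, settings, thermo)
        assert len(traj.walkers) == 3
        expected = settings.n_walkers * (settings.n_steps // settings.lambda_move_interval)
        assert b.total_samples == pytest.approx(expected)

    def test_weight_vectors_normalized(self, harmonic, thermo):
        bias = init_bias(np.linspace(0, 1, 5), thermo=thermo)
        settings = SamplerSettings(n_steps=3000, lambda_move_interval=10, seed=3)
        traj, _ = run_expanded_ensemble(harmonic, bias, settings, thermo)
        np.testing.assert_allclose(traj.single.weights.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(traj.single.weights >= 0)


def test_force_series_validation():
    with pytest.raises(ValueError, match="two retained samples"):
        ForceSeries(lam=[0.0], dt=0.1, samples=np.ones((1, 1)))
    with pytest.raises(ValueError, match="finite"):
        ForceSeries(lam=[0.0], dt=0.1, samples=np.array([[1.0], [np.inf]]))
    with pytest.raises(ValueError):
        SamplerSettings(timestep=-0.1)
    with pytest.raises(ValueError):
        SamplerSettings(move_kind="leapfrog")


class TestMetropolis:
    def test_harmonic_stationary_variance_is_exact(self, harmonic, thermo):
        # Metropolis sampling has no time-step bias; check <dH/dl> at k=1
        settings = SamplerSettings(timestep=0.02, n_steps=300000,
                                   sample_interval=10, seed=3,
                                   move_kind="metropolis")
        series, _ = run_fixed_lambda(harmonic, [0.0], settings, thermo,
                                     record_cross_energies=False)
        x = series[0].samples[:, 0]
        blocks = np.array_split(x, 10)
        se = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(10)
        assert abs(x.mean() - 1.5) < 3 * se

    def test_step_rejects_uphill_sometimes(self, harmonic, thermo):
        from alchemetric.sampling import metropolis_step

        settings = SamplerSettings(timestep=0.05, move_kind="metropolis")
        rng = np.random.default_rng(0)
        x = np.array([3.0])  # far up the well: mostly downhill acceptance
        moved = 0
        for _ in range(50):
            x2 = metropolis_step(x, harmonic, 1.0, settings, thermo, rng)
            moved += not np.array_equal(x2, x)
            x = x2
        assert 0 < moved <= 50

    def test_expanded_ensemble_supports_metropolis(self, harmonic, thermo):
        bias = init_bias(np.linspace(0, 1, 3), thermo=thermo)
        settings = SamplerSettings(n_steps=2000, lambda_move_interval=10, seed=5,
                                   move_kind="metropolis")
        traj, _ = run_expanded_ensemble(harmonic, bias, settings, thermo)
        np.testing.assert_allclose(traj.single.weights.sum(axis=1), 1.0, atol=1e-12)
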