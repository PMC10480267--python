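"""Built-in desk-scale benchmark studies.

These are the package's reference experiments: worked-example improvement
factors recomputed from published benchmark-table RMSE pairs, free-energy
recovery of the λ-coupled harmonic oscillator by every estimator, a paired
uniform-vs-dynamic-target variance-reduction study on a toy with strongly
λ-dependent correlation times, and metric-contrast profiles on the 2D
micro-solvation toy.  The ``evaluate`` CLI subcommand, the test suite and
the acceptance script all call these functions, so the study conditions
(problem sizes, time steps, grids) are defined once, here.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np
from scipy import stats

from .awh import free_energy_from_bias, init_bias
from .estimators import (
    bar_chain,
    mbar_from_diffs,
    ti_trapezoid,
)
from .metrics import diffusion_metric, fisher_rao_metric, friction_metric
from .sampling import SamplerSettings, run_expanded_ensemble, run_fixed_lambda
from .systems import (
    HarmonicAlchemy,
    MicroSolvationSystem,
    ThermoParams,
    harmonic_free_energy,
    mean_gradient_harmonic,
)

__all__ = [
    "WORKED_EXAMPLE_IF_CELLS",
    "worked_example_improvement_factors",
    "harmonic_recovery_study",
    "ti_analytic_harmonic",
    "variance_reduction_study",
    "friction_oracle_study",
    "microsolvation_metric_profiles",
    "microsolvation_variance_check",
]

#: Worked-example RMSE pairs (optimized, flat-target reference) from published
#: alchemical benchmark tables, with the improvement factor printed alongside
#: them.  Only cells whose printed IF equals the squared RMSE ratio after
#: 2-decimal rounding are listed; the remaining printed cells were evidently
#: computed from unrounded RMSEs and cannot be reproduced from the table.
WORKED_EXAMPLE_IF_CELLS = [
    # (label, rmse_optimized, rmse_reference, printed_improvement_factor)
    ("dipeptide_awh_diffusion_4ns", 1.02, 1.17, 0.76),
    ("dipeptide_bar_friction_4ns", 1.01, 1.52, 0.44),
    ("dipeptide_bar_friction_8ns", 0.61, 0.70, 0.76),
    ("dipeptide_bar_fisher_rao_4ns", 1.59, 1.52, 1.09),
    ("dipeptide_bar_fisher_rao_8ns", 0.71, 0.70, 1.03),
    ("dipeptide_mbar_friction_4ns", 1.38, 1.48, 0.87),
    ("dipeptide_mbar_friction_8ns", 0.66, 0.69, 0.91),
    ("ligand_awh_seq21_diffusion_4ns", 1.2, 4.9, 0.06),
    ("ligand_awh_seq21_diffusion_8ns", 0.7, 4.1, 0.03),
    ("ligand_awh_seq41_diffusion_8ns", 1.0, 4.1, 0.06),
    ("ligand_bar_sim_friction_4ns", 5.3, 5.6, 0.90),
    ("ligand_mbar_sim_friction_8ns", 0.7, 1.3, 0.29),
]


def worked_example_improvement_factors() -> Dict[str, dict]:
    """Recompute each worked-example IF cell as (RMSE_opt/RMSE_ref)²."""
    from .estimators import empirical_improvement_factor

    out = {}
    for label, rmse_opt, rmse_ref, printed in WORKED_EXAMPLE_IF_CELLS:
        computed = empirical_improvement_factor(rmse_opt, rmse_ref)
        out[label] = {
            "computed": computed,
            "rounded": round(computed, 2),
            "printed": printed,
        }
    return out


def _blocked_se(x: np.ndarray, n_blocks: int = 10) -> float:
    n_blocks = min(n_blocks, len(x))
    blocks = np.array_split(np.asarray(x, dtype=float), n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def ti_analytic_harmonic(k_A: float = 1.0, k_B: float = 4.0, n_points: int = 21,
                         temperature: float = 1.0):
    """TI on the exact mean gradients of the harmonic toy (pure quadrature).

    Returns (estimate, exact, |error|); the only error is the O(Δλ²)
    trapezoidal quadrature error.
    """
    system = HarmonicAlchemy(k_A=k_A, k_B=k_B)
    thermo = ThermoParams(temperature)
    grid = np.linspace(0.0, 1.0, n_points)
    means = [mean_gradient_harmonic(system, l, thermo) for l in grid]
    result = ti_trapezoid(means, grid, thermo=thermo)
    exact = harmonic_free_energy(system, thermo)
    return result.delta_g, exact, abs(result.delta_g - exact)


def harmonic_recovery_study(
    seed: int = 1,
    n_seeds: int = 20,
    k_A: float = 1.0,
    k_B: float = 4.0,
    n_points: int = 9,
    fixed_points: int = 21,
    fixed_steps: int = 120000,
    fixed_timestep: float = 0.0025,
    awh_steps: int = 100000,
    timestep: float = 0.005,
) -> Dict[str, np.ndarray]:
    """Recover ΔG = ln(k_B/k_A)/(2β) with AWH, TI, BAR-chain and MBAR.

    Per seed: one set of fixed-λ runs on the grid feeding TI (sampled
    gradients), BAR-chain and MBAR, plus one uniform-target and one
    dynamic-target expanded-ensemble run.  Returns per-method arrays of
    estimates over seeds plus the exact value.
    """
    system = HarmonicAlchemy(k_A=k_A, k_B=k_B)
    thermo = ThermoParams()
    grid = np.linspace(0.0, 1.0, n_points)
    fixed_grid = np.linspace(0.0, 1.0, fixed_points)
    exact = harmonic_free_energy(system, thermo)
    out: Dict[str, List[float]] = {
        "awh_uniform": [], "awh_dynamic": [], "ti": [], "bar": [], "mbar": []
    }
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_seeds) % (2**31)
    for i in range(n_seeds):
        fixed = SamplerSettings(timestep=fixed_timestep, n_steps=fixed_steps,
                                sample_interval=20, seed=int(seeds[3 * i]))
        series, diffs = run_fixed_lambda(system, fixed_grid, fixed, thermo)
        means = [fs.samples[:, 0].mean() for fs in series]
        ses = [_blocked_se(fs.samples[:, 0]) for fs in series]
        out["ti"].append(ti_trapezoid(means, fixed_grid, stderrs=ses, thermo=thermo).delta_g)
        out["bar"].append(bar_chain(diffs, thermo).delta_g)
        out["mbar"].append(mbar_from_diffs(diffs, thermo)[1].delta_g)
        for mode, dyn in (("awh_uniform", False), ("awh_dynamic", True)):
            settings = SamplerSettings(
                timestep=timestep, n_steps=awh_steps, lambda_move_interval=10,
                seed=int(seeds[3 * i + (1 if not dyn else 2)]),
            )
            bias = init_bias(grid, initial_error=1.0, thermo=thermo, update_interval=25)
            _, bias = run_expanded_ensemble(system, bias, settings, thermo,
                                            dynamic_target=dyn, record_trajectory=False)
            out[mode].append(free_energy_from_bias(bias, thermo).delta_g)
    result = {k: np.asarray(v) for k, v in out.items()}
    result["exact"] = exact
    return result


def variance_reduction_study(
    seed: int = 1,
    n_pairs: int = 48,
    k_A: float = 1.0,
    k_B: float = 16.0,
    n_points: int = 11,
    awh_steps: int = 240000,
    timestep: float = 0.005,
) -> Dict[str, object]:
    """Paired uniform vs dynamic-target AWH runs at equal budget.

    The toy's correlation time γ/k(λ) varies 16-fold across λ, so the
    optimal target π ∝ √g is strongly nonuniform and dynamic optimization
    should lower the ΔG error.  Returns per-seed absolute errors for both
    arms and the one-sided Wilcoxon signed-rank p-value for
    err²(uniform) > err²(dynamic).
    """
    system = HarmonicAlchemy(k_A=k_A, k_B=k_B)
    thermo = ThermoParams()
    grid = np.linspace(0.0, 1.0, n_points)
    exact = harmonic_free_energy(system, thermo)
    err_u, err_d = [], []
    seeds = np.random.SeedSequence(seed + 1).generate_state(n_pairs) % (2**31)
    for i in range(n_pairs):
        for dyn, store in ((False, err_u), (True, err_d)):
            settings = SamplerSettings(timestep=timestep, n_steps=awh_steps,
                                       lambda_move_interval=10, seed=int(seeds[i]))
            bias = init_bias(grid, initial_error=1.0, thermo=thermo, update_interval=25)
            _, bias = run_expanded_ensemble(system, bias, settings, thermo,
                                            dynamic_target=dyn, record_trajectory=False)
            store.append(free_energy_from_bias(bias, thermo).delta_g - exact)
    err_u = np.asarray(err_u)
    err_d = np.asarray(err_d)
    diff = err_u**2 - err_d**2
    test = stats.wilcoxon(diff, alternative="greater")
    return {
        "errors_uniform": err_u,
        "errors_dynamic": err_d,
        "var_uniform": float(np.mean(err_u**2)),
        "var_dynamic": float(np.mean(err_d**2)),
        "p_value": float(test.pvalue),
        "exact": exact,
    }


def friction_oracle_study(
    seed: int = 1,
    k_A: float = 1.0,
    k_B: float = 4.0,
    lambdas=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_steps: int = 1000000,
    timestep: float = 0.005,
):
    """Friction-metric estimates vs the closed-form g(λ) = Δk²γ/(4β²k³).

    Returns (estimate, analytic) arrays over the requested λ values.
    """
    system = HarmonicAlchemy(k_A=k_A, k_B=k_B)
    thermo = ThermoParams()
    grid = np.asarray(lambdas, dtype=float)
    settings = SamplerSettings(timestep=timestep, n_steps=n_steps,
                               sample_interval=5, seed=seed)
    series, _ = run_fixed_lambda(system, grid, settings, thermo,
                                 record_cross_energies=False)
    est = friction_metric(series)
    analytic = np.array([
        system.analytic_friction_metric(l, settings.friction_gamma, thermo) for l in grid
    ])
    return est, analytic


def microsolvation_metric_profiles(
    seed: int = 1,
    n_solvent: int = 8,
    box_length: float = 4.0,
    lambdas=(0.0, 0.25, 0.5, 0.75, 1.0),
    fixed_steps: int = 160000,
    ee_steps: int = 240000,
    timestep: float = 3e-4,
):
    """Friction, Fisher–Rao and diffusion profiles on the 2D solvation toy.

    Fixed-λ runs feed the friction and Fisher–Rao estimates; one
    expanded-ensemble run at a frozen near-converged bias supplies the
    diffusion metric on the same grid.
    """
    system = MicroSolvationSystem(n_solvent=n_solvent, box_length=box_length)
    thermo = ThermoParams()
    grid = np.asarray(lambdas, dtype=float)
    fixed = SamplerSettings(timestep=timestep, n_steps=fixed_steps,
                            sample_interval=20, seed=seed)
    series, _ = run_fixed_lambda(system, grid, fixed, thermo,
                                 record_cross_energies=False)
    fric = friction_metric(series)
    fisher = fisher_rao_metric(series)
    ee = SamplerSettings(timestep=timestep, n_steps=ee_steps,
                         lambda_move_interval=20, seed=seed + 1)
    bias = init_bias(grid, initial_error=2.0, thermo=thermo, update_interval=25)
    traj, bias = run_expanded_ensemble(system, bias, ee, thermo)
    diff = diffusion_metric(traj, interpolate_missing=True)
    return {"friction": fric, "fisher_rao": fisher, "diffusion": diff, "bias": bias}


def microsolvation_variance_check(
    seed: int = 1,
    n_repeats: int = 40,
    n_solvent: int = 6,
    box_length: float = 4.0,
    n_points: int = 5,
    ee_steps: int = 30000,
    timestep: float = 3e-4,
):
    """Compare the predicted Var ΔG = 2𝕍/τ with the empirical repeat variance.

    The prediction uses the diffusion metric of a long reference run and
    the uniform target actually sampled; τ is the per-run sampling time.
    The functional is only an asymptotic, Markov-assumption estimate, so
    agreement within a small factor is the expected outcome.
    """
    from .paths import LambdaPath, variance_functional

    system = MicroSolvationSystem(n_solvent=n_solvent, box_length=box_length)
    thermo = ThermoParams()
    grid = np.linspace(0.0, 1.0, n_points)
    # reference metric from one longer run
    ref = SamplerSettings(timestep=timestep, n_steps=3 * ee_steps,
                          lambda_move_interval=20, seed=seed)
    bias0 = init_bias(grid, initial_error=2.0, thermo=thermo, update_interval=25)
    traj, _ = run_expanded_ensemble(system, bias0, ref, thermo)
    metric = diffusion_metric(traj, interpolate_missing=True)
    path = LambdaPath(lambdas=grid[:, None], s=grid)
    tau = ee_steps * timestep
    v, var_pred = variance_functional(path, _scalar_interp(metric), total_time=tau)
    estimates = []
    seeds = np.random.SeedSequence(seed + 7).generate_state(n_repeats) % (2**31)
    for i in range(n_repeats):
        settings = SamplerSettings(timestep=timestep, n_steps=ee_steps,
                                   lambda_move_interval=20, seed=int(seeds[i]))
        bias = init_bias(grid, initial_error=2.0, thermo=thermo, update_interval=25)
        _, bias = run_expanded_ensemble(system, bias, settings, thermo,
                                        record_trajectory=False)
        estimates.append(free_energy_from_bias(bias, thermo).delta_g)
    estimates = np.asarray(estimates)
    return {
        "v_functional": v,
        "var_predicted": var_pred,
        "var_empirical": float(np.var(estimates, ddof=1)),
        "estimates": estimates,
    }


def _scalar_interp(metric):
    """1D scalar MetricEstimate → interpolating callable (NaN-safe)."""
    lams = metric.lambdas[:, 0]
    vals = np.asarray(metric.scalars(), dtype=float)
    good = np.isfinite(vals)
    return lambda l: float(np.interp(l, lams[good], vals[good]))
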