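"""Free-energy estimators for fixed-λ data and the repeat-evaluation harness.

Thermodynamic integration (trapezoidal quadrature of ⟨∂H/∂λ⟩), the Bennett
acceptance ratio for a pair of states (self-consistent root of the Fermi
weighted balance, with the standard asymptotic variance), a chain of BAR
legs over adjacent λ points, and MBAR (all-pairs reduced energies, solved
by minimizing the convex MBAR objective followed by self-consistent
polishing).  The evaluation harness mirrors how repeated free-energy runs
are scored in practice: RMSE against a pooled reference, a bootstrap
one-sigma interval, and the empirical improvement factor — the squared
RMSE ratio, which under 1/√τ error decay is the fraction of compute time
an optimized protocol needs to reach the reference accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .awh import FreeEnergyResult
from .systems import ThermoParams

__all__ = [
    "EnergyDifferenceSet",
    "EvalReport",
    "ti_trapezoid",
    "bar_pair",
    "bar_chain",
    "mbar_solve",
    "rmse_over_repeats",
    "bootstrap_sigma",
    "empirical_improvement_factor",
    "evaluate_repeats",
]


@dataclass
class EnergyDifferenceSet:
    """Reduced energies of every sample evaluated at every λ state.

    ``reduced_energies[k]`` is an array of shape (K, N_k): row j holds
    βU(x_n; λ_j) for the N_k samples drawn from state k.  Adjacent-pair
    forward/reverse work values for BAR and the pooled u_kn matrix for
    MBAR both derive from it.
    """

    reduced_energies: List[np.ndarray]

    def __post_init__(self) -> None:
        k = len(self.reduced_energies)
        self.reduced_energies = [np.asarray(u, dtype=float) for u in self.reduced_energies]
        for u in self.reduced_energies:
            if u.ndim != 2 or u.shape[0] != k:
                raise ValueError("each entry must have shape (K, N_k)")
            if u.shape[1] == 0:
                raise ValueError("every state needs at least one sample")
            if not np.all(np.isfinite(u)):
                raise ValueError("reduced energies must be finite")

    @property
    def n_states(self) -> int:
        return len(self.reduced_energies)

    @property
    def sample_counts(self) -> np.ndarray:
        return np.array([u.shape[1] for u in self.reduced_energies])

    def pair_work(self, i: int, j: int):
        """(forward, reverse) reduced work for the leg i→j: β(U_j−U_i) on
        samples from i, and β(U_i−U_j) on samples from j."""
        ui = self.reduced_energies[i]
        uj = self.reduced_energies[j]
        return ui[j] - ui[i], uj[i] - uj[j]

    def u_kn(self):
        """Pooled (K, N_total) matrix and per-state counts N_k for MBAR."""
        return np.concatenate(self.reduced_energies, axis=1), self.sample_counts


def ti_trapezoid(mean_gradients, lambda_grid, stderrs=None, thermo: ThermoParams | None = None) -> FreeEnergyResult:
    """Thermodynamic integration: ΔG = ∫⟨∂H/∂λ⟩ dλ by the trapezoidal rule.

    The standard error propagates the per-point standard errors through
    the quadrature weights assuming independent λ points.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    means = np.asarray(mean_gradients, dtype=float)
    if grid.ndim != 1 or len(grid) != len(means) or len(grid) < 2:
        raise ValueError("need matching 1D grid and gradients with at least two points")
    dg = float(np.trapezoid(means, grid))
    if stderrs is None:
        se = 0.0
    else:
        ses = np.asarray(stderrs, dtype=float)
        d = np.diff(grid)
        weights = np.zeros_like(grid)
        weights[:-1] += d / 2.0
        weights[1:] += d / 2.0
        se = float(np.sqrt(np.sum((weights * ses) ** 2)))
    return FreeEnergyResult(delta_g=dg, stderr=abs(se), method="ti")


def _bar_root_function(forward: np.ndarray, reverse: np.ndarray, m: float):
    def h(x: float) -> float:
        return float(expit(-(m + forward - x)).sum() - expit(-(-m + reverse + x)).sum())

    return h


def bar_pair(forward, reverse, thermo: ThermoParams | None = None) -> FreeEnergyResult:
    """Bennett acceptance ratio for one pair of states.

    ``forward`` are reduced works β(U_B−U_A) on samples from A, ``reverse``
    β(U_A−U_B) on samples from B.  The self-consistency equation is solved
    by bracketed root finding to 1e-12 in βΔG; the standard error is the
    usual asymptotic Fermi-function variance.  When the two work
    distributions barely overlap, the result is flagged unreliable.
    """
    thermo = thermo or ThermoParams()
    forward = np.asarray(forward, dtype=float)
    reverse = np.asarray(reverse, dtype=float)
    if forward.size == 0 or reverse.size == 0:
        raise ValueError("both forward and reverse work sets must be nonempty")
    n_f, n_r = len(forward), len(reverse)
    m = float(np.log(n_f / n_r))
    h = _bar_root_function(forward, reverse, m)
    # expand a bracket geometrically from the mean-work midpoint
    x0 = 0.5 * (float(np.mean(forward)) - float(np.mean(reverse)))
    half = 1.0
    lo, hi = x0 - half, x0 + half
    for _ in range(200):
        if h(lo) < 0 < h(hi) or h(lo) > 0 > h(hi):
            break
        half *= 2.0
        lo, hi = x0 - half, x0 + half
    else:
        raise RuntimeError("BAR bracket expansion failed; work distributions may not overlap")
    if h(lo) == 0.0:
        x = lo
    elif h(hi) == 0.0:
        x = hi
    else:
        x = brentq(h, lo, hi, xtol=1e-12, rtol=8.881784197001252e-16)
    # asymptotic variance from the Fermi weights at the solution
    f_w = expit(-(m + forward - x))
    g_w = expit(-(-m + reverse + x))
    reliable = True
    mean_f, mean_g = float(f_w.mean()), float(g_w.mean())
    if mean_f < 1e-10 or mean_g < 1e-10:
        warnings.warn("BAR overlap is vanishing; the standard error is unreliable", stacklevel=2)
        reliable = False
        var = np.inf
    else:
        var = (float(np.mean(f_w**2)) / mean_f**2 - 1.0) / n_f + (
            float(np.mean(g_w**2)) / mean_g**2 - 1.0
        ) / n_r
    se = float(np.sqrt(var)) if np.isfinite(var) else np.inf
    if not np.isfinite(se):
        se = 0.0
        reliable = False
    return FreeEnergyResult(
        delta_g=x / thermo.beta, stderr=se / thermo.beta, method="bar", reliable=reliable
    )


def bar_chain(diffs: EnergyDifferenceSet, thermo: ThermoParams | None = None) -> FreeEnergyResult:
    """Sum of BAR legs over adjacent λ pairs; leg SEs combined in quadrature."""
    thermo = thermo or ThermoParams()
    legs = []
    for i in range(diffs.n_states - 1):
        fwd, rev = diffs.pair_work(i, i + 1)
        legs.append(bar_pair(fwd, rev, thermo))
    dg = sum(leg.delta_g for leg in legs)
    se = float(np.sqrt(sum(leg.stderr**2 for leg in legs)))
    return FreeEnergyResult(
        delta_g=dg,
        stderr=se,
        method="bar_chain",
        per_leg=np.array([leg.delta_g for leg in legs]),
        reliable=all(leg.reliable for leg in legs),
    )


def mbar_solve(
    u_kn,
    sample_counts,
    thermo: ThermoParams | None = None,
    tol: float = 1e-12,
    max_iter: int = 10000,
):
    """Self-consistent MBAR solution over all states.

    ``u_kn`` has shape (K, N) with every pooled sample's reduced energy at
    every state; ``sample_counts`` gives N_k per state.  The convex MBAR
    objective is minimized (BFGS with analytic gradient), then polished by
    damped self-consistent iteration until max|Δf| < tol.  Returns
    ``(f_k, FreeEnergyResult)`` with f gauged to f_0 = 0 and the end-to-end
    ΔG with a covariance-based standard error.
    """
    thermo = thermo or ThermoParams()
    u_kn = np.asarray(u_kn, dtype=float)
    n_k = np.asarray(sample_counts, dtype=float)
    k_states, n_tot = u_kn.shape
    if len(n_k) != k_states or n_k.sum() != n_tot:
        raise ValueError("sample_counts inconsistent with u_kn")
    log_n = np.log(n_k)

    def self_consistent(f):
        c_log = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - c_log[None, :], axis=1)
        return f_new - f_new[0]

    def grad_hess(f):
        a = log_n[:, None] + f[:, None] - u_kn            # (K, N)
        lse = logsumexp(a, axis=0)
        w = np.exp(a - lse)                                # columns sum to 1
        grad = w.sum(axis=1) - n_k
        hess = np.diag(w.sum(axis=1)) - w @ w.T
        return grad, hess

    # damped self-consistent warm-up, then Newton on the convex objective
    f = np.zeros(k_states)
    delta = np.inf
    for _ in range(20):
        f_new = self_consistent(f)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            break
    iteration = 0
    while delta >= tol:
        if iteration >= max_iter:
            raise RuntimeError(
                f"MBAR did not converge in {max_iter} iterations; last residual {delta:.3e}"
            )
        grad, hess = grad_hess(f)
        # gauge: fix f_0 = 0 by solving the reduced system
        try:
            step = np.linalg.solve(hess[1:, 1:], grad[1:])
        except np.linalg.LinAlgError:
            step = None
        if step is not None and np.all(np.isfinite(step)):
            f_new = f.copy()
            f_new[1:] -= step
        else:
            f_new = self_consistent(f)
        f_new = f_new - f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        iteration += 1
    # asymptotic covariance from the normalized weight matrix
    # W_nk = exp(f_k - u_kn) / sum_l N_l exp(f_l - u_ln):
    # Theta = V S (I - S V' diag(N) V S)^+ S V'  with W = U S V'
    c_log = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
    w_mat = np.exp(f[:, None] - u_kn - c_log[None, :]).T   # (N, K)
    _, s_vals, vt = np.linalg.svd(w_mat, full_matrices=False)
    sv = s_vals[:, None] * vt                              # S V', (K, K)
    inner = np.eye(k_states) - sv @ (n_k[:, None] * sv.T)
    theta = sv.T @ np.linalg.pinv(inner, hermitian=True) @ sv
    var = theta[-1, -1] + theta[0, 0] - 2.0 * theta[-1, 0]
    se = float(np.sqrt(max(var, 0.0)))
    result = FreeEnergyResult(
        delta_g=float(f[-1] - f[0]) / thermo.beta,
        stderr=se / thermo.beta,
        method="mbar",
        per_leg=np.diff(f) / thermo.beta,
    )
    return f, result


def mbar_from_diffs(diffs: EnergyDifferenceSet, thermo: ThermoParams | None = None):
    """Convenience: run MBAR directly on an :class:`EnergyDifferenceSet`."""
    u_kn, n_k = diffs.u_kn()
    return mbar_solve(u_kn, n_k, thermo)


# ---------------------------------------------------------------------------
# Repeat-evaluation harness
# ---------------------------------------------------------------------------

def rmse_over_repeats(estimates, reference: float) -> float:
    """√(mean (estimate − reference)²) over repeated runs."""
    e = np.asarray(estimates, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.sqrt(np.mean((e - reference) ** 2)))


def bootstrap_sigma(
    values,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 5000,
    seed: int = 0,
):
    """One-sigma bootstrap interval (percentiles 15.87–84.13) of a statistic."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    stats = np.array([statistic(v[row]) for row in idx])
    lo, hi = np.percentile(stats, [15.865525393145708, 84.1344746068543])
    return float(lo), float(hi)


def empirical_improvement_factor(rmse_optimized: float, rmse_reference: float) -> float:
    """(RMSE_opt / RMSE_ref)²: the compute-time fraction implied by 1/√τ decay."""
    if rmse_reference <= 0:
        raise ValueError("reference RMSE must be positive")
    if rmse_optimized < 0:
        raise ValueError("RMSE must be non-negative")
    return (rmse_optimized / rmse_reference) ** 2


@dataclass
class EvalReport:
    """Repeat-study scores: per-configuration RMSE, bootstrap CI and IF."""

    rmse: Dict[str, float]
    rmse_ci: Dict[str, tuple]
    improvement_factor: Dict[str, float]
    n_repeats: Dict[str, int]
    reference: float
    reference_config: Optional[str] = None

    def __post_init__(self) -> None:
        for name, r in self.rmse.items():
            if r < 0:
                raise ValueError(f"negative RMSE for {name}")


def evaluate_repeats(
    estimates_by_config: Dict[str, Sequence[float]],
    reference: Optional[float] = None,
    reference_config: Optional[str] = None,
    n_boot: int = 5000,
    seed: int = 0,
) -> EvalReport:
    """Score repeated free-energy runs per configuration.

    The reference value defaults to the pooled mean over every estimate of
    every configuration; improvement factors are squared RMSE ratios
    against ``reference_config`` (when given).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in estimates_by_config.items()}
    if not arrays:
        raise ValueError("no configurations to evaluate")
    if reference is None:
        reference = float(np.mean(np.concatenate(list(arrays.values()))))
    rmse = {k: rmse_over_repeats(v, reference) for k, v in arrays.items()}
    rmse_ci = {
        k: bootstrap_sigma(v, statistic=lambda s: rmse_over_repeats(s, reference),
                           n_boot=n_boot, seed=seed)
        for k, v in arrays.items()
    }
    ifs: Dict[str, float] = {}
    if reference_config is not None:
        ref_rmse = rmse[reference_config]
        ifs = {
            k: empirical_improvement_factor(r, ref_rmse)
            for k, r in rmse.items()
            if k != reference_config
        }
    return EvalReport(
        rmse=rmse,
        rmse_ci=rmse_ci,
        improvement_factor=ifs,
        n_repeats={k: len(v) for k, v in arrays.items()},
        reference=reference,
        reference_config=reference_config,
    )
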