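"""Configuration and λ sampling: overdamped Langevin moves at fixed λ and
the expanded-ensemble walk in which λ itself is dynamical.

Configurations evolve by the Euler–Maruyama discretization of overdamped
(position) Langevin dynamics,

    x' = x − (Δt/γ) ∇H(x; λ) + √(2Δt/(βγ)) ξ,   ξ ~ N(0, 1),

which samples the Boltzmann distribution at the chosen λ up to O(Δt)
discretization bias (kept small by the default time step).  In expanded
-ensemble mode, a full-grid Gibbs move redraws the λ index from the exact
conditional P(λ|x) ∝ π_λ exp(f_λ − βH(x;λ)) between stretches of
configuration moves; the conditional weight vectors w are exactly the
w_λ(t) needed by the diffusion metric and are recorded along the way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .awh import AWHBias, accumulate_sample, bias_update, dynamic_target_update
from .estimators import EnergyDifferenceSet
from .systems import AlchemicalSystem, Configuration, ThermoParams

__all__ = [
    "SamplerSettings",
    "ForceSeries",
    "WalkerTrace",
    "Trajectory",
    "SimulationError",
    "langevin_step",
    "metropolis_step",
    "lambda_conditional_weights",
    "lambda_gibbs_move",
    "run_fixed_lambda",
    "run_expanded_ensemble",
]

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerSettings:
    """Knobs of the stochastic sampler (reduced units).

    ``sample_interval`` counts configuration steps between recorded samples
    in fixed-λ runs; ``lambda_move_interval`` counts configuration steps
    between λ Gibbs moves (and recorded samples) in expanded-ensemble runs.
    Identical seeds give identical trajectories.
    """

    timestep: float = 0.005
    friction_gamma: float = 1.0
    n_steps: int = 10000
    sample_interval: int = 10
    equilibration_fraction: float = 0.1
    seed: int = 0
    move_kind: str = "langevin"
    lambda_move_interval: int = 10
    n_walkers: int = 1

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction_gamma <= 0:
            raise ValueError("friction_gamma must be positive")
        if self.sample_interval < 1 or self.lambda_move_interval < 1:
            raise ValueError("intervals must be at least 1 step")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must lie in [0, 1)")
        if self.move_kind not in ("langevin", "metropolis"):
            raise ValueError("move_kind must be 'langevin' or 'metropolis'")
        if self.n_walkers < 1:
            raise ValueError("need at least one walker")


@dataclass
class ForceSeries:
    """Time series of ∂H/∂λ^μ sampled at one fixed λ point."""

    lam: np.ndarray                 # (D,)
    dt: float                       # time between retained samples
    samples: np.ndarray             # (N, D)
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] < 2:
            raise ValueError("a force series needs at least two retained samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("force samples must be finite")
        if self.dt <= 0:
            raise ValueError("sampling interval dt must be positive")


@dataclass
class WalkerTrace:
    """Per-sample records of one expanded-ensemble walker."""

    times: np.ndarray               # (S,)
    lambda_indices: np.ndarray      # (S,)
    energies: np.ndarray            # (S,) energy at the current λ (summary)
    forces: np.ndarray              # (S, K, D): ∂H/∂λ at every grid point
    weights: np.ndarray             # (S, K): conditional weights w_λ


@dataclass
class Trajectory:
    """Expanded-ensemble trajectory (one entry per walker)."""

    walkers: List[WalkerTrace]
    lambda_grid: np.ndarray         # (K, D)
    dt_between_samples: float

    @property
    def single(self) -> WalkerTrace:
        if len(self.walkers) != 1:
            raise ValueError("trajectory holds more than one walker")
        return self.walkers[0]


def _coords(config) -> np.ndarray:
    return config.coordinates if isinstance(config, Configuration) else np.asarray(config, dtype=float)


def langevin_step(config, system: AlchemicalSystem, lam, settings: SamplerSettings,
                  thermo: ThermoParams, rng: np.random.Generator):
    """One Euler–Maruyama step of overdamped Langevin dynamics."""
    x = _coords(config)
    grad = system.gradient(x, lam)
    if not np.all(np.isfinite(grad)):
        raise SimulationError(f"non-finite force at lambda={lam!r}; x={x!r}")
    dt, gamma = settings.timestep, settings.friction_gamma
    noise = rng.standard_normal(x.shape)
    x_new = x - (dt / gamma) * grad + np.sqrt(2.0 * dt / (thermo.beta * gamma)) * noise
    if isinstance(config, Configuration):
        return Configuration(coordinates=x_new)
    return x_new


def metropolis_step(config, system: AlchemicalSystem, lam, settings: SamplerSettings,
                    thermo: ThermoParams, rng: np.random.Generator):
    """One Gaussian random-walk Metropolis move (acceptance min(1, e^{−βΔH})).

    The proposal width matches the Langevin diffusive scale √(2Δt/(βγ)).
    """
    x = _coords(config)
    scale = np.sqrt(2.0 * settings.timestep / (thermo.beta * settings.friction_gamma))
    proposal = x + scale * rng.standard_normal(x.shape)
    delta = system.energy(proposal, lam) - system.energy(x, lam)
    if not np.isfinite(delta):
        accept = delta < 0  # moving off an infinite-energy configuration
    else:
        accept = np.log(rng.uniform()) < -thermo.beta * delta
    x_new = proposal if accept else x.copy()
    if isinstance(config, Configuration):
        return Configuration(coordinates=x_new)
    return x_new


def _propagate_block(system, x, lam, noise, settings, thermo, rng):
    """Advance one block of configuration moves; returns stacked positions."""
    if settings.move_kind == "langevin":
        return system.simulate_block(x, lam, noise, settings.timestep / settings.friction_gamma)
    # random-walk Metropolis with the same diffusive proposal scale
    out = np.empty_like(noise)
    e = system.energy(x, lam)
    beta = thermo.beta
    log_u = np.log(rng.uniform(size=len(noise)))
    for i in range(len(noise)):
        proposal = x + noise[i]
        e_new = system.energy(proposal, lam)
        if log_u[i] < -beta * (e_new - e):
            x, e = proposal, e_new
        out[i] = x
    return out


def _weights_from_energies(energies: np.ndarray, bias: AWHBias, beta: float) -> np.ndarray:
    logw = bias.conditional_log_weights(energies, beta)
    logw = logw - logw.max()
    w = np.exp(logw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise SimulationError("conditional lambda weights underflowed to zero")
    return w / total


def lambda_conditional_weights(config, system: AlchemicalSystem, bias: AWHBias,
                               thermo: ThermoParams) -> np.ndarray:
    """Conditional w_λ = P(λ|x) ∝ π_λ exp(f_λ − βH(x;λ)), normalized to 1.

    The joint normalizer cancels; a max-shift keeps the exponentials in
    range.  Invariant under adding a constant to all f_λ.
    """
    x = _coords(config)
    energies = system.energy_grid(x, bias.lambda_grid)
    return _weights_from_energies(energies, bias, thermo.beta)


def lambda_gibbs_move(config, bias: AWHBias, system: AlchemicalSystem,
                      thermo: ThermoParams, rng: np.random.Generator) -> int:
    """Redraw the λ index from the full conditional (independence Gibbs move).

    Sampling the exact conditional satisfies detailed balance with respect
    to the joint expanded-ensemble distribution at a frozen bias.
    """
    w = lambda_conditional_weights(config, system, bias, thermo)
    return int(np.searchsorted(np.cumsum(w), rng.uniform()))


def _normalize_grid(lambda_grid, n_dims: int) -> np.ndarray:
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.ndim == 1:
        grid = grid[:, None]
    if grid.ndim != 2 or grid.shape[1] != n_dims:
        raise ValueError(f"lambda grid must have shape (K, {n_dims})")
    if grid.shape[0] == 0:
        raise ValueError("lambda grid must be nonempty")
    return grid


def run_fixed_lambda(
    system: AlchemicalSystem,
    lambda_grid,
    settings: SamplerSettings,
    thermo: ThermoParams,
    record_cross_energies: bool = True,
) -> Tuple[List[ForceSeries], Optional[EnergyDifferenceSet]]:
    """Independent equilibrium runs at each grid point.

    Returns one equilibrated :class:`ForceSeries` per λ (the configured
    equilibration fraction discarded) and, when requested, the reduced
    energies of every retained sample at every grid state — the raw
    material for BAR and MBAR.
    """
    grid = _normalize_grid(lambda_grid, system.n_lambda_dims)
    k_states = grid.shape[0]
    dt, gamma = settings.timestep, settings.friction_gamma
    a = dt / gamma
    sig = np.sqrt(2.0 * dt / (thermo.beta * gamma))
    series: List[ForceSeries] = []
    cross: List[np.ndarray] = []
    seeds = np.random.SeedSequence(settings.seed).spawn(k_states)
    for j, lam in enumerate(grid):
        rng = np.random.default_rng(seeds[j])
        x = system.initial_configuration(rng)
        n = settings.n_steps
        interval = settings.sample_interval
        n_samples = n // interval
        n_discard = int(settings.equilibration_fraction * n_samples)
        forces = np.empty((n_samples, system.n_lambda_dims))
        energies = np.empty((k_states, n_samples)) if record_cross_energies else None
        count = 0
        chunk = 8192 - (8192 % interval)
        t = 0
        try:
            while t < n:
                block = min(chunk, n - t)
                noise = rng.standard_normal((block,) + np.shape(x)) * sig
                xs = _propagate_block(system, x, lam, noise, settings, thermo, rng)
                x = xs[-1]
                if not np.all(np.isfinite(x)):
                    raise SimulationError("non-finite coordinates")
                # global steps t+1 .. t+block; retain those divisible by interval
                first = interval - (t % interval) - 1
                pick = xs[first::interval]
                t += block
                if len(pick):
                    take = min(len(pick), n_samples - count)
                    pick = pick[:take]
                    forces[count : count + take] = system.dhdlambda_block(pick, lam)
                    if energies is not None:
                        energies[:, count : count + take] = system.energy_grid_block(pick, grid)
                    count += take
        except SimulationError as err:
            raise SimulationError(f"propagation failed at lambda={lam.tolist()}: {err}") from err
        retained = forces[n_discard:count]
        if not np.all(np.isfinite(retained)):
            raise SimulationError(f"propagation failed at lambda={lam.tolist()}: non-finite forces")
        series.append(ForceSeries(lam=lam, dt=dt * interval, samples=retained,
                                  n_discarded=n_discard))
        if energies is not None:
            cross.append(thermo.beta * energies[:, n_discard:count])
    diffs = EnergyDifferenceSet(cross) if record_cross_energies else None
    return series, diffs


def run_expanded_ensemble(
    system: AlchemicalSystem,
    bias: AWHBias,
    settings: SamplerSettings,
    thermo: ThermoParams,
    dynamic_target: bool = False,
    target_floor: float = 0.05,
    target_min_interval: int = 1,
    online_block_size: int = 200,
    record_trajectory: bool = True,
) -> Tuple[Trajectory, AWHBias]:
    """Expanded-ensemble run: alternate configuration moves and λ moves.

    Every ``lambda_move_interval`` configuration steps each walker makes a
    full-grid Gibbs λ move; the conditional weight vector is accumulated
    into the shared bias, which updates itself every
    ``bias.update_interval`` accumulated samples.  With ``dynamic_target``
    the target distribution is re-optimized to √g of an on-the-fly
    diffusion-metric estimate after each bias update once the initial
    stage has been left.  Walkers run sequentially within each round and
    share the one bias.
    """
    from .metrics import OnlineDiffusionMetric  # local import to avoid a cycle

    grid = bias.lambda_grid
    k_states = grid.shape[0]
    beta = thermo.beta
    dt, gamma = settings.timestep, settings.friction_gamma
    a = dt / gamma
    sig = np.sqrt(2.0 * dt / (beta * gamma))
    n_rounds = settings.n_steps // settings.lambda_move_interval
    if n_rounds < 1:
        raise ValueError("n_steps shorter than one lambda move interval")

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_walkers)
    rngs = [np.random.default_rng(s) for s in seeds]
    xs = [system.initial_configuration(r) for r in rngs]
    idxs = [0 for _ in range(settings.n_walkers)]

    online = OnlineDiffusionMetric(grid, dt=dt * settings.lambda_move_interval,
                                   block_size=online_block_size) if dynamic_target else None

    rec: List[dict] = [
        {"times": [], "idx": [], "energy": [], "forces": [], "weights": []}
        for _ in range(settings.n_walkers)
    ]
    nmove = settings.lambda_move_interval
    for rnd in range(n_rounds):
        for wi in range(settings.n_walkers):
            rng = rngs[wi]
            x = xs[wi]
            lam = grid[idxs[wi]]
            noise = rng.standard_normal((nmove,) + np.shape(x)) * sig
            x = _propagate_block(system, x, lam, noise, settings, thermo, rng)[-1]
            if not np.all(np.isfinite(x)):
                raise SimulationError(
                    f"propagation failed at lambda={lam.tolist()} (walker {wi})"
                )
            xs[wi] = x
            energies = system.energy_grid(x, grid)
            w = _weights_from_energies(energies, bias, beta)
            idxs[wi] = int(np.searchsorted(np.cumsum(w), rng.uniform()))
            accumulate_sample(bias, w)
            need_forces = record_trajectory or online is not None
            forces = system.dhdlambda_grid(x, grid) if need_forces else None
            if online is not None:
                online.add_sample(forces, w)
            if record_trajectory:
                r = rec[wi]
                r["times"].append((rnd + 1) * nmove * dt)
                r["idx"].append(idxs[wi])
                r["energy"].append(energies[idxs[wi]])
                r["forces"].append(forces)
                r["weights"].append(w)
            if bias.samples_since_update >= bias.update_interval:
                bias_update(bias)
                if online is not None and bias.stage == "final":
                    est = online.estimate()
                    if est is not None:
                        dynamic_target_update(bias, est, floor=target_floor,
                                              min_interval=target_min_interval)

    walkers = [
        WalkerTrace(
            times=np.asarray(r["times"]),
            lambda_indices=np.asarray(r["idx"], dtype=int),
            energies=np.asarray(r["energy"]),
            forces=np.asarray(r["forces"]) if record_trajectory else np.empty((0, k_states, system.n_lambda_dims)),
            weights=np.asarray(r["weights"]) if record_trajectory else np.empty((0, k_states)),
        )
        for r in rec
    ]
    traj = Trajectory(walkers=walkers, lambda_grid=grid,
                      dt_between_samples=dt * nmove)
    return traj, bias
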