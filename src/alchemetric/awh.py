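"""Adaptive expanded-ensemble bias (accelerated-weight-histogram style).

The expanded ensemble samples the joint distribution

    P(x, λ) ∝ π_λ exp(f_λ − βH(x; λ)),

and the bias parameters f_λ are adapted until the marginal over λ matches
the target π_λ, at which point f_λ → βG_λ up to a constant (the gauge here
fixes f at the first grid point to zero).

The update runs in two stages.  The initial stage applies a constant,
robust update of size Δ; each time the walker "covers" the grid (every
point's epoch histogram reaches a fraction of its target share) Δ is
halved.  Once enough real samples have accumulated that the constant
update is no larger than the asymptotic one, the final stage takes over
with Δ = K/N_eff, a stochastic-approximation (1/N) gain for which the
standard error of f decays like 1/√N.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .systems import ThermoParams

__all__ = [
    "AWHBias",
    "init_bias",
    "accumulate_sample",
    "bias_update",
    "check_initial_stage_exit",
    "dynamic_target_update",
    "free_energy_from_bias",
    "FreeEnergyResult",
]

logger = logging.getLogger(__name__)

INITIAL = "initial"
FINAL = "final"


@dataclass
class FreeEnergyResult:
    """A free energy difference with standard error and method tag."""

    delta_g: float
    stderr: float
    method: str
    per_leg: Optional[np.ndarray] = None
    reliable: bool = True

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("standard error must be non-negative")


@dataclass
class AWHBias:
    """State of the adaptive bias over a λ grid.

    ``f`` is dimensionless (converges to βG up to the gauge), ``target`` is
    the sampling target π (normalized point masses) and ``histogram`` holds
    the weight accumulated since the previous update.
    """

    lambda_grid: np.ndarray          # (K, D)
    f: np.ndarray                    # (K,)
    target: np.ndarray               # (K,)
    histogram: np.ndarray            # (K,), since the last update
    epoch_histogram: np.ndarray      # (K,), since the last covering
    stage: str
    update_size: float
    n_eff: float
    initial_error: float
    update_interval: int = 25
    covering_threshold: float = 0.2
    final_gain: float = 2.0
    samples_since_update: float = 0.0
    epoch_samples: float = 0.0
    total_samples: float = 0.0
    n_updates: int = 0
    n_coverings: int = 0
    last_target_update: int = -(10**9)
    f_trace: List[Tuple[float, str, np.ndarray]] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.f)

    def conditional_log_weights(self, energies: np.ndarray, beta: float) -> np.ndarray:
        return np.log(self.target) + self.f - beta * energies

    def to_json(self) -> str:
        return json.dumps(
            {
                "lambda_grid": self.lambda_grid.tolist(),
                "f": self.f.tolist(),
                "target": self.target.tolist(),
                "histogram": self.histogram.tolist(),
                "epoch_histogram": self.epoch_histogram.tolist(),
                "stage": self.stage,
                "update_size": self.update_size,
                "n_eff": self.n_eff,
                "initial_error": self.initial_error,
                "update_interval": self.update_interval,
                "covering_threshold": self.covering_threshold,
                "final_gain": self.final_gain,
                "samples_since_update": self.samples_since_update,
                "epoch_samples": self.epoch_samples,
                "total_samples": self.total_samples,
                "n_updates": self.n_updates,
                "n_coverings": self.n_coverings,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AWHBias":
        d = json.loads(text)
        return cls(
            lambda_grid=np.asarray(d["lambda_grid"], dtype=float),
            f=np.asarray(d["f"], dtype=float),
            target=np.asarray(d["target"], dtype=float),
            histogram=np.asarray(d["histogram"], dtype=float),
            epoch_histogram=np.asarray(d["epoch_histogram"], dtype=float),
            stage=d["stage"],
            update_size=d["update_size"],
            n_eff=d["n_eff"],
            initial_error=d["initial_error"],
            update_interval=d["update_interval"],
            covering_threshold=d["covering_threshold"],
            final_gain=d.get("final_gain", 2.0),
            samples_since_update=d["samples_since_update"],
            epoch_samples=d["epoch_samples"],
            total_samples=d["total_samples"],
            n_updates=d["n_updates"],
            n_coverings=d["n_coverings"],
        )


def _normalize_target(target: np.ndarray) -> np.ndarray:
    target = np.asarray(target, dtype=float)
    if np.any(target <= 0) or not np.all(np.isfinite(target)):
        raise ValueError("target distribution must be positive and finite")
    total = target.sum()
    if total <= 0:
        raise ValueError("target distribution is not normalizable")
    if abs(total - 1.0) > 1e-9:
        warnings.warn("custom target did not sum to 1; renormalizing", stacklevel=2)
    return target / total


def init_bias(
    lambda_grid,
    target="uniform",
    initial_error: float = 1.0,
    thermo: ThermoParams | None = None,
    update_interval: int = 25,
    covering_threshold: float = 0.2,
    final_gain: float = 2.0,
) -> AWHBias:
    """Create a fresh bias: f ≡ 0, requested target, initial-stage update size.

    The initial update size is β·initial_error/K, i.e. the dimensionless
    error the user expects in the initial free-energy guess, spread over
    the grid.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.ndim == 1:
        grid = grid[:, None]
    if grid.ndim != 2 or grid.shape[0] == 0:
        raise ValueError("lambda grid must be a nonempty (K,) or (K, D) array")
    k = grid.shape[0]
    if initial_error <= 0:
        raise ValueError("initial_error must be positive")
    thermo = thermo or ThermoParams()
    if isinstance(target, str):
        if target != "uniform":
            raise ValueError(f"unknown target mode {target!r}")
        pi = np.full(k, 1.0 / k)
    else:
        pi = _normalize_target(target)
        if len(pi) != k:
            raise ValueError("target length does not match grid")
    update_size = thermo.beta * initial_error / k
    return AWHBias(
        lambda_grid=grid,
        f=np.zeros(k),
        target=pi,
        histogram=np.zeros(k),
        epoch_histogram=np.zeros(k),
        stage=INITIAL,
        update_size=update_size,
        n_eff=k / update_size,
        initial_error=initial_error,
        update_interval=update_interval,
        covering_threshold=covering_threshold,
        final_gain=final_gain,
    )


def accumulate_sample(bias: AWHBias, weights: np.ndarray) -> AWHBias:
    """Add one conditional-weight vector to the histograms."""
    w = np.asarray(weights, dtype=float)
    if w.shape != bias.histogram.shape:
        raise ValueError("weight vector shape does not match the grid")
    bias.histogram += w
    bias.epoch_histogram += w
    m = float(w.sum())
    bias.samples_since_update += m
    bias.epoch_samples += m
    bias.total_samples += m
    return bias


def check_initial_stage_exit(bias: AWHBias) -> bool:
    """Covering/halving bookkeeping; returns True on transition to the final stage.

    A covering epoch completes when every point's epoch histogram exceeds
    ``covering_threshold`` times its target share of the epoch samples;
    each covering halves the update size.  The initial stage exits when the
    constant update size drops to (or below) the final-stage size K/N
    implied by the accumulated samples.
    """
    if bias.stage != INITIAL:
        return False
    k = bias.n_points
    if bias.epoch_samples > 0:
        required = bias.covering_threshold * bias.target * bias.epoch_samples
        if np.all(bias.epoch_histogram >= required):
            bias.n_coverings += 1
            bias.update_size /= 2.0
            bias.n_eff = k / bias.update_size
            bias.epoch_histogram[:] = 0.0
            bias.epoch_samples = 0.0
            logger.info(
                "awh covering %d complete; update size halved to %.3g",
                bias.n_coverings,
                bias.update_size,
            )
    if bias.total_samples > 0 and bias.update_size <= bias.final_gain * k / bias.total_samples:
        bias.stage = FINAL
        bias.n_eff = max(bias.n_eff, bias.total_samples)
        bias.update_size = bias.final_gain * k / bias.n_eff
        logger.info("awh entering final stage at N=%g samples", bias.total_samples)
        return True
    return False


def bias_update(bias: AWHBias) -> AWHBias:
    """Apply one free-energy update from the accumulated histogram.

    f_λ ← f_λ − Δ·(h_λ − m·π_λ) with m the samples accumulated since the
    last update; Δ is the stage-dependent update size.  The histogram is
    reset and the gauge (f at the first grid point = 0) re-fixed.
    """
    m = bias.samples_since_update
    if m <= 0:
        warnings.warn("bias_update called with no accumulated samples; no-op", stacklevel=2)
        return bias
    if bias.stage == FINAL:
        bias.n_eff += m
        bias.update_size = bias.final_gain * bias.n_points / bias.n_eff
    delta = bias.update_size
    bias.f -= delta * (bias.histogram - m * bias.target)
    bias.f -= bias.f[0]
    bias.histogram[:] = 0.0
    bias.samples_since_update = 0.0
    bias.n_updates += 1
    if bias.stage == INITIAL:
        check_initial_stage_exit(bias)
    bias.f_trace.append((bias.total_samples, bias.stage, bias.f.copy()))
    return bias


def dynamic_target_update(
    bias: AWHBias,
    metric,
    floor: float = 0.05,
    min_interval: int = 1,
) -> AWHBias:
    """Re-target the bias to π_λ ∝ max(√det g(λ), floor·max √det g).

    Only acts in the final stage and no more often than every
    ``min_interval`` bias updates; otherwise a no-op.  ``metric`` is a
    :class:`~alchemetric.metrics.MetricEstimate` on the same grid (or a
    plain array of per-point scalar/tensor values).
    """
    if bias.stage != FINAL:
        return bias
    if bias.n_updates - bias.last_target_update < min_interval:
        return bias
    values = getattr(metric, "values", metric)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        det = np.clip(values, 0.0, None)
    else:
        det = np.clip(np.linalg.det(values), 0.0, None)
    sqrt_det = np.sqrt(det)
    sqrt_det = np.where(np.isfinite(sqrt_det), sqrt_det, 0.0)
    if len(sqrt_det) != bias.n_points:
        raise ValueError("metric grid does not match the bias grid")
    top = sqrt_det.max()
    if top <= 0:
        warnings.warn("all-zero metric; falling back to a uniform target", stacklevel=2)
        bias.target = np.full(bias.n_points, 1.0 / bias.n_points)
    else:
        pi = np.maximum(sqrt_det, floor * top)
        bias.target = pi / pi.sum()
    bias.last_target_update = bias.n_updates
    logger.info("awh target updated at update %d", bias.n_updates)
    return bias


def free_energy_from_bias(bias: AWHBias, thermo: ThermoParams | None = None) -> FreeEnergyResult:
    """ΔG between the last and first grid points, ΔG = (f_K − f_0)/β.

    The standard error is a block average over the final-stage trace of
    f_K − f_0 (the second half, so most of the transient is excluded);
    it is a rough estimate, flagged unreliable when no final-stage trace
    exists yet.
    """
    thermo = thermo or ThermoParams()
    delta_f = float(bias.f[-1] - bias.f[0])
    trace = [fk[-1] - fk[0] for (_, stage, fk) in bias.f_trace if stage == FINAL]
    reliable = len(trace) >= 8
    if len(trace) >= 2:
        tail = np.asarray(trace[len(trace) // 2 :])
        n_blocks = min(10, len(tail))
        blocks = np.array_split(tail, n_blocks)
        means = np.array([b.mean() for b in blocks])
        se = float(means.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else float("nan")
    else:
        se = float("nan")
        reliable = False
    if not np.isfinite(se):
        se = 0.0
        reliable = False
    return FreeEnergyResult(
        delta_g=delta_f / thermo.beta, stderr=se / thermo.beta, method="awh", reliable=reliable
    )
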