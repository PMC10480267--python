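"""Metric estimators on λ space: friction, diffusion and Fisher–Rao.

The friction metric is the integrated time-autocorrelation of the
generalized force F_μ = −∂H/∂λ^μ at fixed λ,

    g_μν(λ) = ∫₀^∞ ⟨δF_μ(t) δF_ν(0)⟩_λ dt,

which is also the friction tensor of slowly driven nonequilibrium
protocols.  For expanded-ensemble random walks the diffusion metric
replaces the fixed-λ average by conditional-weight-weighted correlations,

    g_μν(λ) = ∫₀^∞ ⟨δF_μ(t) w_λ(t) δF_ν(0) w_λ(0)⟩ / ⟨w_λ²⟩ dt,

with w_λ(t) = P(λ|x(t)).  The Fisher–Rao metric is the equal-time
covariance ⟨δF_μ δF_ν⟩ and ignores time correlations entirely — it is the
comparison point that shows why time correlations matter.

Discrete integrals use dt·(C₀/2 + Σ_{k≤W} C_k) with an automatic
self-consistent window (smallest W ≥ 5·τ_int(W), capped at a tenth of the
series length).  Cross terms are symmetrized.  Uncertainties are jackknife
standard errors over contiguous blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .sampling import ForceSeries, Trajectory

__all__ = [
    "MetricEstimate",
    "integrated_correlation",
    "friction_metric",
    "fisher_rao_metric",
    "diffusion_metric",
    "metric_field_2d",
    "OnlineDiffusionMetric",
]

logger = logging.getLogger(__name__)

#: Hard floor on usable series length for the correlation integrals.
MIN_SERIES_LENGTH = 50


@dataclass
class MetricEstimate:
    """A metric profile: scalar g(λ) in 1D or a 2×2 tensor field in 2D.

    ``values`` has shape (K,) for scalars or (K, D, D) for tensors; the
    ``missing`` mask marks grid points that could not be estimated (e.g.
    never visited by the walker) and ``interpolated`` marks values filled
    in afterwards.
    """

    lambdas: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    kind: str
    window: Optional[np.ndarray] = None
    missing: Optional[np.ndarray] = None
    interpolated: Optional[np.ndarray] = None
    n_clipped: int = 0
    grid_shape: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.lambdas = np.atleast_2d(np.asarray(self.lambdas, dtype=float))
        if self.lambdas.shape[0] < self.lambdas.shape[1] and self.lambdas.shape[0] == 1:
            self.lambdas = self.lambdas.T
        self.values = np.asarray(self.values, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(
                self.values if self.values.ndim == 1 else self.values.reshape(len(self.values), -1).sum(axis=1)
            )

    @property
    def is_tensor(self) -> bool:
        return self.values.ndim == 3

    def scalars(self) -> np.ndarray:
        """Scalar profile: g itself in 1D, √det g for tensor fields."""
        if not self.is_tensor:
            return self.values
        return self.sqrt_det()

    def sqrt_det(self) -> np.ndarray:
        if not self.is_tensor:
            return np.sqrt(np.clip(self.values, 0.0, None))
        det = np.linalg.det(self.values)
        return np.sqrt(np.clip(det, 0.0, None))


def _crosscov(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased cross-covariance C_k = (1/n)Σ δa_{t+k} δb_t, k = 0..max_lag (FFT)."""
    n = len(a)
    da = a - a.mean()
    db = b - b.mean()
    size = 1
    while size < 2 * n:
        size *= 2
    fa = np.fft.rfft(da, size)
    fb = np.fft.rfft(db, size)
    corr = np.fft.irfft(fa * np.conjugate(fb), size)[: max_lag + 1]
    return corr / n


def _auto_window(rho: np.ndarray, cap: int, factor: float = 5.0) -> int:
    """Smallest W with W ≥ factor·τ_int(W); τ_int(W) = ½ + Σ_{k≤W} ρ_k."""
    tau = 0.5
    for w in range(1, cap + 1):
        tau += rho[w]
        if w >= factor * tau:
            return w
    return cap


def integrated_correlation(
    series_a,
    series_b,
    dt: float,
    window_rule: str = "auto",
    max_window: Optional[int] = None,
) -> float:
    """∫⟨δa(t) δb(0)⟩dt ≈ dt·(C₀/2 + Σ_{k=1..W} C_k), symmetrized in a↔b.

    ``window_rule`` is ``"auto"`` (self-consistent windowing) or ``"full"``
    (use the cap directly).  ``max_window`` caps W; default len/10.
    """
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("series must have equal lengths")
    n = len(a)
    if n < MIN_SERIES_LENGTH:
        raise ValueError(
            f"series of length {n} is too short for a correlation integral; "
            f"sample at least {MIN_SERIES_LENGTH} points"
        )
    cap = max(1, n // 10)
    if max_window is not None:
        cap = max(1, min(cap, int(max_window)))
    c_ab = _crosscov(a, b, cap)
    if a is b or np.shares_memory(a, b) or np.array_equal(a, b):
        c_sym = c_ab
    else:
        c_ba = _crosscov(b, a, cap)
        c_sym = 0.5 * (c_ab + c_ba)
    # normalization scale for the window rule
    va = float(np.var(a))
    vb = float(np.var(b))
    scale = np.sqrt(va * vb)
    if scale <= 0:
        return 0.0
    rho = c_sym / scale
    w = _auto_window(rho, cap) if window_rule == "auto" else cap
    return float(dt * (0.5 * c_sym[0] + np.sum(c_sym[1 : w + 1])))


def _series_metric(samples: np.ndarray, dt: float, window_rule: str,
                   max_window: Optional[int]):
    """Friction metric value of one multi-component force series."""
    d = samples.shape[1]
    if d == 1:
        return integrated_correlation(samples[:, 0], samples[:, 0], dt,
                                      window_rule, max_window)
    g = np.empty((d, d))
    for mu in range(d):
        for nu in range(mu, d):
            val = integrated_correlation(samples[:, mu], samples[:, nu], dt,
                                         window_rule, max_window)
            g[mu, nu] = g[nu, mu] = val
    return g


def _jackknife(samples: np.ndarray, dt: float, window_rule: str,
               max_window: Optional[int], n_blocks: int = 10):
    """Jackknife SE from per-block metric estimates on contiguous blocks."""
    n = samples.shape[0]
    n_blocks = min(n_blocks, n // MIN_SERIES_LENGTH)
    if n_blocks < 2:
        return np.full(
            () if samples.shape[1] == 1 else (samples.shape[1], samples.shape[1]), np.nan
        )
    blocks = np.array_split(samples, n_blocks, axis=0)
    vals = np.array([
        _series_metric(b, dt, window_rule, max_window) for b in blocks
    ])
    theta = vals.mean(axis=0)
    loo = np.array([(n_blocks * theta - vals[i]) / (n_blocks - 1) for i in range(n_blocks)])
    return np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))


def friction_metric(
    force_series: "List[ForceSeries]",
    window_rule: str = "auto",
    max_window: Optional[int] = None,
    n_blocks: int = 10,
) -> MetricEstimate:
    """Friction metric g(λ) from fixed-λ generalized-force series.

    Scalar per point in 1D, symmetric tensor in higher λ dimension; the
    series must be long compared to the force correlation time for the
    correlation integral to converge.  Negative scalar estimates (possible
    at finite sampling) are clipped to zero and counted.
    """
    if not force_series:
        raise ValueError("need at least one force series")
    lams = np.array([fs.lam for fs in force_series])
    d = force_series[0].samples.shape[1]
    values, errors, windows = [], [], []
    n_clipped = 0
    for fs in force_series:
        g = _series_metric(fs.samples, fs.dt, window_rule, max_window)
        if d == 1 and g < 0:
            g = 0.0
            n_clipped += 1
            logger.info("clipped negative friction estimate at lambda=%s", fs.lam)
        values.append(g)
        errors.append(_jackknife(fs.samples, fs.dt, window_rule, max_window, n_blocks))
        windows.append(len(fs.samples))
    values = np.asarray(values)
    return MetricEstimate(
        lambdas=lams,
        values=values if d > 1 else values.reshape(-1),
        stderr=np.asarray(errors),
        kind="friction",
        window=np.asarray(windows),
        n_clipped=n_clipped,
    )


def fisher_rao_metric(force_series: "List[ForceSeries]", n_blocks: int = 10) -> MetricEstimate:
    """Equal-time (co)variance of ∂H/∂λ per grid point (no time correlations)."""
    if not force_series:
        raise ValueError("need at least one force series")
    lams = np.array([fs.lam for fs in force_series])
    d = force_series[0].samples.shape[1]
    values, errors = [], []
    for fs in force_series:
        x = fs.samples
        cov = np.cov(x, rowvar=False, ddof=0)
        values.append(float(cov) if d == 1 else np.atleast_2d(cov))
        nb = min(n_blocks, len(x) // 10)
        if nb >= 2:
            blocks = np.array_split(x, nb, axis=0)
            vals = np.array([
                float(np.cov(b, rowvar=False, ddof=0)) if d == 1 else np.atleast_2d(np.cov(b, rowvar=False, ddof=0))
                for b in blocks
            ])
            errors.append(vals.std(axis=0, ddof=1) / np.sqrt(nb))
        else:
            errors.append(np.full((d, d) if d > 1 else (), np.nan))
    return MetricEstimate(
        lambdas=lams,
        values=np.asarray(values),
        stderr=np.asarray(errors),
        kind="fisher_rao",
    )


def _weighted_point_metric(forces: np.ndarray, weights: np.ndarray, dt: float,
                           window_rule: str, max_window: Optional[int]):
    """Diffusion-metric numerator/denominator for one grid point.

    ``forces``: (S, D) force components at this point; ``weights``: (S,)
    conditional weights.  Returns (∫corr of δF·w, ⟨w²⟩); the caller divides.
    """
    w2 = float(np.mean(weights**2))
    if w2 <= 0:
        return None, 0.0
    wsum = weights.sum()
    fbar = (weights[:, None] * forces).sum(axis=0) / wsum
    prod = (forces - fbar) * weights[:, None]
    d = forces.shape[1]
    if d == 1:
        num = integrated_correlation(prod[:, 0], prod[:, 0], dt, window_rule, max_window)
    else:
        num = np.empty((d, d))
        for mu in range(d):
            for nu in range(mu, d):
                val = integrated_correlation(prod[:, mu], prod[:, nu], dt,
                                             window_rule, max_window)
                num[mu, nu] = num[nu, mu] = val
    return num, w2


def diffusion_metric(
    trajectory: "Trajectory",
    window_rule: str = "auto",
    max_window: Optional[int] = None,
    interpolate_missing: bool = False,
    min_weight_mass: float = 1e-10,
) -> MetricEstimate:
    """Diffusion metric from an expanded-ensemble trajectory.

    For each grid point the integrated correlation of δF_λ(t)·w_λ(t) is
    normalized by ⟨w_λ²⟩, with δF taken about the w-weighted mean force.
    Points the walk never visited are reported missing; log-linear
    interpolation across gaps is applied only on request and flagged.
    Multiple walkers contribute sample-weighted averages of their
    correlation integrals.
    """
    grid = trajectory.lambda_grid
    k_states, d = grid.shape[0], trajectory.walkers[0].forces.shape[2]
    dt = trajectory.dt_between_samples
    shape = (k_states,) if d == 1 else (k_states, d, d)
    values = np.full(shape, np.nan)
    missing = np.zeros(k_states, dtype=bool)
    n_clipped = 0
    for j in range(k_states):
        nums, dens, lens = [], [], []
        for wt in trajectory.walkers:
            mean_w2 = float(np.mean(wt.weights[:, j] ** 2))
            if mean_w2 < min_weight_mass:
                continue
            num, w2 = _weighted_point_metric(
                wt.forces[:, j, :], wt.weights[:, j], dt, window_rule, max_window
            )
            if num is None:
                continue
            nums.append(num)
            dens.append(w2)
            lens.append(len(wt.weights))
        if not nums:
            missing[j] = True
            continue
        lens = np.asarray(lens, dtype=float)
        frac = lens / lens.sum()
        num = sum(f * n for f, n in zip(frac, nums))
        den = float(np.dot(frac, dens))
        g = num / den
        if d == 1 and g < 0:
            g = 0.0
            n_clipped += 1
        values[j] = g
    interpolated = np.zeros(k_states, dtype=bool)
    if interpolate_missing and missing.any() and (~missing).sum() >= 2:
        scal = values if d == 1 else np.linalg.det(values)
        good = ~missing
        pos = np.arange(k_states, dtype=float)
        logv = np.log(np.clip(scal[good], 1e-300, None))
        fill = np.exp(np.interp(pos[missing], pos[good], logv))
        if d == 1:
            values[missing] = fill
        else:  # isotropic tensor with the interpolated determinant
            values[missing] = np.sqrt(fill)[:, None, None] * np.eye(d)
        interpolated = missing.copy()
        missing = np.zeros(k_states, dtype=bool)
        logger.info("interpolated diffusion metric at %d grid points", interpolated.sum())
    return MetricEstimate(
        lambdas=grid,
        values=values,
        stderr=np.full(shape, np.nan),
        kind="diffusion",
        missing=missing,
        interpolated=interpolated,
        n_clipped=n_clipped,
    )


def metric_field_2d(trajectory: "Trajectory", grid_shape: tuple,
                    window_rule: str = "auto", max_window: Optional[int] = None,
                    interpolate_missing: bool = True) -> MetricEstimate:
    """2×2 diffusion-metric tensor field on a rectangular 2D λ grid.

    The trajectory's flat grid must enumerate a (n₁, n₂) rectangle; the
    returned estimate carries ``grid_shape`` so that √det g can be mapped
    back onto the rectangle for path optimization.
    """
    n1, n2 = grid_shape
    if n1 * n2 != trajectory.lambda_grid.shape[0]:
        raise ValueError("grid_shape does not match the trajectory's lambda grid")
    est = diffusion_metric(trajectory, window_rule=window_rule, max_window=max_window,
                           interpolate_missing=interpolate_missing)
    est.grid_shape = (n1, n2)
    return est


class OnlineDiffusionMetric:
    """Blocked on-the-fly diffusion-metric accumulator with forgetting.

    Samples stream in one at a time; every ``block_size`` samples the block
    contributes a correlation integral per grid point, and blocks are
    combined with exponential forgetting (half-life in blocks) so that
    early, not-yet-equilibrated data fades out.  Used to drive dynamic
    target optimization during expanded-ensemble runs.
    """

    def __init__(self, lambda_grid: np.ndarray, dt: float, block_size: int = 64,
                 half_life_blocks: float = 10.0, window_rule: str = "auto"):
        self.lambda_grid = np.atleast_2d(lambda_grid)
        self.k_states = self.lambda_grid.shape[0]
        self.dt = dt
        self.block_size = max(int(block_size), MIN_SERIES_LENGTH)
        self.decay = 0.5 ** (1.0 / half_life_blocks)
        self.window_rule = window_rule
        self._buf_f: list = []
        self._buf_w: list = []
        d = self.lambda_grid.shape[1]
        self._num = np.zeros((self.k_states,) if d == 1 else (self.k_states, d, d))
        self._den = np.zeros(self.k_states)
        self._norm = np.zeros(self.k_states)
        self.n_blocks = 0

    def add_sample(self, forces: np.ndarray, weights: np.ndarray) -> None:
        self._buf_f.append(np.asarray(forces, dtype=float))
        self._buf_w.append(np.asarray(weights, dtype=float))
        if len(self._buf_w) >= self.block_size:
            self._flush()

    def _flush(self) -> None:
        forces = np.asarray(self._buf_f)      # (S, K, D)
        weights = np.asarray(self._buf_w)     # (S, K)
        self._buf_f, self._buf_w = [], []
        self._num *= self.decay
        self._den *= self.decay
        self._norm *= self.decay
        for j in range(self.k_states):
            w = weights[:, j]
            mass = float(np.mean(w**2))
            if mass <= 0:
                continue
            num, w2 = _weighted_point_metric(forces[:, j, :], w, self.dt,
                                             self.window_rule, max_window=len(w) // 4)
            if num is None:
                continue
            self._num[j] += num
            self._den[j] += w2
            self._norm[j] += 1.0
        self.n_blocks += 1

    def estimate(self) -> Optional[MetricEstimate]:
        """Current metric estimate, or None until at least one block landed."""
        if self.n_blocks == 0:
            return None
        ok = self._den > 0
        if not np.any(ok):
            return None
        values = np.full_like(self._num, np.nan)
        den = self._den[ok] if self._num.ndim == 1 else self._den[ok][:, None, None]
        values[ok] = self._num[ok] / den
        if self._num.ndim == 1:
            values = np.where(ok, np.clip(values, 0.0, None), np.nan)
            # unsampled points: fall back to the smallest seen value so the
            # target floor, not a spurious zero, decides their share
            if np.any(~ok) and np.any(ok):
                values[~ok] = np.nanmin(values[ok])
        return MetricEstimate(
            lambdas=self.lambda_grid,
            values=values,
            stderr=np.full_like(values, np.nan),
            kind="diffusion",
            missing=~ok,
        )
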