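"""Path functionals and λ-path optimization.

A λ path {λ^μ(s) | s ∈ [0,1]} connects the end states; given a metric
g_μν(λ) its thermodynamic length and variance functional are

    𝓛 = ∫₀¹ √(λ̇^μ g_μν λ̇^ν) ds,      𝕍 = ∫₀¹ (λ̇^μ g_μν λ̇^ν) / π_s ds,

with the Cauchy–Schwarz bound 𝕍 ≥ 𝓛², saturated when the sampling target
follows π_s ∝ √(λ̇ᵀ g λ̇) (equivalently π_λ = √g/𝓛 in 1D).  The (theoretical)
improvement factor IF = 𝓛²/𝕍_unif ∈ (0, 1] is the predicted fraction of
compute time the optimal target needs relative to uniform sampling.

Discretization: the midpoint/endpoint-averaged-metric rule is used for
both 𝓛 and 𝕍 (segment length ℓ_i = √(Δλᵀ ḡ Δλ), segment target mass p_i),
so the discrete bound 𝕍 = Σ ℓ_i²/p_i ≥ (Σ ℓ_i)² = 𝓛² is exact and equality
at p_i ∝ ℓ_i holds to machine precision — no discretization slack is needed
in the equality case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import networkx as nx
import numpy as np

from .metrics import MetricEstimate

__all__ = [
    "LambdaPath",
    "PathDiagnostics",
    "metric_on_path",
    "path_length",
    "segment_lengths",
    "variance_functional",
    "optimal_target",
    "improvement_factor",
    "path_diagnostics",
    "build_simultaneous_path",
    "build_sequential_path",
    "build_three_leg_path",
    "reparameterize_path",
    "optimize_path_2d",
]

_NEG_TOL = 1e-10


@dataclass
class LambdaPath:
    """Ordered λ vectors with strictly increasing parameter s ∈ [0, 1]."""

    lambdas: np.ndarray            # (n, D)
    s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lambdas = np.atleast_2d(np.asarray(self.lambdas, dtype=float))
        if self.lambdas.shape[0] < 2:
            raise ValueError("a path needs at least two points")
        if self.s is None:
            self.s = np.linspace(0.0, 1.0, self.lambdas.shape[0])
        self.s = np.asarray(self.s, dtype=float)
        if len(self.s) != self.lambdas.shape[0]:
            raise ValueError("s and lambdas must have matching lengths")
        if not (np.all(np.diff(self.s) > 0) and self.s[0] == 0.0 and self.s[-1] == 1.0):
            raise ValueError("s must increase strictly from 0 to 1")

    @property
    def n_points(self) -> int:
        return self.lambdas.shape[0]

    @property
    def n_dims(self) -> int:
        return self.lambdas.shape[1]


@dataclass
class PathDiagnostics:
    """Length, variance functionals and predicted improvement for one path."""

    length: float
    v_uniform: float
    v_target: float
    improvement_factor: float
    optimal_pi: np.ndarray
    total_time: Optional[float] = None
    var_estimate: Optional[float] = None


def _tensor_at(metric, lam: np.ndarray, d: int) -> np.ndarray:
    """Evaluate a metric (callable | MetricEstimate | array) as a D×D tensor."""
    if callable(metric):
        val = np.asarray(metric(lam if d > 1 else float(lam[0])), dtype=float)
    elif isinstance(metric, MetricEstimate):
        val = _interp_estimate(metric, lam)
    else:
        raise TypeError("metric must be callable or a MetricEstimate")
    if val.ndim == 0:
        return val.reshape(1, 1)
    return val


def _interp_estimate(est: MetricEstimate, lam: np.ndarray) -> np.ndarray:
    grid = est.lambdas
    if grid.shape[1] == 1:
        xs = grid[:, 0]
        order = np.argsort(xs)
        if est.is_tensor:
            d = est.values.shape[1]
            out = np.empty((d, d))
            for mu in range(d):
                for nu in range(d):
                    out[mu, nu] = np.interp(lam[0], xs[order], est.values[order, mu, nu])
            return out
        return np.atleast_1d(np.interp(lam[0], xs[order], est.values[order])).reshape(1, 1)
    if est.grid_shape is None:
        raise ValueError("2D interpolation needs grid_shape on the MetricEstimate")
    n1, n2 = est.grid_shape
    x1 = est.lambdas[:, 0].reshape(n1, n2)[:, 0]
    x2 = est.lambdas[:, 1].reshape(n1, n2)[0, :]
    vals = est.values.reshape(n1, n2, *est.values.shape[1:])
    i = int(np.clip(np.searchsorted(x1, lam[0]) - 1, 0, n1 - 2))
    j = int(np.clip(np.searchsorted(x2, lam[1]) - 1, 0, n2 - 2))
    t = 0.0 if x1[i + 1] == x1[i] else (lam[0] - x1[i]) / (x1[i + 1] - x1[i])
    u = 0.0 if x2[j + 1] == x2[j] else (lam[1] - x2[j]) / (x2[j + 1] - x2[j])
    t = float(np.clip(t, 0.0, 1.0))
    u = float(np.clip(u, 0.0, 1.0))
    # bilinear per tensor component
    v = ((1 - t) * (1 - u) * vals[i, j] + t * (1 - u) * vals[i + 1, j]
         + (1 - t) * u * vals[i, j + 1] + t * u * vals[i + 1, j + 1])
    return np.atleast_2d(v)


def metric_on_path(path: LambdaPath, metric) -> np.ndarray:
    """Metric tensors evaluated at every path point, shape (n, D, D)."""
    d = path.n_dims
    return np.array([_tensor_at(metric, lam, d) for lam in path.lambdas])


def segment_lengths(path: LambdaPath, metric) -> np.ndarray:
    """ℓ_i = √(Δλᵀ ḡ Δλ) with ḡ the mean of the endpoint tensors."""
    tensors = metric_on_path(path, metric)
    dl = np.diff(path.lambdas, axis=0)
    gbar = 0.5 * (tensors[:-1] + tensors[1:])
    sq = np.einsum("id,idj,ij->i", dl, gbar, dl)
    if np.any(sq < -_NEG_TOL * np.max(np.abs(sq), initial=1.0)):
        raise ValueError("metric is negative along the path even after clipping")
    return np.sqrt(np.clip(sq, 0.0, None))


def path_length(path: LambdaPath, metric) -> float:
    """Thermodynamic length 𝓛 = Σ_i √(Δλᵀ ḡ Δλ) (additive over subpaths)."""
    return float(np.sum(segment_lengths(path, metric)))


def _segment_masses(path: LambdaPath, target) -> np.ndarray:
    """Per-segment target probability mass p_i from a per-point density π(s)."""
    ds = np.diff(path.s)
    if target is None:
        p = ds.copy()
    else:
        pi = np.asarray(target, dtype=float)
        if len(pi) == path.n_points:
            p = 0.5 * (pi[:-1] + pi[1:]) * ds
        elif len(pi) == path.n_points - 1:
            p = pi * ds
        else:
            raise ValueError("target must be per-point or per-segment")
        if np.any(p < 0) or p.sum() <= 0:
            raise ValueError("target must be positive on the path support")
    return p / p.sum()


def variance_functional(
    path: LambdaPath,
    metric,
    target=None,
    total_time: Optional[float] = None,
) -> Tuple[float, Optional[float]]:
    """(𝕍, Var ΔG) for a sampling target along the path.

    𝕍 = Σ_i ℓ_i²/p_i with p_i the per-segment target mass (uniform in s if
    ``target`` is None; the exact per-segment optimum p_i ∝ ℓ_i if
    ``target="optimal"``, for which 𝕍 = 𝓛² holds identically in the
    discrete form); Var ΔG = 2𝕍/τ when a total sampling time is given.
    """
    ell = segment_lengths(path, metric)
    if isinstance(target, str):
        if target != "optimal":
            raise ValueError(f"unknown target mode {target!r}")
        if ell.sum() <= 0:
            raise ValueError("optimal target undefined for a zero-length path")
        p = ell / ell.sum()
    else:
        p = _segment_masses(path, target)
    if np.any((p <= 0) & (ell > 0)):
        raise ValueError("target vanishes on a segment with nonzero length")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ell > 0, ell**2 / p, 0.0)
    v = float(np.sum(terms))
    var = 2.0 * v / total_time if total_time else None
    return v, var


def optimal_target(path: LambdaPath, metric) -> np.ndarray:
    """Optimal per-point target density π(s) ∝ √(λ̇ᵀ g λ̇) (i.e. √g/𝓛 in 1D).

    Invariant to an overall scaling of the metric; normalized so that the
    trapezoidal integral over s equals 1.
    """
    ell = segment_lengths(path, metric)
    ds = np.diff(path.s)
    speed = ell / ds                      # per-segment √(λ̇ᵀgλ̇)
    pi = np.empty(path.n_points)
    pi[0] = speed[0]
    pi[-1] = speed[-1]
    pi[1:-1] = (ell[:-1] + ell[1:]) / (ds[:-1] + ds[1:])
    norm = float(np.sum(0.5 * (pi[:-1] + pi[1:]) * ds))
    if norm <= 0:
        return np.full(path.n_points, 1.0)
    return pi / norm


def improvement_factor(path: LambdaPath, metric) -> float:
    """IF = 𝓛²/𝕍_uniform ∈ (0, 1]; equals 1 iff the speed √(λ̇ᵀgλ̇) is constant."""
    length = path_length(path, metric)
    v_unif, _ = variance_functional(path, metric, target=None)
    if v_unif <= 0:
        return 1.0
    return float(length**2 / v_unif)


def path_diagnostics(
    path: LambdaPath,
    metric,
    target: Optional[np.ndarray] = None,
    total_time: Optional[float] = None,
) -> PathDiagnostics:
    """Bundle 𝓛, 𝕍_unif, 𝕍(π), IF and the optimal target for one path."""
    length = path_length(path, metric)
    v_unif, _ = variance_functional(path, metric, target=None)
    v_tgt, var = variance_functional(path, metric, target=target, total_time=total_time)
    return PathDiagnostics(
        length=length,
        v_uniform=v_unif,
        v_target=v_tgt,
        improvement_factor=(length**2 / v_unif) if v_unif > 0 else 1.0,
        optimal_pi=optimal_target(path, metric),
        total_time=total_time,
        var_estimate=var,
    )


# ---------------------------------------------------------------------------
# Path constructions
# ---------------------------------------------------------------------------

def build_simultaneous_path(n_points: int, n_dims: int = 2) -> LambdaPath:
    """Diagonal path: all λ components move together on n equidistant points."""
    if n_points < 2:
        raise ValueError("need at least two points")
    s = np.linspace(0.0, 1.0, n_points)
    return LambdaPath(lambdas=np.tile(s[:, None], (1, n_dims)), s=s)


def build_sequential_path(n_points: int, component_order=None, n_dims: int = 2) -> LambdaPath:
    """One component at a time; the shared corner point is not duplicated.

    With 21 points in two dimensions this gives the familiar 11 + 11 − 1
    layout (one leg per component, one shared corner).
    """
    if component_order is None:
        component_order = list(range(n_dims))
    n_dims = len(component_order)
    if n_dims == 1:
        return build_simultaneous_path(n_points, 1)
    if n_points < n_dims + 1:
        raise ValueError("too few points for one leg per component")
    # distribute points over legs as evenly as possible, corners shared
    base = (n_points - 1) // n_dims
    extra = (n_points - 1) % n_dims
    lams = [np.zeros(n_dims)]
    current = np.zeros(n_dims)
    for leg, comp in enumerate(component_order):
        n_seg = base + (1 if leg < extra else 0)
        for i in range(1, n_seg + 1):
            nxt = current.copy()
            nxt[comp] = i / n_seg
            lams.append(nxt)
        current = lams[-1].copy()
    return LambdaPath(lambdas=np.asarray(lams))


def build_three_leg_path(channel_value: float, n_points: int) -> LambdaPath:
    """Straight-leg path (0,0)→(c,0)→(c,1)→(1,1) in (λ_coulomb, λ_other).

    First move λ_coulomb to the channel value c, traverse the channel in
    λ_other, then finish λ_coulomb; points are distributed over the legs in
    proportion to Euclidean leg length and the total count is exact.  With
    c = 0 the path degenerates to a sequential (one-component-at-a-time)
    path.
    """
    if not 0.0 <= channel_value <= 1.0:
        raise ValueError("channel_value must lie in [0, 1]")
    if n_points < 4:
        raise ValueError("need at least four points")
    corners = np.array([
        [0.0, 0.0],
        [channel_value, 0.0],
        [channel_value, 1.0],
        [1.0, 1.0],
    ])
    leg_len = np.linalg.norm(np.diff(corners, axis=0), axis=1)
    n_segments = n_points - 1
    keep = leg_len > 0
    raw = np.where(keep, leg_len, 0.0)
    alloc = np.floor(n_segments * raw / raw.sum()).astype(int)
    alloc[keep] = np.maximum(alloc[keep], 1)
    while alloc.sum() > n_segments:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_segments:
        frac = n_segments * raw / raw.sum() - alloc
        frac[~keep] = -np.inf
        alloc[np.argmax(frac)] += 1
    lams = [corners[0]]
    for leg in range(3):
        if alloc[leg] == 0:
            continue
        for i in range(1, alloc[leg] + 1):
            lams.append(corners[leg] + (corners[leg + 1] - corners[leg]) * i / alloc[leg])
    return LambdaPath(lambdas=np.asarray(lams))


def reparameterize_path(path: LambdaPath, metric) -> LambdaPath:
    """Redistribute points to equal metric length per segment (π_s = 1).

    Inverts the cumulative thermodynamic length at uniform quantiles; the
    endpoints are fixed and the number of points preserved.
    """
    ell = segment_lengths(path, metric)
    total = float(ell.sum())
    if total <= 0:
        return LambdaPath(lambdas=path.lambdas.copy(), s=path.s.copy())
    cum = np.concatenate([[0.0], np.cumsum(ell)]) / total
    targets = np.linspace(0.0, 1.0, path.n_points)
    new_lams = np.empty_like(path.lambdas)
    for d in range(path.n_dims):
        new_lams[:, d] = np.interp(targets, cum, path.lambdas[:, d])
    new_lams[0] = path.lambdas[0]
    new_lams[-1] = path.lambdas[-1]
    return LambdaPath(lambdas=new_lams, s=targets)


# ---------------------------------------------------------------------------
# 2D shortest-path optimization
# ---------------------------------------------------------------------------

def optimize_path_2d(
    field: MetricEstimate,
    start=(0.0, 0.0),
    end=(1.0, 1.0),
    band: Optional[float] = None,
) -> Tuple[LambdaPath, float]:
    """Minimum-length simple path on the 8-connected grid of a tensor field.

    Edge cost √(Δλᵀ ḡ Δλ) with ḡ the mean of the endpoint tensors (negative
    eigen-directions clipped at zero through the quadratic form).  The
    optional band constraint |λ₁ − λ₂| ≤ d removes nodes where the two λ
    components differ too much.  Returns the path and its discrete 𝓛.
    """
    if field.grid_shape is None:
        raise ValueError("field needs grid_shape (use metric_field_2d or set it)")
    n1, n2 = field.grid_shape
    lams = field.lambdas.reshape(n1, n2, 2)
    if field.is_tensor:
        tensors = field.values.reshape(n1, n2, 2, 2)
    else:  # isotropic scalar field
        tensors = field.values.reshape(n1, n2)[:, :, None, None] * np.eye(2)

    def in_band(i, j):
        if band is None:
            return True
        return abs(lams[i, j, 0] - lams[i, j, 1]) <= band + 1e-12

    def node_ok(i, j):
        return in_band(i, j) and np.all(np.isfinite(tensors[i, j]))

    graph = nx.Graph()
    moves = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for i in range(n1):
        for j in range(n2):
            if not node_ok(i, j):
                continue
            for di, dj in moves:
                i2, j2 = i + di, j + dj
                if not (0 <= i2 < n1 and 0 <= j2 < n2) or not node_ok(i2, j2):
                    continue
                dl = lams[i2, j2] - lams[i, j]
                gbar = 0.5 * (tensors[i, j] + tensors[i2, j2])
                cost = float(np.sqrt(max(dl @ gbar @ dl, 0.0)))
                graph.add_edge((i, j), (i2, j2), weight=cost)

    def locate(pt):
        d = np.sum((lams.reshape(-1, 2) - np.asarray(pt)) ** 2, axis=1)
        idx = int(np.argmin(d))
        return (idx // n2, idx % n2)

    src, dst = locate(start), locate(end)
    if src not in graph or dst not in graph:
        raise ValueError(f"start or end excluded by the band constraint |dl|<={band}")
    try:
        nodes = nx.dijkstra_path(graph, src, dst, weight="weight")
    except nx.NetworkXNoPath:
        raise ValueError(f"feasible region disconnected under band constraint |dl|<={band}")
    cost = float(nx.path_weight(graph, nodes, weight="weight"))
    path_lams = np.array([lams[i, j] for i, j in nodes])
    return LambdaPath(lambdas=path_lams), cost
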