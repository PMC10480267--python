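"""Toy alchemical model systems with analytic λ-derivatives.

An alchemical transformation couples a Hamiltonian H(x; λ) between two end
states, H = H_A at λ = 0 and H = H_B at λ = 1; the intermediate form is a
free choice.  Everything here is expressed in reduced units (k_B = 1), so
inverse temperature β = 1/T and all energies are in units of k_B·T at T = 1.

The systems in this module are deliberately small — a λ-coupled harmonic
oscillator, a soft-core pair potential, a 2D micro-solvation box and a
two-component λ toy — so that free energies, mean generalized forces and
(for the Gaussian systems) the full friction metric are available in closed
form and can serve as oracles for the samplers and estimators built on top.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "KB",
    "ThermoParams",
    "Configuration",
    "AlchemicalSystem",
    "SingularConfigurationError",
    "softcore_distance",
    "softcore_pair_energy",
    "softcore_dVdlambda",
    "SoftCorePair",
    "HarmonicAlchemy",
    "harmonic_free_energy",
    "mean_gradient_harmonic",
    "MicroSolvationSystem",
    "TwoLambdaToy",
    "make_system",
]

#: Boltzmann constant in the package's reduced unit convention.
KB = 1.0


class SingularConfigurationError(ValueError):
    """Raised when a configuration sits on a potential singularity (r = 0
    with a plain, non-soft-core interaction)."""


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic state: temperature in energy/k_B units (reduced)."""

    temperature: float = 1.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive and finite, got {self.temperature}")

    @property
    def beta(self) -> float:
        """Inverse temperature 1/(k_B T)."""
        return 1.0 / (KB * self.temperature)


@dataclass
class Configuration:
    """Positions (and optionally momenta) of all particles."""

    coordinates: np.ndarray
    momenta: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("configuration coordinates must be finite")
        if self.momenta is not None:
            self.momenta = np.asarray(self.momenta, dtype=float)
            if not np.all(np.isfinite(self.momenta)):
                raise ValueError("configuration momenta must be finite")


def _as_lambda_vector(lam, n_dims: int) -> np.ndarray:
    vec = np.atleast_1d(np.asarray(lam, dtype=float))
    if vec.shape != (n_dims,):
        raise ValueError(f"lambda vector has shape {vec.shape}, expected ({n_dims},)")
    if not np.all(np.isfinite(vec)):
        raise ValueError("lambda components must be finite")
    return vec


class AlchemicalSystem(ABC):
    """Abstract contract for a λ-coupled Hamiltonian.

    Implementations provide the potential energy, its spatial gradient and
    the vector of generalized-force conjugates ∂H/∂λ^μ.  The endpoint
    contract is H(x; 0,…,0) = H_A and H(x; 1,…,1) = H_B.
    """

    n_lambda_dims: int = 1

    def lam_vector(self, lam) -> np.ndarray:
        return _as_lambda_vector(lam, self.n_lambda_dims)

    @abstractmethod
    def energy(self, x: np.ndarray, lam) -> float:
        """Potential energy H(x; λ)."""

    @abstractmethod
    def dhdlambda(self, x: np.ndarray, lam) -> np.ndarray:
        """Vector of ∂H/∂λ^μ, shape (n_lambda_dims,).

        The generalized force conjugate to λ is F_μ = −∂H/∂λ^μ.
        """

    @abstractmethod
    def gradient(self, x: np.ndarray, lam) -> np.ndarray:
        """Spatial gradient ∇_x H(x; λ) (negative of the force on x)."""

    @abstractmethod
    def initial_configuration(self, rng: np.random.Generator) -> np.ndarray:
        """A reasonable starting configuration for sampling."""

    # Grid conveniences; subclasses may vectorize these.
    def energy_grid(self, x: np.ndarray, lambda_grid: np.ndarray) -> np.ndarray:
        """Energies at every λ point of a grid, shape (K,)."""
        return np.array([self.energy(x, lam) for lam in np.atleast_2d(lambda_grid)])

    def dhdlambda_grid(self, x: np.ndarray, lambda_grid: np.ndarray) -> np.ndarray:
        """∂H/∂λ at every λ point, shape (K, n_lambda_dims)."""
        return np.array([self.dhdlambda(x, lam) for lam in np.atleast_2d(lambda_grid)])

    # Block propagation; subclasses with linear forces may vectorize the
    # identical Euler recursion (same trajectory, sample for sample).
    def simulate_block(self, x: np.ndarray, lam, noise: np.ndarray, step_over_gamma: float) -> np.ndarray:
        """Positions after each of len(noise) overdamped Euler steps.

        Implements x_{t+1} = x_t − (Δt/γ)∇H(x_t; λ) + noise_t and returns
        the stacked positions, shape (n_steps, *x.shape).
        """
        out = np.empty_like(noise)
        for i in range(len(noise)):
            x = x - step_over_gamma * self.gradient(x, lam) + noise[i]
            out[i] = x
        return out

    def dhdlambda_block(self, xs: np.ndarray, lam) -> np.ndarray:
        """∂H/∂λ for a stack of configurations, shape (m, n_lambda_dims)."""
        return np.array([self.dhdlambda(x, lam) for x in xs])

    def energy_grid_block(self, xs: np.ndarray, lambda_grid: np.ndarray) -> np.ndarray:
        """Energies of a stack of configurations at all grid points, (K, m)."""
        return np.array([self.energy_grid(x, lambda_grid) for x in xs]).T


# ---------------------------------------------------------------------------
# Soft-core pair potential
# ---------------------------------------------------------------------------

def softcore_distance(r, sigma, lambda_factor, alpha: float = 0.5, p_exponent: int = 1):
    """Soft-core modified distance (α σ⁶ λ^p + r⁶)^{1/6}.

    ``lambda_factor`` is the coupling factor of the *other* end state: the
    state-A potential is evaluated at the distance softened by λ^p, the
    state-B potential at the distance softened by (1−λ)^p, so each state's
    singularity is lifted exactly when its weight goes to zero.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("pair distance r must be non-negative")
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be positive")
    lf = np.asarray(lambda_factor, dtype=float)
    if np.any(lf < 0) or np.any(lf > 1):
        raise ValueError("lambda_factor must lie in [0, 1]")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return (alpha * sigma**6 * lf**p_exponent + r**6) ** (1.0 / 6.0)


def _lj(r, sigma, epsilon):
    """Plain Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶]."""
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def _lj_dr(r, sigma, epsilon):
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r


def _coul(r, q_product):
    return q_product / r


def _coul_dr(r, q_product):
    return -q_product / r**2


@dataclass(frozen=True)
class SoftCorePair:
    """Soft-core λ-coupled pair interaction between two end states.

    The Lennard-Jones soft-core distance is used for the Coulomb term as
    well, which avoids artificial minima from mismatched distance
    functions.  Defaults: α = 0.5, p = 1.
    """

    sigma_A: float = 1.0
    sigma_B: float = 1.0
    epsilon_A: float = 1.0
    epsilon_B: float = 1.0
    charge_product_A: float = 0.0
    charge_product_B: float = 0.0
    alpha: float = 0.5
    p_exponent: int = 1

    def __post_init__(self) -> None:
        if self.sigma_A <= 0 or self.sigma_B <= 0:
            raise ValueError("sigma parameters must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.p_exponent not in (1, 2):
            raise ValueError("p_exponent must be 1 or 2")

    def _state_energy(self, r_state, sigma, epsilon, q_product):
        e = np.zeros_like(np.asarray(r_state, dtype=float))
        if epsilon != 0.0:
            e = e + _lj(r_state, sigma, epsilon)
        if q_product != 0.0:
            e = e + _coul(r_state, q_product)
        return e

    def _state_energy_dr(self, r_state, sigma, epsilon, q_product):
        d = np.zeros_like(np.asarray(r_state, dtype=float))
        if epsilon != 0.0:
            d = d + _lj_dr(r_state, sigma, epsilon)
        if q_product != 0.0:
            d = d + _coul_dr(r_state, q_product)
        return d

    def _check_singular(self, r, lam) -> None:
        at_A = lam == 0.0 and (self.epsilon_A != 0.0 or self.charge_product_A != 0.0)
        at_B = lam == 1.0 and (self.epsilon_B != 0.0 or self.charge_product_B != 0.0)
        if np.any(np.asarray(r) == 0.0) and (at_A or at_B):
            raise SingularConfigurationError(
                "r = 0 with a fully coupled plain potential (lambda at an end point)"
            )

    def distances(self, r, lam):
        """Soft-core distances (r_A, r_B) at coupling λ (unchecked fast path)."""
        r6 = np.asarray(r, dtype=float) ** 6
        p = self.p_exponent
        r_a = (self.alpha * self.sigma_A**6 * lam**p + r6) ** (1.0 / 6.0)
        r_b = (self.alpha * self.sigma_B**6 * (1.0 - lam) ** p + r6) ** (1.0 / 6.0)
        return r_a, r_b

    def energy(self, r, lam: float):
        """V_sc(r) = (1−λ) V^A(r_A) + λ V^B(r_B)."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self._check_singular(r, lam)
        r_a, r_b = self.distances(r, lam)
        v = 0.0
        if lam < 1.0:
            v = v + (1.0 - lam) * self._state_energy(
                r_a, self.sigma_A, self.epsilon_A, self.charge_product_A
            )
        if lam > 0.0:
            v = v + lam * self._state_energy(
                r_b, self.sigma_B, self.epsilon_B, self.charge_product_B
            )
        return v

    def dVdlambda(self, r, lam: float):
        """Analytic ∂V_sc/∂λ, including the λ-dependence of r_A and r_B."""
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self._check_singular(r, lam)
        r_a, r_b = self.distances(r, lam)
        p = self.p_exponent
        va = self._state_energy(r_a, self.sigma_A, self.epsilon_A, self.charge_product_A)
        vb = self._state_energy(r_b, self.sigma_B, self.epsilon_B, self.charge_product_B)
        out = vb - va
        # dr_A/dλ = α σ_A⁶ p λ^{p−1} / (6 r_A⁵); dr_B/dλ = −α σ_B⁶ p (1−λ)^{p−1} / (6 r_B⁵)
        if lam < 1.0 or p > 1:
            dva = self._state_energy_dr(r_a, self.sigma_A, self.epsilon_A, self.charge_product_A)
            dra = self.alpha * self.sigma_A**6 * p * lam ** (p - 1) / (6.0 * r_a**5)
            out = out + (1.0 - lam) * dva * dra
        if lam > 0.0 or p > 1:
            dvb = self._state_energy_dr(r_b, self.sigma_B, self.epsilon_B, self.charge_product_B)
            drb = -self.alpha * self.sigma_B**6 * p * (1.0 - lam) ** (p - 1) / (6.0 * r_b**5)
            out = out + lam * dvb * drb
        return out

    def dVdr(self, r, lam: float):
        """Analytic ∂V_sc/∂r for pair forces; dr_state/dr = r⁵/r_state⁵."""
        self._check_singular(r, lam)
        r = np.asarray(r, dtype=float)
        r_a, r_b = self.distances(r, lam)
        out = np.zeros_like(r)
        if lam < 1.0:
            dva = self._state_energy_dr(r_a, self.sigma_A, self.epsilon_A, self.charge_product_A)
            out = out + (1.0 - lam) * dva * r**5 / r_a**5
        if lam > 0.0:
            dvb = self._state_energy_dr(r_b, self.sigma_B, self.epsilon_B, self.charge_product_B)
            out = out + lam * dvb * r**5 / r_b**5
        return out


def softcore_pair_energy(r, lam: float, pair: SoftCorePair, thermo: ThermoParams | None = None):
    """Soft-core pair energy; ``thermo`` is accepted for interface symmetry."""
    return pair.energy(r, lam)


def softcore_dVdlambda(r, lam: float, pair: SoftCorePair, thermo: ThermoParams | None = None):
    """Analytic λ-derivative of the soft-core pair energy."""
    return pair.dVdlambda(r, lam)


# ---------------------------------------------------------------------------
# Harmonic oscillator toy
# ---------------------------------------------------------------------------

class HarmonicAlchemy(AlchemicalSystem):
    """λ-coupled harmonic oscillator: H = ½ k(λ) Σx², k(λ) = (1−λ)k_A + λk_B.

    Closed forms (β = 1/T, overdamped friction γ):

    * free energy difference   ΔG = ln(k_B/k_A) / (2β)
    * mean gradient            ⟨∂H/∂λ⟩ = (k_B − k_A) / (2β k(λ))
    * friction metric          g(λ) = (k_B − k_A)² γ / (4 β² k(λ)³)
    * Fisher–Rao metric        (k_B − k_A)² / (2 β² k(λ)²)
    """

    n_lambda_dims = 1

    def __init__(self, k_A: float = 1.0, k_B: float = 4.0, n_dof: int = 1):
        if k_A <= 0 or k_B <= 0:
            raise ValueError("spring constants must be positive")
        self.k_A = float(k_A)
        self.k_B = float(k_B)
        self.n_dof = int(n_dof)

    def spring_constant(self, lam: float) -> float:
        return (1.0 - lam) * self.k_A + lam * self.k_B

    def energy(self, x, lam) -> float:
        (l,) = self.lam_vector(lam)
        return 0.5 * self.spring_constant(l) * float(np.sum(np.square(x)))

    def dhdlambda(self, x, lam) -> np.ndarray:
        self.lam_vector(lam)
        return np.array([0.5 * (self.k_B - self.k_A) * float(np.sum(np.square(x)))])

    def gradient(self, x, lam) -> np.ndarray:
        (l,) = self.lam_vector(lam)
        return self.spring_constant(l) * np.asarray(x, dtype=float)

    def initial_configuration(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.n_dof)

    def energy_grid(self, x, lambda_grid) -> np.ndarray:
        k = (1.0 - lambda_grid[:, 0]) * self.k_A + lambda_grid[:, 0] * self.k_B
        return 0.5 * k * float(np.sum(np.square(x)))

    def dhdlambda_grid(self, x, lambda_grid) -> np.ndarray:
        val = 0.5 * (self.k_B - self.k_A) * float(np.sum(np.square(x)))
        return np.full((len(lambda_grid), 1), val)

    def simulate_block(self, x, lam, noise, step_over_gamma):
        # linear force k(λ)x makes the Euler recursion an AR(1) filter
        from scipy.signal import lfilter

        (l,) = self.lam_vector(lam)
        c = 1.0 - step_over_gamma * self.spring_constant(l)
        x = np.asarray(x, dtype=float)
        out, _ = lfilter([1.0], [1.0, -c], noise, axis=0, zi=(c * x)[None, :])
        return out

    def dhdlambda_block(self, xs, lam) -> np.ndarray:
        return 0.5 * (self.k_B - self.k_A) * np.sum(np.square(xs), axis=1, keepdims=True)

    def energy_grid_block(self, xs, lambda_grid) -> np.ndarray:
        k = (1.0 - lambda_grid[:, 0]) * self.k_A + lambda_grid[:, 0] * self.k_B
        x2 = np.sum(np.square(xs), axis=1)
        return 0.5 * k[:, None] * x2[None, :]

    # Analytic references -------------------------------------------------
    def analytic_mean_gradient(self, lam: float, thermo: ThermoParams) -> float:
        return (self.k_B - self.k_A) * self.n_dof / (2.0 * thermo.beta * self.spring_constant(lam))

    def analytic_friction_metric(self, lam: float, gamma: float, thermo: ThermoParams) -> float:
        beta = thermo.beta
        k = self.spring_constant(lam)
        return (self.k_B - self.k_A) ** 2 * gamma * self.n_dof / (4.0 * beta**2 * k**3)

    def analytic_fisher_rao_metric(self, lam: float, thermo: ThermoParams) -> float:
        beta = thermo.beta
        k = self.spring_constant(lam)
        return (self.k_B - self.k_A) ** 2 * self.n_dof / (2.0 * beta**2 * k**2)


def harmonic_free_energy(system: HarmonicAlchemy, thermo: ThermoParams) -> float:
    """Exact ΔG = G_B − G_A = n_dof · ln(k_B/k_A) / (2β) (Gaussian partition ratio)."""
    return system.n_dof * math.log(system.k_B / system.k_A) / (2.0 * thermo.beta)


def mean_gradient_harmonic(system: HarmonicAlchemy, lam: float, thermo: ThermoParams) -> float:
    """Exact ⟨∂H/∂λ⟩_λ = (k_B − k_A)/(2 β k(λ)) per degree of freedom."""
    return system.analytic_mean_gradient(lam, thermo)


# ---------------------------------------------------------------------------
# 2D micro-solvation toy
# ---------------------------------------------------------------------------

class MicroSolvationSystem(AlchemicalSystem):
    """A solute coupled by soft-core interactions to a 2D Lennard-Jones bath.

    n_solvent particles interact through a plain, truncated-and-shifted LJ
    potential in a periodic square box (minimum image, cutoff at half the
    box length).  Particle 0 is the solute: at λ = 0 it is an ideal-gas
    particle, at λ = 1 it is fully coupled through the soft-core pair
    (whose state A is the null interaction).  Correlation times of the
    generalized force grow markedly with λ as the solute becomes caged,
    which is what makes this toy useful for metric contrast studies.
    """

    n_lambda_dims = 1

    def __init__(
        self,
        n_solvent: int = 8,
        box_length: float = 4.0,
        sigma_ss: float = 1.0,
        epsilon_ss: float = 1.0,
        solute: SoftCorePair | None = None,
    ):
        if n_solvent < 1 or n_solvent > 64:
            raise ValueError("n_solvent must be between 1 and 64 (desk scale)")
        if box_length <= 2.0 * sigma_ss:
            raise ValueError("box too small for the cutoff convention")
        self.n_solvent = int(n_solvent)
        self.box_length = float(box_length)
        self.sigma_ss = float(sigma_ss)
        self.epsilon_ss = float(epsilon_ss)
        self.solute = solute or SoftCorePair(
            sigma_A=1.0, sigma_B=1.0, epsilon_A=0.0, epsilon_B=1.0,
            charge_product_A=0.0, charge_product_B=0.0,
        )
        self.cutoff = self.box_length / 2.0
        # shift so the solvent-solvent potential is zero at the cutoff
        self._ss_shift = float(_lj(self.cutoff, self.sigma_ss, self.epsilon_ss))

    @property
    def n_particles(self) -> int:
        return self.n_solvent + 1

    def _minimum_image(self, disp: np.ndarray) -> np.ndarray:
        return disp - self.box_length * np.round(disp / self.box_length)

    def _solvent_pairs(self, x: np.ndarray):
        pos = x[1:]
        disp = self._minimum_image(pos[None, :, :] - pos[:, None, :])
        iu = np.triu_indices(self.n_solvent, k=1)
        d = disp[iu]
        r = np.sqrt(np.sum(d * d, axis=1))
        return d, r

    def _solute_pairs(self, x: np.ndarray):
        disp = self._minimum_image(x[1:] - x[0])
        r = np.sqrt(np.sum(disp * disp, axis=1))
        return disp, r

    def energy(self, x, lam) -> float:
        (l,) = self.lam_vector(lam)
        x = np.asarray(x, dtype=float).reshape(self.n_particles, 2)
        _, r_ss = self._solvent_pairs(x)
        inside = r_ss < self.cutoff
        e = float(np.sum(_lj(r_ss[inside], self.sigma_ss, self.epsilon_ss) - self._ss_shift))
        _, r_su = self._solute_pairs(x)
        inside_u = r_su < self.cutoff
        if np.any(inside_u) and l > 0.0:
            shift = self.solute.energy(self.cutoff, l)
            e += float(np.sum(self.solute.energy(r_su[inside_u], l) - shift))
        return e

    def _solute_energy_dlam(self, r_su: np.ndarray, l: float) -> float:
        inside = r_su < self.cutoff
        if not np.any(inside):
            return 0.0
        shift = self.solute.dVdlambda(self.cutoff, l)
        return float(np.sum(self.solute.dVdlambda(r_su[inside], l) - shift))

    def dhdlambda(self, x, lam) -> np.ndarray:
        (l,) = self.lam_vector(lam)
        x = np.asarray(x, dtype=float).reshape(self.n_particles, 2)
        _, r_su = self._solute_pairs(x)
        return np.array([self._solute_energy_dlam(r_su, l)])

    def dhdlambda_grid(self, x, lambda_grid) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(self.n_particles, 2)
        _, r_su = self._solute_pairs(x)
        return np.array([[self._solute_energy_dlam(r_su, float(l[0]))] for l in lambda_grid])

    def energy_grid(self, x, lambda_grid) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(self.n_particles, 2)
        _, r_ss = self._solvent_pairs(x)
        inside = r_ss < self.cutoff
        e_ss = float(np.sum(_lj(r_ss[inside], self.sigma_ss, self.epsilon_ss) - self._ss_shift))
        _, r_su = self._solute_pairs(x)
        inside_u = r_su < self.cutoff
        out = np.empty(len(lambda_grid))
        for j, lamv in enumerate(lambda_grid):
            l = float(lamv[0])
            e = e_ss
            if np.any(inside_u) and l > 0.0:
                shift = self.solute.energy(self.cutoff, l)
                e += float(np.sum(self.solute.energy(r_su[inside_u], l) - shift))
            out[j] = e
        return out

    def gradient(self, x, lam) -> np.ndarray:
        (l,) = self.lam_vector(lam)
        x = np.asarray(x, dtype=float).reshape(self.n_particles, 2)
        grad = np.zeros_like(x)
        # solvent-solvent forces
        pos = x[1:]
        disp = self._minimum_image(pos[None, :, :] - pos[:, None, :])  # disp[i,j] = r_j - r_i
        r = np.sqrt(np.sum(disp * disp, axis=2))
        np.fill_diagonal(r, np.inf)
        mask = r < self.cutoff
        dvdr = np.where(mask, _lj_dr(np.where(mask, r, 1.0), self.sigma_ss, self.epsilon_ss), 0.0)
        # dH/dx_i = sum_j dV/dr * (x_i - x_j)/r = -sum_j dvdr * disp[i,j]/r
        grad[1:] = -np.sum((dvdr / np.where(mask, r, 1.0))[:, :, None] * disp, axis=1)
        # solute-solvent forces
        if l > 0.0:
            dsp, r_su = self._solute_pairs(x)  # dsp = solvent - solute
            inside = r_su < self.cutoff
            if np.any(inside):
                dvdr_u = np.zeros_like(r_su)
                dvdr_u[inside] = self.solute.dVdr(r_su[inside], l)
                unit = dsp / r_su[:, None]
                contrib = dvdr_u[:, None] * unit
                grad[0] -= np.sum(contrib, axis=0)
                grad[1:] += contrib
        return grad

    def initial_configuration(self, rng: np.random.Generator) -> np.ndarray:
        n_side = int(math.ceil(math.sqrt(self.n_particles)))
        spacing = self.box_length / n_side
        pts = [
            (spacing * (i + 0.5), spacing * (j + 0.5))
            for i in range(n_side)
            for j in range(n_side)
        ]
        x = np.array(pts[: self.n_particles])
        x += 0.05 * spacing * rng.standard_normal(x.shape)
        return x


# ---------------------------------------------------------------------------
# Two-component λ toy
# ---------------------------------------------------------------------------

class TwoLambdaToy(AlchemicalSystem):
    """Two-component λ = (λ_c, λ_o) toy with a low-metric channel at λ_c = 0.5.

    A single 1D coordinate in a harmonic confinement of stiffness
    k(λ_o) = (1−λ_o)k_A + λ_o k_B (λ_o plays the role of the non-Coulomb
    coupling) plus a charge-like linear term q(λ_c)·x (a charge in a uniform
    field).  The charge interpolation

        q(λ_c) = q_A + Δq λ_c + a λ_c(1−λ_c)(1−2λ_c),   a = 2Δq by default,

    preserves the end states and makes q'(0.5) = 0, so fluctuations of the
    generalized force conjugate to λ_c vanish on the line λ_c = 0.5: a
    synthetic analogue of the low-metric channel seen in ligand-mutation
    metric landscapes.  With the default antisymmetric charges (q_A = −q_B)
    the mean position also vanishes on that line, which suppresses the
    dominant part of the λ_o component there as well, so the whole channel
    is cheap to traverse.  Being Gaussian, the full 2×2 friction tensor is
    analytic (see :meth:`analytic_friction_tensor`).
    """

    n_lambda_dims = 2

    def __init__(
        self,
        k_A: float = 1.0,
        k_B: float = 4.0,
        q_A: float = -1.0,
        q_B: float = 1.0,
        channel_amplitude: float | None = None,
    ):
        if k_A <= 0 or k_B <= 0:
            raise ValueError("spring constants must be positive")
        self.k_A = float(k_A)
        self.k_B = float(k_B)
        self.q_A = float(q_A)
        self.q_B = float(q_B)
        dq = self.q_B - self.q_A
        self.channel_amplitude = 2.0 * dq if channel_amplitude is None else float(channel_amplitude)

    def spring_constant(self, lam_o: float) -> float:
        return (1.0 - lam_o) * self.k_A + lam_o * self.k_B

    def charge(self, lam_c: float) -> float:
        dq = self.q_B - self.q_A
        a = self.channel_amplitude
        return self.q_A + dq * lam_c + a * lam_c * (1.0 - lam_c) * (1.0 - 2.0 * lam_c)

    def charge_dlam(self, lam_c: float) -> float:
        dq = self.q_B - self.q_A
        a = self.channel_amplitude
        return dq + a * (1.0 - 6.0 * lam_c + 6.0 * lam_c**2)

    def energy(self, x, lam) -> float:
        lc, lo = self.lam_vector(lam)
        xs = float(np.sum(np.asarray(x, dtype=float)))
        x2 = float(np.sum(np.square(x)))
        return 0.5 * self.spring_constant(lo) * x2 + self.charge(lc) * xs

    def dhdlambda(self, x, lam) -> np.ndarray:
        lc, lo = self.lam_vector(lam)
        xs = float(np.sum(np.asarray(x, dtype=float)))
        x2 = float(np.sum(np.square(x)))
        return np.array([self.charge_dlam(lc) * xs, 0.5 * (self.k_B - self.k_A) * x2])

    def gradient(self, x, lam) -> np.ndarray:
        lc, lo = self.lam_vector(lam)
        return self.spring_constant(lo) * np.asarray(x, dtype=float) + self.charge(lc)

    def initial_configuration(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(1)

    def simulate_block(self, x, lam, noise, step_over_gamma):
        # linear force k x + q: AR(1) filter with a constant input
        from scipy.signal import lfilter

        lc, lo = self.lam_vector(lam)
        c = 1.0 - step_over_gamma * self.spring_constant(lo)
        drive = noise - step_over_gamma * self.charge(lc)
        x = np.asarray(x, dtype=float)
        out, _ = lfilter([1.0], [1.0, -c], drive, axis=0, zi=(c * x)[None, :])
        return out

    def dhdlambda_block(self, xs, lam) -> np.ndarray:
        lc, _ = self.lam_vector(lam)
        xs = np.asarray(xs, dtype=float)
        out = np.empty((len(xs), 2))
        out[:, 0] = self.charge_dlam(lc) * np.sum(xs, axis=1)
        out[:, 1] = 0.5 * (self.k_B - self.k_A) * np.sum(np.square(xs), axis=1)
        return out

    def energy_grid_block(self, xs, lambda_grid) -> np.ndarray:
        lc = lambda_grid[:, 0]
        lo = lambda_grid[:, 1]
        xs = np.asarray(xs, dtype=float)
        xsum = np.sum(xs, axis=1)
        x2 = np.sum(np.square(xs), axis=1)
        k = (1.0 - lo) * self.k_A + lo * self.k_B
        dq = self.q_B - self.q_A
        a = self.channel_amplitude
        q = self.q_A + dq * lc + a * lc * (1.0 - lc) * (1.0 - 2.0 * lc)
        return 0.5 * k[:, None] * x2[None, :] + q[:, None] * xsum[None, :]

    def energy_grid(self, x, lambda_grid) -> np.ndarray:
        lc = lambda_grid[:, 0]
        lo = lambda_grid[:, 1]
        xs = float(np.sum(np.asarray(x, dtype=float)))
        x2 = float(np.sum(np.square(x)))
        k = (1.0 - lo) * self.k_A + lo * self.k_B
        dq = self.q_B - self.q_A
        a = self.channel_amplitude
        q = self.q_A + dq * lc + a * lc * (1.0 - lc) * (1.0 - 2.0 * lc)
        return 0.5 * k * x2 + q * xs

    def dhdlambda_grid(self, x, lambda_grid) -> np.ndarray:
        lc = lambda_grid[:, 0]
        xs = float(np.sum(np.asarray(x, dtype=float)))
        x2 = float(np.sum(np.square(x)))
        dq = self.q_B - self.q_A
        a = self.channel_amplitude
        qd = dq + a * (1.0 - 6.0 * lc + 6.0 * lc**2)
        out = np.empty((len(lambda_grid), 2))
        out[:, 0] = qd * xs
        out[:, 1] = 0.5 * (self.k_B - self.k_A) * x2
        return out

    def free_energy(self, lam, thermo: ThermoParams) -> float:
        """Exact G(λ) up to a λ-independent constant (Gaussian integral)."""
        lc, lo = self.lam_vector(lam)
        beta = thermo.beta
        k = self.spring_constant(lo)
        q = self.charge(lc)
        return math.log(k) / (2.0 * beta) - q**2 / (2.0 * k)

    def analytic_friction_tensor(self, lam, gamma: float, thermo: ThermoParams) -> np.ndarray:
        """Closed-form 2×2 friction metric for overdamped dynamics.

        With x ~ N(μ, v), μ = −q/k, v = 1/(βk) and OU time constant
        τ = γ/k:  g_cc = q'² v τ;  g_oo = (Δk/2)²(4μ²vτ + v²τ);
        g_co = q'Δk μ v τ.
        """
        lc, lo = self.lam_vector(lam)
        beta = thermo.beta
        k = self.spring_constant(lo)
        qd = self.charge_dlam(lc)
        q = self.charge(lc)
        mu = -q / k
        v = 1.0 / (beta * k)
        tau = gamma / k
        dk = self.k_B - self.k_A
        g_cc = qd**2 * v * tau
        g_oo = (dk / 2.0) ** 2 * (4.0 * mu**2 * v * tau + v**2 * tau)
        g_co = qd * dk * mu * v * tau
        return np.array([[g_cc, g_co], [g_co, g_oo]])


_SYSTEM_KINDS = {
    "harmonic": HarmonicAlchemy,
    "micro_solvation": MicroSolvationSystem,
    "two_lambda": TwoLambdaToy,
}


def make_system(kind: str, **params) -> AlchemicalSystem:
    """Construct a registered toy system by name (used by the config layer)."""
    try:
        cls = _SYSTEM_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown system kind {kind!r}; known: {sorted(_SYSTEM_KINDS)}") from None
    if kind == "micro_solvation" and "solute" in params and isinstance(params["solute"], dict):
        params = dict(params)
        params["solute"] = SoftCorePair(**params["solute"])
    return cls(**params)
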