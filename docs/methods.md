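# Methods

## Scope and unit conventions

`alchemetric` implements the machinery needed to study — and optimize — the
efficiency of alchemical free energy calculations: soft-core λ-coupling,
fixed-λ and expanded-ensemble sampling with an adaptive bias,
time-correlation metrics on λ space, thermodynamic-length path functionals,
and the standard free-energy estimators (TI, BAR, MBAR).  Everything runs
on small, analytically tractable model systems so that every statistical
claim can be checked against a closed form or an enumeration oracle.

All quantities are in reduced units: k_B = 1, so β = 1/T, and the default
temperature is T = 1.  Lengths, energies and times are dimensionless; the
friction coefficient γ of the overdamped dynamics defaults to 1.  No unit
conversion layer is provided — published kJ/mol-scale results enter only
through the worked-example table arithmetic, which is unit-agnostic.

## Model systems

**Soft-core pair potential.**  The pair interaction interpolates two end
states as V_sc(r) = (1−λ)V^A(r_A) + λV^B(r_B), where each state's potential
(Lennard-Jones plus a Coulomb term q/r) is evaluated at a softened
distance r_state = (α σ⁶ c^p + r⁶)^{1/6}, with c = λ for state A and
c = 1−λ for state B.  The same softened distance is used for the Coulomb
term, which avoids artificial minima from mismatched distance functions.
Defaults α = 0.5 and p = 1 follow current practice.  The λ-derivative is
the full chain rule including ∂r_state/∂λ and is validated against central
finite differences at 1e−6 relative tolerance.

**Harmonic oscillator toy.**  H = ½k(λ)x² with k(λ) = (1−λ)k_A + λk_B.
Under overdamped dynamics every quantity of interest is closed-form:
ΔG = ln(k_B/k_A)/(2β), ⟨∂H/∂λ⟩ = (k_B−k_A)/(2βk), the friction metric
g(λ) = (k_B−k_A)²γ/(4β²k³) (from the Ornstein–Uhlenbeck x²
autocorrelation), and the Fisher–Rao metric (k_B−k_A)²/(2β²k²).  The
correlation time γ/k varies linearly-inversely with λ, which makes this
toy the reference system for everything from sampler calibration to
variance-reduction studies.

**Micro-solvation toy.**  One solute in a periodic 2D box of Lennard-Jones
solvent (minimum image, truncated and shifted at half the box length),
coupled to the solvent through soft-core pairs whose state A is the null
interaction: an ideal-gas particle at λ = 0, fully coupled at λ = 1.
Defaults: 8 solvent particles, box length 4σ (area density 0.5), ε = σ = 1.
This is the smallest system in which the physical mechanism behind the
metric contrast appears: at low λ the ghost solute decorrelates quickly
(large force fluctuations, short memory), while near λ = 1 caging by the
solvent stretches the force correlation time.  It is a desk-scale analogue
of solvation free-energy calculations, not a model of water: there are no
long-range electrostatics, no third dimension, and no thermostat beyond
the overdamped Langevin bath, so passing tests demonstrate the estimators'
statistical behavior, not force-field realism.

**Two-component λ toy.**  A single coordinate with H = ½k(λ_o)x² +
q(λ_c)·x, where λ_c plays the role of a Coulomb coupling (a charge in a
uniform field) and λ_o scales the confinement stiffness (the stand-in for
all other couplings).  The charge interpolation q(λ_c) = q_A + Δq λ_c +
2Δq λ_c(1−λ_c)(1−2λ_c) preserves the end states and has derivative
3Δq(1−2λ_c)², which vanishes exactly at λ_c = 0.5.  With the default
antisymmetric charges (q_A = −q_B) the mean position also vanishes there,
so the full 2×2 friction tensor — which is analytic for this Gaussian
system — has a line of vanishing determinant at λ_c = 0.5: a synthetic
analogue of the low-metric channels observed in ligand-mutation metric
landscapes.  A soft-core term was deliberately not used for the λ_o
component: keeping the system Gaussian is what makes the exact tensor
field available as an oracle for the 2D estimators and path tools.

## Sampling

Configurations evolve by the Euler–Maruyama discretization of overdamped
(position) Langevin dynamics, x' = x − (Δt/γ)∇H + √(2Δt/(βγ))ξ.  Momenta
add nothing at this scale, so no velocity integrator is provided.  The
discretization inflates the sampled variance of a harmonic mode by
1/(1 − Δt·k/2γ); default time steps (5·10⁻³ for the harmonic systems,
3·10⁻⁴ for the Lennard-Jones box) keep this bias at the few-per-mil level,
well below the statistical resolution of the tests.  For linear-force
systems the identical recursion is evaluated as an AR(1) filter
(`simulate_block`), which is a performance path, not a different
integrator: it reproduces the generic loop sample for sample.

In expanded-ensemble mode λ becomes dynamical: after every
`lambda_move_interval` configuration steps (default 10) the λ index is
redrawn from the full conditional P(λ|x) ∝ π_λ exp(f_λ − βH(x;λ)) — an
independence Gibbs move over the whole grid, which trivially satisfies
detailed balance at a frozen bias and directly yields the conditional
weight vectors w_λ(t) the diffusion metric needs.  Several walkers may
share one bias; they advance round-robin within a single process.

All stochastic operations are pure functions of their inputs and a seed;
per-λ and per-walker streams are spawned from a single `SeedSequence`.

## The adaptive bias

The bias state holds dimensionless free energies f_λ (gauge: f = 0 at the
first grid point), a target π_λ and an accumulation histogram.  Each
update applies f ← f − Δ·(h − m·π), where h is the weight histogram since
the previous update and m its total mass.  The exact update scheme of
production AWH implementations is not reproduced here; this
Wang–Landau-style surrogate is designed to satisfy the two properties
that matter for the studies:

* **Initial stage** — Δ is constant (β·`initial_error`/K initially) and
  robust to bad starting guesses.  Whenever every grid point has collected
  at least `covering_threshold` (default 0.2) of its target share within
  the current epoch, the grid is "covered" and Δ is halved.  The stage
  ends when enough real samples have accumulated that the constant update
  is no larger than the asymptotic one.
* **Final stage** — Δ = c·K/N with N the accumulated samples and c = 2
  (`final_gain`).  This is a stochastic-approximation gain ∝ 1/N, for
  which the error of f decays as 1/√N; the tests verify the log-log decay
  slope.  The gain constant c = 2 makes the transient from the initial
  stage decay quadratically faster than the statistical error, removing a
  residual bias that is clearly measurable at c = 1 while costing only a
  ~30% asymptotic variance factor.

**Dynamic target optimization.**  After the initial stage the target can
be re-optimized to π_λ ∝ max(√det g(λ), floor·max √det g) whenever the
bias updates (and never more often than `min_interval` updates; with the
default cadences consecutive updates are ≥250 MD steps apart).  The floor
(default 5% of the maximum) prevents starvation of end points whose
metric estimate is small or noisy.  The metric driving this is estimated
on the fly: samples are collected in blocks (default 200), each block
contributes a windowed correlation integral per grid point, and blocks
are combined with exponential forgetting (half-life 10 blocks) so that
pre-convergence data fades out.

ΔG is read off as (f_last − f_first)/β.  Its standard error is a block
average over the second half of the final-stage trace of f — a rough
estimate, adequate for weighting and sanity checks; the repeat studies
use across-seed spreads instead.

## Metrics

The friction metric is the integrated time-autocorrelation of the
generalized force F = −∂H/∂λ at fixed λ; the diffusion metric replaces
the fixed-λ average by conditional-weight-weighted correlations of
δF_λ(t)·w_λ(t), normalized by ⟨w_λ²⟩, with δF taken about the w-weighted
mean; the Fisher–Rao metric is the equal-time covariance of F.  Discrete
correlation integrals use dt·(C₀/2 + Σ_{k≤W} C_k) with an automatic
window: the smallest W with W ≥ 5·τ_int(W) (τ_int the integrated
autocorrelation time up to lag W), capped at a tenth of the series
length.  Cross-components are symmetrized; scalar estimates that come out
negative at finite sampling are clipped to zero and counted.  Grid points
an expanded-ensemble walk never visited are reported as missing and only
interpolated (log-linearly) on request.  Uncertainties are jackknife
standard errors over ten contiguous blocks.

## Path functionals and optimization

For a path λ(s) with metric g, the thermodynamic length is
𝓛 = ∫√(λ̇ᵀgλ̇)ds and the variance functional 𝕍 = ∫(λ̇ᵀgλ̇)/π_s ds, with
Var ΔG = 2𝕍/τ for total sampling time τ.  Both are discretized with the
same rule — segment length ℓ_i = √(Δλᵀ ḡ Δλ) with ḡ the mean of the
endpoint tensors, segment target mass p_i — so the Cauchy–Schwarz bound
𝕍 = Σℓ_i²/p_i ≥ (Σℓ_i)² = 𝓛² is exact in discrete form and saturates
identically at p_i ∝ ℓ_i (`target="optimal"`).  The per-point optimal
density π = √g/𝓛 agrees with the segment optimum up to discretization.
The predicted improvement factor IF = 𝓛²/𝕍_unif ∈ (0, 1] is the fraction
of compute time the optimal target needs relative to uniform sampling;
the empirical counterpart is the squared RMSE ratio of repeated runs,
which is how the worked-example table cells are reproduced.

Path constructions cover the standard choices: the diagonal
(simultaneous) path, sequential one-component-at-a-time paths with the
shared corner not duplicated (21 points in 2D = 11 + 11 − 1), and
straight three-leg channel paths (0,0)→(c,0)→(c,1)→(1,1) with points
allocated to legs by length.  `reparameterize_path` redistributes points
to equal metric length per segment by inverting the cumulative length.

2D path optimization runs Dijkstra on the 8-connected grid graph with
edge cost √(Δλᵀ ḡ Δλ); no monotonicity constraint is imposed, and an
optional band |λ₁−λ₂| ≤ d (default off; 0.5 when requested) restricts the
search to near-diagonal regions.  On ≤5×5 grids the result is checked
against exhaustive enumeration of all simple paths with branch-and-bound
pruning.  Smooth (curved) path refinement is out of scope; the optimum on
a grid is necessarily angular.

## Estimators

TI integrates per-λ mean gradients with the trapezoidal rule (O(Δλ²)
quadrature error, verified to scale as h²).  BAR solves the Bennett
self-consistency equation by bracketed Brent root finding (tolerance
1e−12 in βΔG) with the standard asymptotic Fermi-function variance;
near-zero overlap is flagged rather than silently reported.  The chain
estimator sums adjacent-pair legs with quadrature-combined errors — a
slight optimism, since neighboring legs share each intermediate state's
samples.  MBAR solves the self-consistent equations by damped iteration
followed by Newton steps on the gauge-reduced system (convergence at
max|Δf| < 1e−12) and reports the standard asymptotic covariance computed
from the SVD of the normalized weight matrix; this SE is calibrated
against repeat spreads in the tests.  No resampling for statistical
inefficiency is performed anywhere.

The evaluation harness scores repeated runs by RMSE against a pooled (or
supplied) reference, attaches one-sigma bootstrap intervals (5000
resamples, percentiles 15.87–84.13) and reports empirical improvement
factors as squared RMSE ratios.

## Benchmark studies and problem sizes

The built-in studies fix the package's reference experiment conditions:

* **Harmonic recovery** — k_A = 1, k_B = 4.  Fixed-λ runs: 21 points,
  Δt = 0.0025, 1.2·10⁵ steps each, 10% equilibration discard, feeding TI,
  BAR-chain and MBAR.  Expanded-ensemble runs: 9 points, Δt = 0.005,
  10⁵ steps, uniform and dynamic targets.  20 seeds by default; all five
  estimates agree with ln(4)/2 within three standard errors of the mean.
* **Variance reduction** — k_A = 1, k_B = 16 (correlation time varies
  16-fold), 11 points, 2.4·10⁵ steps per run, 48 paired seeds, one-sided
  Wilcoxon test on paired squared errors.  The dynamic target roughly
  halves the empirical variance; the run length is chosen so the
  asymptotic regime, where the variance functional applies, dominates.
* **Friction oracle** — five λ values, 10⁶ steps at Δt = 0.005, sampled
  every 5 steps; estimates match the closed form within a few percent,
  tested at 15%.
* **Micro-solvation contrast** — five λ values; 1.6·10⁵ fixed steps per λ
  and a 2.4·10⁵-step expanded-ensemble run at Δt = 3·10⁻⁴.  The friction
  profile's dynamic range exceeds the Fisher–Rao profile's by a factor
  ~5, and the diffusion profile tracks the friction profile from below.
* **Variance prediction** — the 2𝕍/τ prediction from the diffusion metric
  agrees with the empirical variance of 40 short repeats within a factor
  3; the functional is asymptotic and Markov-approximate, so
  order-of-magnitude agreement is the designed expectation.

These sizes are the package's own reference conditions; scaling any of
them up tightens the statistical checks but does not change what they
measure.

## Numerical choices and degenerate inputs

Conditional λ-weights are computed with a max-shift before
exponentiation; a fully underflowed weight vector is an error, not a
silent renormalization.  Soft-core energies at r = 0 are finite for
λ ∈ (0, 1) and raising a `SingularConfigurationError` at the end points
when the corresponding plain potential is nonzero.  Tensor fields are
clipped to det ≥ 0 before square roots; path-length quadratic forms
tolerate eigenvalue noise down to −1e−10 relative before erroring.  Ties
in the 2D shortest-path search resolve deterministically through the
graph library's ordering.  Custom targets that do not sum to one are
renormalized with a warning; non-positive targets are rejected.

## Known limitations

* The AWH surrogate reproduces the two-stage structure and 1/√N decay,
  not any production implementation's exact update or covering rule.
* The reported AWH standard error is a trace block average and can be
  optimistic early in the final stage; repeat studies rely on across-seed
  spreads.
* The diffusion metric presumes a reasonably converged bias; the
  forgetting factor limits, but does not eliminate, pre-convergence
  contamination.
* BAR-chain standard errors ignore the covariance between legs sharing a
  state's samples.
* The micro-solvation toy is 2D, short-ranged and small; it demonstrates
  statistical mechanisms, not solvation thermodynamics of real systems.
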