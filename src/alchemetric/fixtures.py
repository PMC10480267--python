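"""Seeded fixture generation: small, deterministic input files.

Everything a test or demo needs can be produced here without running the
heavier studies: harmonic-toy ∂H/∂λ series at 21 equally spaced λ points
(dhdl-style XVG files), a synthetic 2D channel metric-tensor field, a set
of fluctuation-theorem-consistent Gaussian work samples and a minimal XVG
example.  Identical seeds yield byte-identical files.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SeriesFile, write_xvg_series
from .metrics import MetricEstimate
from .sampling import SamplerSettings, run_fixed_lambda
from .systems import HarmonicAlchemy, ThermoParams, TwoLambdaToy

__all__ = ["generate_fixtures", "channel_field", "two_lambda_tensor_field", "crooks_gaussian_work"]


def channel_field(n1: int = 11, n2: int = 11, channel: float = 0.5,
                  low: float = 0.05, high: float = 1.0,
                  width: float = 0.08) -> MetricEstimate:
    """Synthetic 2D channel metric field (isotropic tensors).

    The scalar metric is ``high`` everywhere except in a Gaussian dip of
    depth ``low`` along the row λ_coulomb = ``channel`` — a hand-built
    stand-in for metric landscapes whose cheapest route rides a line of
    low metric at intermediate coupling rather than the diagonal.
    """
    l1 = np.linspace(0.0, 1.0, n1)
    l2 = np.linspace(0.0, 1.0, n2)
    lams, tensors = [], []
    for a in l1:
        g = high + (low - high) * math.exp(-((a - channel) / width) ** 2)
        for b in l2:
            lams.append((a, b))
            tensors.append(g * np.eye(2))
    est = MetricEstimate(
        lambdas=np.asarray(lams),
        values=np.asarray(tensors),
        stderr=np.full((n1 * n2, 2, 2), np.nan),
        kind="synthetic_channel",
    )
    est.grid_shape = (n1, n2)
    return est


def two_lambda_tensor_field(n1: int = 11, n2: int = 11, gamma: float = 1.0) -> MetricEstimate:
    """Analytic 2×2 friction-tensor field of the two-component toy.

    The field carries a line of vanishing √det g at λ_coulomb = 0.5 (the
    toy's low-metric channel) on top of an overall decrease with the
    confinement stiffness.
    """
    toy = TwoLambdaToy()
    thermo = ThermoParams()
    l1 = np.linspace(0.0, 1.0, n1)
    l2 = np.linspace(0.0, 1.0, n2)
    lams, tensors = [], []
    for a in l1:
        for b in l2:
            lams.append((a, b))
            tensors.append(toy.analytic_friction_tensor((a, b), gamma, thermo))
    est = MetricEstimate(
        lambdas=np.asarray(lams),
        values=np.asarray(tensors),
        stderr=np.full((n1 * n2, 2, 2), np.nan),
        kind="friction",
    )
    est.grid_shape = (n1, n2)
    return est


def crooks_gaussian_work(delta_g: float = 1.0, sigma: float = 1.0, n: int = 5000,
                         seed: int = 0):
    """Gaussian work samples satisfying the Crooks fluctuation theorem (β = 1).

    Forward W ~ N(ΔG + σ²/2, σ²), reverse W ~ N(−ΔG + σ²/2, σ²); BAR on
    these recovers ΔG without bias.
    """
    rng = np.random.default_rng(seed)
    forward = rng.normal(delta_g + sigma**2 / 2.0, sigma, n)
    reverse = rng.normal(-delta_g + sigma**2 / 2.0, sigma, n)
    return forward, reverse


def generate_fixtures(seed: int, outdir) -> list:
    """Write the full fixture set into ``outdir``; returns the file list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    # 1. harmonic-toy dhdl series at 21 equally spaced lambda points
    system = HarmonicAlchemy(k_A=1.0, k_B=4.0)
    thermo = ThermoParams()
    grid = np.linspace(0.0, 1.0, 21)
    settings = SamplerSettings(timestep=0.005, n_steps=6000, sample_interval=5,
                               seed=seed)
    series, _ = run_fixed_lambda(system, grid, settings, thermo,
                                 record_cross_energies=False)
    for j, fs in enumerate(series):
        path = outdir / f"dhdl_{j:02d}.xvg"
        sf = SeriesFile(
            comments=[f"# harmonic toy dH/dl at lambda = {fs.lam[0]:.6f}",
                      "@ xaxis label \"time\""],
            labels=["dH/dl"],
            times=np.arange(len(fs.samples)) * fs.dt,
            values=fs.samples,
        )
        write_xvg_series(sf, path, force=True)
        written.append(path)

    # 2. synthetic 2D channel metric field
    field = channel_field()
    frame = pd.DataFrame(
        {
            "lambda1": field.lambdas[:, 0],
            "lambda2": field.lambdas[:, 1],
            "g11": field.values[:, 0, 0],
            "g12": field.values[:, 0, 1],
            "g22": field.values[:, 1, 1],
            "sqrt_det": field.sqrt_det(),
        }
    )
    field_path = outdir / "channel_field.csv"
    frame.to_csv(field_path, index=False, float_format="%.17g")
    written.append(field_path)

    # 3. Crooks-consistent Gaussian work samples
    fwd, rev = crooks_gaussian_work(seed=seed)
    work_path = outdir / "crooks_work.csv"
    pd.DataFrame({"forward": fwd, "reverse": rev}).to_csv(
        work_path, index=False, float_format="%.17g"
    )
    written.append(work_path)

    # 4. minimal XVG example
    example = outdir / "example.xvg"
    example.write_text(
        "# minimal xvg example\n"
        '@ s0 legend "dH/dl"\n'
        "0.0 1.5\n"
        "0.1 1.25\n"
    )
    written.append(example)
    return written
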