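"""File formats and run configuration.

Time series travel in the GROMACS-style XVG dialect (lines starting with
``#`` or ``@`` are comments/metadata, whitespace-separated numeric rows,
legends recoverable from ``@ s0 legend "..."`` lines) or plain CSV; metric
profiles, paths and evaluation reports are written as CSV/JSON with
full-precision floats.  Run configurations are YAML documents validated
against a strict schema (unknown keys rejected).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .awh import FreeEnergyResult
from .estimators import EvalReport
from .metrics import MetricEstimate
from .paths import LambdaPath, PathDiagnostics
from .sampling import ForceSeries

__all__ = [
    "SeriesFile",
    "read_xvg_series",
    "write_xvg_series",
    "read_series",
    "force_series_from_file",
    "write_force_series",
    "write_profile_csv",
    "read_metric_csv",
    "write_path_csv",
    "read_path_csv",
    "write_trajectory",
    "read_trajectory",
    "result_to_json",
    "metric_to_json",
    "metric_from_json",
    "diagnostics_to_json",
    "RunConfig",
    "ConfigError",
    "load_config",
]


class ConfigError(ValueError):
    pass


@dataclass
class SeriesFile:
    """A parsed column time series: comments, labels, time + value columns."""

    comments: List[str]
    labels: List[str]
    times: np.ndarray
    values: np.ndarray          # (n, n_columns)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.times):
            raise ValueError("times and values must have matching lengths")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("time column must be strictly increasing")


def read_xvg_series(path) -> SeriesFile:
    """Parse an XVG-dialect file: ``#``/``@`` comment lines, numeric rows.

    Column labels are recovered from ``@ sN legend "..."`` metadata when
    present.  Ragged or non-numeric rows raise with the line number.
    """
    path = Path(path)
    comments: List[str] = []
    legends: dict = {}
    rows: List[List[float]] = []
    n_cols = None
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#") or line.startswith("@"):
                comments.append(line)
                if line.startswith("@") and "legend" in line and line[1:].strip().startswith("s"):
                    parts = line.split(None, 2)
                    if len(parts) == 3 and parts[1][0] == "s" and parts[1][1:].isdigit():
                        legends[int(parts[1][1:])] = parts[2].split("legend", 1)[-1].strip().strip('"')
                continue
            fields = line.split()
            try:
                row = [float(v) for v in fields]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value in data row") from None
            if n_cols is None:
                n_cols = len(row)
            elif len(row) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(row)} columns, expected {n_cols})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.asarray(rows)
    labels = [legends.get(i, f"s{i}") for i in range(data.shape[1] - 1)]
    return SeriesFile(comments=comments, labels=labels, times=data[:, 0], values=data[:, 1:])


def write_xvg_series(series: SeriesFile, path, force: bool = False) -> Path:
    """Write a SeriesFile in the XVG dialect with legend metadata."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    lines = [c if c.startswith(("#", "@")) else f"# {c}" for c in series.comments
             if not ("legend" in c and c.startswith("@ s"))]
    for i, label in enumerate(series.labels):
        lines.append(f'@ s{i} legend "{label}"')
    for t, row in zip(series.times, series.values):
        lines.append(" ".join([repr(float(t))] + [repr(float(v)) for v in row]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_series(path) -> SeriesFile:
    """Read a time series from XVG dialect or CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
        if frame.shape[1] < 2:
            raise ValueError(f"{path}: need a time column plus at least one value column")
        return SeriesFile(
            comments=[],
            labels=list(frame.columns[1:]),
            times=frame.iloc[:, 0].to_numpy(dtype=float),
            values=frame.iloc[:, 1:].to_numpy(dtype=float),
        )
    return read_xvg_series(path)


def force_series_from_file(path, lam, n_discard: int = 0) -> ForceSeries:
    """Load an externally produced per-λ ∂H/∂λ series (dhdl-style file)."""
    sf = read_series(path)
    dt = float(np.median(np.diff(sf.times)))
    return ForceSeries(
        lam=np.atleast_1d(lam),
        dt=dt,
        samples=sf.values[n_discard:],
        n_discarded=n_discard,
    )


def write_force_series(fs: ForceSeries, path, force: bool = False) -> Path:
    """Export a force series in the XVG dialect."""
    times = np.arange(len(fs.samples)) * fs.dt
    labels = [f"dH/dl component {mu}" for mu in range(fs.samples.shape[1])]
    sf = SeriesFile(
        comments=[f"# lambda = {fs.lam.tolist()}", f"# discarded = {fs.n_discarded}"],
        labels=labels,
        times=times,
        values=fs.samples,
    )
    return write_xvg_series(sf, path, force=force)


# ---------------------------------------------------------------------------
# Profiles, paths and reports
# ---------------------------------------------------------------------------

def _metric_frame(est: MetricEstimate) -> pd.DataFrame:
    d = est.lambdas.shape[1]
    cols = {f"lambda{i + 1}": est.lambdas[:, i] for i in range(d)}
    if est.is_tensor:
        cols["g11"] = est.values[:, 0, 0]
        cols["g12"] = est.values[:, 0, 1]
        cols["g22"] = est.values[:, 1, 1]
        cols["sqrt_det"] = est.sqrt_det()
        if est.stderr.ndim == 3:
            cols["stderr_g11"] = est.stderr[:, 0, 0]
            cols["stderr_g12"] = est.stderr[:, 0, 1]
            cols["stderr_g22"] = est.stderr[:, 1, 1]
    else:
        cols["value"] = est.values
        cols["stderr"] = est.stderr if est.stderr.ndim == 1 else np.full(len(est.values), np.nan)
    return pd.DataFrame(cols)


def write_profile_csv(obj, path, force: bool = False) -> Path:
    """Write a MetricEstimate, PathDiagnostics or EvalReport as CSV.

    Column order is deterministic and floats are written at full repr
    precision; existing files are not overwritten unless forced.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    if isinstance(obj, MetricEstimate):
        frame = _metric_frame(obj)
    elif isinstance(obj, PathDiagnostics):
        frame = pd.DataFrame(
            {
                "quantity": ["length", "v_uniform", "v_target", "improvement_factor"],
                "value": [obj.length, obj.v_uniform, obj.v_target, obj.improvement_factor],
            }
        )
    elif isinstance(obj, EvalReport):
        rows = []
        for name in obj.rmse:
            lo, hi = obj.rmse_ci[name]
            rows.append(
                {
                    "configuration": name,
                    "rmse": obj.rmse[name],
                    "rmse_ci_low": lo,
                    "rmse_ci_high": hi,
                    "improvement_factor": obj.improvement_factor.get(name, np.nan),
                    "n_repeats": obj.n_repeats[name],
                }
            )
        frame = pd.DataFrame(rows)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} as a profile CSV")
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_metric_csv(path) -> MetricEstimate:
    """Read a metric profile CSV back into a MetricEstimate."""
    frame = pd.read_csv(Path(path))
    lam_cols = [c for c in frame.columns if c.startswith("lambda")]
    lams = frame[lam_cols].to_numpy(dtype=float)
    if "g11" in frame.columns:
        k = len(frame)
        values = np.empty((k, 2, 2))
        values[:, 0, 0] = frame["g11"]
        values[:, 0, 1] = values[:, 1, 0] = frame["g12"]
        values[:, 1, 1] = frame["g22"]
        stderr = np.full_like(values, np.nan)
    else:
        values = frame["value"].to_numpy(dtype=float)
        stderr = frame["stderr"].to_numpy(dtype=float) if "stderr" in frame else np.full_like(values, np.nan)
    est = MetricEstimate(lambdas=lams, values=values, stderr=stderr, kind="loaded")
    if lams.shape[1] == 2:
        n1 = len(np.unique(lams[:, 0]))
        n2 = len(np.unique(lams[:, 1]))
        if n1 * n2 == len(lams):
            est.grid_shape = (n1, n2)
    return est


def write_path_csv(path_obj: LambdaPath, path, force: bool = False) -> Path:
    p = Path(path)
    if p.exists() and not force:
        raise FileExistsError(f"{p} exists; pass force=True to overwrite")
    cols = {"s": path_obj.s}
    for i in range(path_obj.n_dims):
        cols[f"lambda{i + 1}"] = path_obj.lambdas[:, i]
    pd.DataFrame(cols).to_csv(p, index=False, float_format="%.17g")
    return p


def read_path_csv(path) -> LambdaPath:
    frame = pd.read_csv(Path(path))
    lam_cols = [c for c in frame.columns if c.startswith("lambda")]
    return LambdaPath(lambdas=frame[lam_cols].to_numpy(dtype=float),
                      s=frame["s"].to_numpy(dtype=float))


def write_trajectory(traj, prefix, force: bool = False) -> List[Path]:
    """Write an expanded-ensemble trajectory as CSV + JSON metadata.

    One CSV per walker (time, lambda_index, energy, w_*, F_* columns) and a
    sidecar ``<prefix>_meta.json`` carrying the λ grid and sample spacing.
    """
    prefix = Path(prefix)
    written = []
    k = traj.lambda_grid.shape[0]
    d = traj.lambda_grid.shape[1]
    meta = {
        "lambda_grid": traj.lambda_grid.tolist(),
        "dt_between_samples": traj.dt_between_samples,
        "n_walkers": len(traj.walkers),
    }
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    if meta_path.exists() and not force:
        raise FileExistsError(f"{meta_path} exists; pass force=True to overwrite")
    meta_path.write_text(json.dumps(meta, indent=2))
    written.append(meta_path)
    for wi, wt in enumerate(traj.walkers):
        cols = {"time": wt.times, "lambda_index": wt.lambda_indices, "energy": wt.energies}
        for j in range(k):
            cols[f"w{j}"] = wt.weights[:, j]
        for j in range(k):
            for mu in range(d):
                cols[f"F{j}_{mu}"] = wt.forces[:, j, mu]
        path = prefix.with_name(f"{prefix.name}_walker{wi}.csv")
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    return written


def read_trajectory(prefix):
    """Read a trajectory written by :func:`write_trajectory`."""
    from .sampling import Trajectory, WalkerTrace

    prefix = Path(prefix)
    meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text())
    grid = np.asarray(meta["lambda_grid"], dtype=float)
    k, d = grid.shape
    walkers = []
    for wi in range(meta["n_walkers"]):
        frame = pd.read_csv(prefix.with_name(f"{prefix.name}_walker{wi}.csv"))
        s = len(frame)
        forces = np.empty((s, k, d))
        weights = np.empty((s, k))
        for j in range(k):
            weights[:, j] = frame[f"w{j}"]
            for mu in range(d):
                forces[:, j, mu] = frame[f"F{j}_{mu}"]
        walkers.append(
            WalkerTrace(
                times=frame["time"].to_numpy(dtype=float),
                lambda_indices=frame["lambda_index"].to_numpy(dtype=int),
                energies=frame["energy"].to_numpy(dtype=float),
                forces=forces,
                weights=weights,
            )
        )
    return Trajectory(walkers=walkers, lambda_grid=grid,
                      dt_between_samples=float(meta["dt_between_samples"]))


def result_to_json(result: FreeEnergyResult) -> str:
    d = dataclasses.asdict(result)
    if d.get("per_leg") is not None:
        d["per_leg"] = np.asarray(d["per_leg"]).tolist()
    return json.dumps(d, indent=2)


def metric_to_json(est: MetricEstimate) -> str:
    """Serialize a metric profile (grid, values, errors, bookkeeping) to JSON."""
    return json.dumps(
        {
            "lambdas": est.lambdas.tolist(),
            "values": est.values.tolist(),
            "stderr": np.nan_to_num(est.stderr, nan=-1.0).tolist(),
            "kind": est.kind,
            "missing": est.missing.tolist() if est.missing is not None else None,
            "n_clipped": est.n_clipped,
            "grid_shape": list(est.grid_shape) if est.grid_shape else None,
        },
        indent=2,
    )


def metric_from_json(text: str) -> MetricEstimate:
    d = json.loads(text)
    stderr = np.asarray(d["stderr"], dtype=float)
    stderr[stderr < 0] = np.nan
    est = MetricEstimate(
        lambdas=np.asarray(d["lambdas"], dtype=float),
        values=np.asarray(d["values"], dtype=float),
        stderr=stderr,
        kind=d["kind"],
        missing=np.asarray(d["missing"], dtype=bool) if d.get("missing") is not None else None,
        n_clipped=d.get("n_clipped", 0),
    )
    if d.get("grid_shape"):
        est.grid_shape = tuple(d["grid_shape"])
    return est


def diagnostics_to_json(diag: PathDiagnostics) -> str:
    """Serialize path diagnostics (length, variance functionals, IF) to JSON."""
    return json.dumps(
        {
            "length": diag.length,
            "v_uniform": diag.v_uniform,
            "v_target": diag.v_target,
            "improvement_factor": diag.improvement_factor,
            "optimal_pi": np.asarray(diag.optimal_pi).tolist(),
            "total_time": diag.total_time,
            "var_estimate": diag.var_estimate,
        },
        indent=2,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class SystemSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str
    params: dict = Field(default_factory=dict)


class GridSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_points: int = 9
    n_dims: int = 1
    path: str = "simultaneous"        # simultaneous | sequential | three_leg
    channel_value: float = 0.5


class SamplerSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    timestep: float = 0.005
    friction_gamma: float = 1.0
    n_steps: int = 20000
    sample_interval: int = 10
    equilibration_fraction: float = 0.1
    lambda_move_interval: int = 10
    n_walkers: int = 1
    move_kind: str = "langevin"


class BiasSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_mode: str = "uniform"      # uniform | static-optimized | dynamic-optimized
    initial_error: float = 1.0
    update_interval: int = 25
    covering_threshold: float = 0.2
    target_floor: float = 0.05


class EvaluationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_repeats: int = 20
    n_boot: int = 5000


class RunConfig(BaseModel):
    """Validated description of a run: system, grid, sampler, bias, estimator."""

    model_config = ConfigDict(extra="forbid")
    system: SystemSpec
    grid: GridSpec = GridSpec()
    sampler: SamplerSpec = SamplerSpec()
    bias: BiasSpec = BiasSpec()
    estimator: str = "awh"            # awh | ti | bar | mbar
    evaluation: EvaluationSpec = EvaluationSpec()
    temperature: float = 1.0
    seed: int = 0
    output_dir: Optional[str] = None


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"{path}: invalid YAML: {err}") from err
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        raise ConfigError(f"{path}: {err}") from err
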