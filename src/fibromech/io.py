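"""File formats, pipeline configuration and the end-to-end pipeline.

Formats are plain text with explicit headers and units in column names:

* trace TSV: ``time_s  cell_intensity  background_intensity`` (+ optional
  ``.truth.json`` sidecar with the generator's ground truth);
* per-cell metrics CSV: ``cell_id, force_nN, dff_max, t_peak_s, tau_s,
  censored, responder, response_class``;
* per-force counts CSV: ``force_nN, n_total, n_responding, n_generalized,
  n_transitory``;
* force-curve TSV: ``piezo_position_m  deflection_m`` with the spring
  constant in a ``# spring_constant_N_per_m:`` header line;
* activation fit as JSON.

Floats are written with 9 significant digits, so write-read round-trips
are identity at that precision and reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import (
    BoltzmannFit,
    PopulationResponse,
    bootstrap_activation,
    fit_activation,
    generalized_share,
)
from .errors import SchemaError
from .mechanics import ForceCurve, fit_force_curve
from .synthetic import PopulationSimConfig, simulate_population
from .transients import FluorescenceTrace, TransientMetrics, analyze_trace

logger = logging.getLogger("fibromech")

__all__ = [
    "PipelineConfig",
    "read_trace",
    "write_trace",
    "read_metrics",
    "write_metrics",
    "read_counts",
    "write_counts",
    "read_force_curve",
    "write_force_curve",
    "write_fit",
    "read_fit",
    "counts_from_metrics",
    "run_pipeline",
]

_FLOAT_FMT = "%.9g"

TRACE_COLUMNS = ["time_s", "cell_intensity", "background_intensity"]
METRICS_COLUMNS = [
    "cell_id", "force_nN", "dff_max", "t_peak_s", "tau_s",
    "censored", "responder", "response_class",
]
COUNTS_COLUMNS = ["force_nN", "n_total", "n_responding", "n_generalized", "n_transitory"]
CURVE_COLUMNS = ["piezo_position_m", "deflection_m"]


def _read_table(path, sep: str, required: list[str], numeric=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty input file")
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file") from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed table ({exc})") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    for col in (required if numeric is None else numeric):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad) and df[col].dtype == object:
            # +2: 1-based line numbers plus the header line
            raise SchemaError(
                f"{path}: non-numeric value in column '{col}' at line {bad[0] + 2}"
            )
    return df


def read_trace(
    path, modality: str = "AFM", stim_time: Optional[float] = None
) -> FluorescenceTrace:
    """Read a trace TSV; loads a ``.truth.json`` sidecar if present."""
    df = _read_table(path, "\t", TRACE_COLUMNS)
    truth_path = Path(str(path) + ".truth.json")
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    if stim_time is None and truth is not None:
        stim_time = truth.get("stim_onset")
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(float),
        cell_signal=df["cell_intensity"].to_numpy(float),
        background_signal=df["background_intensity"].to_numpy(float),
        modality=modality,
        stim_time=stim_time,
        truth=truth,
    )


def write_trace(trace: FluorescenceTrace, path) -> Path:
    """Write a trace TSV; emits a ``.truth.json`` sidecar when truth exists."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trace.time,
        "cell_intensity": trace.cell_signal,
        "background_intensity": trace.background_signal,
    })
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if trace.truth is not None:
        Path(str(path) + ".truth.json").write_text(
            json.dumps(trace.truth, indent=1, sort_keys=True)
        )
    return path


def write_metrics(rows: pd.DataFrame, path) -> Path:
    """Write the per-cell metrics CSV."""
    path = Path(path)
    rows[METRICS_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_metrics(path) -> pd.DataFrame:
    df = _read_table(path, ",", ["force_nN", "responder", "response_class"],
                     numeric=["force_nN"])
    df["responder"] = df["responder"].astype(bool)
    return df


def counts_from_metrics(metrics: pd.DataFrame) -> PopulationResponse:
    return PopulationResponse.from_metrics(metrics)


def write_counts(pop: PopulationResponse, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "force_nN": pop.forces,
        "n_total": pop.n_total,
        "n_responding": pop.n_responding,
        "n_generalized": pop.n_generalized,
        "n_transitory": pop.n_transitory,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_counts(path) -> PopulationResponse:
    df = _read_table(path, ",", COUNTS_COLUMNS)
    return PopulationResponse(
        df["force_nN"].to_numpy(float),
        df["n_total"].to_numpy(int),
        df["n_responding"].to_numpy(int),
        df["n_generalized"].to_numpy(int),
        df["n_transitory"].to_numpy(int),
    )


def write_force_curve(curve: ForceCurve, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# spring_constant_N_per_m: {curve.spring_constant:.9g}\n")
        fh.write("piezo_position_m\tdeflection_m\n")
        for z, d in zip(curve.piezo_position, curve.deflection):
            fh.write(f"{z:.9g}\t{d:.9g}\n")
    if curve.truth is not None:
        Path(str(path) + ".truth.json").write_text(
            json.dumps(curve.truth, indent=1, sort_keys=True)
        )
    return path


def read_force_curve(path, spring_constant: Optional[float] = None) -> ForceCurve:
    """Read a force-curve TSV; the spring constant comes from the header
    line unless given explicitly."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    if spring_constant is None:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "spring_constant_N_per_m" in line:
                    spring_constant = float(line.split(":", 1)[1])
                    break
                if not line.startswith("#"):
                    break
    if spring_constant is None:
        raise SchemaError(
            f"{path}: spring constant not found in header and not supplied"
        )
    df = _read_table(path, "\t", CURVE_COLUMNS)
    truth_path = Path(str(path) + ".truth.json")
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return ForceCurve(
        piezo_position=df["piezo_position_m"].to_numpy(float),
        deflection=df["deflection_m"].to_numpy(float),
        spring_constant=spring_constant,
        truth=truth,
    )


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, tuple):
        return list(value)
    return value


def write_fit(fit: BoltzmannFit, path, bootstrap: Optional[dict] = None) -> Path:
    path = Path(path)
    payload = {k: _jsonable(v) for k, v in dataclasses.asdict(fit).items()}
    if bootstrap is not None:
        payload["bootstrap"] = {
            "ci": list(bootstrap["ci"]),
            "ci_level": bootstrap["ci_level"],
            "n_boot": bootstrap["n_boot"],
        }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_fit(path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class PipelineConfig:
    """All tunables of the simulate -> analyze -> fit pipeline.

    Defaults reproduce the study's printed analysis constants: responder
    thresholds 0.01 (mechanical) / 0.1 (chemical), a 4-frame baseline, the
    10 s class boundary on the factor-3 decay time, a 200 nm Hertz fit
    depth, and F0 fixed at 300 nN for the activation fit.
    """

    seed: int = 0
    threshold_mechanical: float = 0.01
    threshold_chemical: float = 0.1
    n_baseline: int = 4
    tau_boundary: float = 10.0
    decay_factor: float = 3.0
    median_filter: bool = False
    f_half_fixed: Optional[float] = 300.0
    fit_method: str = "ls"
    bootstrap_n: int = 1000
    poisson_ratio: float = 0.5
    half_angle_deg: float = 17.5
    depth_limit_m: float = 200e-9
    cell_height_m: float = 2e-6
    probe_radius_m: float = 20e-9
    outdir: str = "fibromech_out"

    def __post_init__(self) -> None:
        if self.threshold_mechanical <= 0 or self.threshold_chemical <= 0:
            raise ValueError("thresholds must be positive")
        if self.depth_limit_m <= 0:
            raise ValueError("depth_limit_m must be positive")

    def threshold_for(self, modality: str) -> float:
        return (
            self.threshold_chemical
            if modality == "chemical"
            else self.threshold_mechanical
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path


def metrics_table(
    pairs, config: PipelineConfig
) -> pd.DataFrame:
    """Analyze a list of (StimulationRecord, FluorescenceTrace) pairs."""
    rows = []
    for record, trace in pairs:
        m: TransientMetrics = analyze_trace(
            trace,
            n_baseline=config.n_baseline,
            threshold=config.threshold_for(trace.modality),
            decay_factor=config.decay_factor,
            tau_boundary=config.tau_boundary,
            median_filter=config.median_filter,
        )
        rows.append({
            "cell_id": record.cell_id,
            "force_nN": record.force_nN,
            "dff_max": m.dff_max,
            "t_peak_s": m.t_peak,
            "tau_s": m.tau_s,
            "censored": m.censored,
            "responder": m.responder,
            "response_class": m.response_class,
        })
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def run_pipeline(
    config: PipelineConfig,
    population: Optional[PopulationSimConfig] = None,
    metrics: Optional[pd.DataFrame] = None,
    outdir=None,
) -> dict:
    """Run simulate -> analyze -> aggregate -> fit and write all artifacts.

    Either supply a per-cell ``metrics`` table (from real recordings) or a
    ``population`` simulation config; with neither, the study-design
    default population (5 forces x 105 cells) is simulated with the
    pipeline seed.  Writes the per-cell metrics CSV, per-force counts CSV,
    activation-fit JSON and a run manifest, and returns their paths plus
    the in-memory results.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if metrics is None:
        if population is None:
            population = PopulationSimConfig(seed=config.seed)
        logger.info("simulating population: %d forces x %d cells",
                    len(population.forces), population.n_per_force)
        pairs = simulate_population(population)
        metrics = metrics_table(pairs, config)
    paths = {"metrics": write_metrics(metrics, outdir / "metrics.csv")}
    pop = counts_from_metrics(metrics)
    paths["counts"] = write_counts(pop, outdir / "counts.csv")
    fit = fit_activation(pop, f_half=config.f_half_fixed, method=config.fit_method)
    boot = None
    if config.bootstrap_n > 0:
        boot = bootstrap_activation(
            pop, n_boot=config.bootstrap_n, seed=config.seed,
            f_half=config.f_half_fixed, method=config.fit_method,
        )
    paths["fit"] = write_fit(fit, outdir / "activation_fit.json", bootstrap=boot)
    shares = {
        float(f): _jsonable(generalized_share(int(g), int(t)))
        for f, g, t in zip(pop.forces, pop.n_generalized, pop.n_transitory)
    }
    manifest = {
        "package": "fibromech",
        "version": __version__,
        "seed": config.seed,
        "config": {k: _jsonable(v) for k, v in dataclasses.asdict(config).items()},
        "population": (
            {
                k: _jsonable(v)
                for k, v in dataclasses.asdict(population).items()
            }
            if population is not None
            else None
        ),
        "generalized_share_by_force": shares,
        "artifacts": {k: str(v.name) for k, v in paths.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return {"paths": paths, "metrics": metrics, "counts": pop, "fit": fit,
            "bootstrap": boot}


def fit_elasticity_files(
    paths, config: PipelineConfig, out_path=None
) -> pd.DataFrame:
    """Fit Young's modulus for each force-curve file; optionally write CSV."""
    rows = []
    for p in paths:
        curve = read_force_curve(p)
        fit = fit_force_curve(
            curve,
            poisson_ratio=config.poisson_ratio,
            half_angle_deg=config.half_angle_deg,
            depth_limit=config.depth_limit_m,
            cell_height=config.cell_height_m,
            probe_radius=config.probe_radius_m,
        )
        rows.append({
            "file": str(p),
            "E_Pa": fit.young_modulus,
            "contact_point_m": fit.contact_point,
            "rms_residual_N": fit.rms_residual,
            "n_points_fit": fit.n_points_fit,
            "valid_depth_vs_height": fit.valid_thin_sample[0],
            "valid_height_vs_tip": fit.valid_thin_sample[1],
        })
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False, float_format=_FLOAT_FMT)
    return df
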