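"""File formats and run configuration.

Trace CSV dialect (one row per traced point)::

    filament_id, strain, strain_rate_pct_per_s, kinesin_nM,
    point_index, x_um, y_um

Strains are serialised as fractions; percent columns carry a ``_pct``
suffix.  Condition summaries, ground truth and model comparisons are
plain CSV; fit reports and simulation summaries are JSON.  The run
configuration is YAML with schema validation at load time — partial
configs are rejected for mechanical constants rather than silently
defaulted — and every run serialises its fully resolved config into the
output directory for provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import units
from .mechanics import MT_SECOND_MOMENT
from .traces import (DEFAULT_SUBSTRATE_LENGTH_MM, CrestParams,
                     ExperimentDataset, FilamentTrace)

__all__ = [
    "TRACE_COLUMNS",
    "TraceFormatError",
    "ConfigError",
    "read_traces",
    "write_traces",
    "write_summaries",
    "write_ground_truth",
    "write_fit_report",
    "write_simulation",
    "RunConfig",
    "load_config",
]

TRACE_COLUMNS = ["filament_id", "strain", "strain_rate_pct_per_s",
                 "kinesin_nM", "point_index", "x_um", "y_um"]


class TraceFormatError(ValueError):
    """A trace file violates the CSV dialect."""


class ConfigError(ValueError):
    """A run configuration is missing or invalid."""


def read_traces(path: str | Path) -> ExperimentDataset:
    """Read an experiment from the trace CSV dialect.

    Raises :class:`TraceFormatError` naming the offending column or row
    for missing columns or non-monotonic point indices.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(
            f"{path}: missing column(s) {', '.join(missing)}")
    traces = []
    for (fid, strain), grp in df.groupby(["filament_id", "strain"],
                                         sort=True):
        grp = grp.sort_index()
        idx = grp["point_index"].to_numpy()
        if np.any(np.diff(idx) <= 0):
            row = int(grp.index[np.argmax(np.diff(idx) <= 0) + 1])
            raise TraceFormatError(
                f"{path}: non-monotonic point_index for filament "
                f"{fid!r} at strain {strain} (row {row})")
        traces.append(FilamentTrace(
            points=grp[["x_um", "y_um"]].to_numpy(dtype=float),
            strain=float(strain),
            strain_rate=float(grp["strain_rate_pct_per_s"].iloc[0]) / 100.0,
            kinesin_nM=float(grp["kinesin_nM"].iloc[0]),
            filament_id=str(fid)))
    return ExperimentDataset(traces=traces)


def write_traces(dataset: ExperimentDataset, path: str | Path) -> None:
    """Write an experiment in the trace CSV dialect (lossless round trip)."""
    frames = []
    for t in dataset.traces:
        n = len(t.points)
        frames.append(pd.DataFrame({
            "filament_id": [t.filament_id] * n,
            "strain": [t.strain] * n,
            "strain_rate_pct_per_s": [t.strain_rate * 100.0] * n,
            "kinesin_nM": [t.kinesin_nM] * n,
            "point_index": np.arange(n),
            "x_um": t.points[:, 0],
            "y_um": t.points[:, 1],
        }))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.9g")


def write_summaries(summaries: pd.DataFrame, path: str | Path) -> None:
    summaries.to_csv(path, index=False)


def write_ground_truth(dataset: ExperimentDataset, path: str | Path) -> None:
    if dataset.ground_truth is None:
        raise ValueError("dataset carries no ground truth")
    dataset.ground_truth.to_csv(path, index=False)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_fit_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=2) + "\n")


def write_simulation(result, json_path: str | Path,
                     traces_path: str | Path | None = None) -> None:
    """Serialise a :class:`~mtbuckle.simulator.SimulationResult`.

    The JSON summary holds per-step metrics; optionally the shapes are
    written in the trace CSV dialect so simulator output feeds the
    measurement pipeline directly.
    """
    summary = {
        "n_nodes": result.model.n_nodes,
        "node_spacing_um": result.model.node_spacing / units.UM,
        "boundary": result.model.boundary,
        "k_spring_N_per_m": result.model.k_spring,
        "anchor_spacing_nm": result.model.anchor_spacing / units.NM,
        "analytic_wavelength_um":
            result.model.analytic_wavelength() / units.UM,
        "strain_history": result.strain_history,
        "axial_force_pN": result.axial_force / units.PN,
        "max_amplitude_um": result.max_amplitude_m / units.UM,
        "dominant_wavelength_um": [
            None if lam is None else lam / units.UM
            for lam in result.dominant_wavelength_m],
        "onset_strain": result.onset_strain,
    }
    write_fit_report(summary, json_path)
    if traces_path is not None:
        traces = [result.to_trace(step=i, filament_id="sim")
                  for i in range(len(result.shapes))]
        write_traces(ExperimentDataset(traces=traces), traces_path)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of an analysis run."""

    # mechanical constants (required in the file)
    youngs_modulus_mpa: dict[float, float]  # per kinesin_nM
    second_moment_m4: float
    substrate_initial_length_mm: float
    # softening / fitting options
    softening_family: str = "hill"
    softening_exponent: float = 2.0
    critical_force_prefactor: float = 2.0
    wavelength_selection: str = "critical"  # or "transitional"
    # crest detection
    noise_sigma_um: float = 0.05
    smooth_window_um: float = 1.0
    amplitude_floor_um: float = 0.15
    prominence_factor: float = 3.0
    orientation_tol_deg: float = 15.0
    seed: int = 0

    def crest_params(self) -> CrestParams:
        return CrestParams(smooth_window_um=self.smooth_window_um,
                           amplitude_floor_um=self.amplitude_floor_um,
                           prominence_factor=self.prominence_factor)

    def to_yaml(self, path: str | Path) -> None:
        """Serialise the fully resolved config (provenance record)."""
        Path(path).write_text(yaml.safe_dump(_jsonify(asdict(self)),
                                             sort_keys=False))


_REQUIRED = ("youngs_modulus_mpa", "second_moment_m4",
             "substrate_initial_length_mm")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Mechanical constants must be present and positive; unknown keys are
    rejected so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(
            f"{path}: mechanical constants are required, missing "
            f"{missing} (partial configs are not defaulted)")
    e_map = raw["youngs_modulus_mpa"]
    if not isinstance(e_map, dict) or not e_map:
        raise ConfigError(f"{path}: youngs_modulus_mpa must map "
                          "kinesin_nM -> MPa")
    e_map = {float(k): float(v) for k, v in e_map.items()}
    if any(v <= 0 for v in e_map.values()):
        raise ConfigError(f"{path}: Young's moduli must be positive")
    for key in ("second_moment_m4", "substrate_initial_length_mm"):
        if float(raw[key]) <= 0:
            raise ConfigError(f"{path}: {key} must be positive")
    raw = dict(raw)
    raw["youngs_modulus_mpa"] = e_map
    return RunConfig(**raw)


def default_config() -> RunConfig:
    """The study's constants: printed moduli at the endpoint conditions."""
    return RunConfig(
        youngs_modulus_mpa={10.0: 49.75, 200.0: 7.15},
        second_moment_m4=MT_SECOND_MOMENT,
        substrate_initial_length_mm=DEFAULT_SUBSTRATE_LENGTH_MM,
    )
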