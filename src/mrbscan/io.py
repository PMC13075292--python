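"""Text formats: scan-trace CSV dialect, fixes, calibration tables, model docs.

A scan trace is stored as a two-column CSV (``t_s,signal``) preceded by
commented metadata lines (``# key: value``) carrying the scan kinematics
(scan speed, electrophoresis clock at scan start, detector start position,
sample rate) and units.  Fixes, ground truth and calibration tables are plain
CSV with units in the column headers; a fitted calibration model is saved as
a small YAML document.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .forward import ScanTrace
from .processing import BoundaryFix
from .quantify import CalibrationModel
from .synthetic import ExperimentConfig

_TRACE_META = {
    "scan_speed_mm_s": float,
    "scan_start_clock_min": float,
    "x_start_mm": float,
}


def write_trace(path: str | Path, trace: ScanTrace) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# mrbscan scan trace\n")
        fh.write(f"# scan_speed_mm_s: {float(trace.scan_speed_mm_s)!r}\n")
        fh.write(f"# scan_start_clock_min: {float(trace.scan_start_clock_min)!r}\n")
        fh.write(f"# x_start_mm: {float(trace.x_start_mm)!r}\n")
        fh.write(f"# sample_rate_hz: {float(1.0 / trace.dt_s)!r}\n")
        fh.write("# units: t_s in s since scan start, signal in detector units\n")
        fh.write("t_s,signal\n")
        for t, s in zip(trace.t_s, trace.signal):
            fh.write(f"{float(t)!r},{float(s)!r}\n")


def read_trace(path: str | Path) -> ScanTrace:
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip()
                if key in _TRACE_META:
                    meta[key] = float(value.strip())
        else:
            data_start = i
            break
    missing = sorted(set(_TRACE_META) - set(meta))
    if missing:
        raise ConfigurationError(
            f"trace file {path} is missing metadata fields: {', '.join(missing)}"
        )
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return ScanTrace(
        t_s=df["t_s"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        **meta,
    )


def write_fixes(path: str | Path, fixes: Sequence[BoundaryFix]) -> None:
    df = pd.DataFrame(
        {
            "clock_min": [f.clock_min for f in fixes],
            "t_boundary_s": [f.t_boundary_s for f in fixes],
            "x_boundary_mm": [f.x_boundary_mm for f in fixes],
            "method": [f.method for f in fixes],
            "quality": [f.quality for f in fixes],
            "valid": [f.valid for f in fixes],
        }
    )
    df.to_csv(path, index=False)


def read_calibration_points(path: str | Path) -> list[tuple[float, float]]:
    """Read a calibration table CSV with columns conc_mM, v_mrb (replicate optional)."""
    df = pd.read_csv(path)
    for col in ("conc_mM", "v_mrb"):
        if col not in df.columns:
            raise ConfigurationError(f"calibration table lacks required column {col!r}")
    return list(zip(df["conc_mM"].astype(float), df["v_mrb"].astype(float)))


def write_model(path: str | Path, model: CalibrationModel, notes: dict | None = None) -> None:
    doc: dict[str, Any] = {
        "model": "v_mrb = slope_a * log10(conc_mM) + intercept_b",
        "slope_a_mm_min_per_decade": model.slope_a,
        "intercept_b_mm_min": model.intercept_b,
        "r2": model.r2,
        "conc_range_mM": list(model.conc_range_mM),
        "lod_mM": model.lod_mM,
        "conventions": {
            "log_base": 10,
            "lod": "inverse prediction of blank mean + k*SD(blank), k default 3",
        },
    }
    if notes:
        doc["notes"] = notes
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_model(path: str | Path) -> CalibrationModel:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return CalibrationModel(
            slope_a=float(doc["slope_a_mm_min_per_decade"]),
            intercept_b=float(doc["intercept_b_mm_min"]),
            r2=float(doc["r2"]),
            conc_range_mM=tuple(float(v) for v in doc["conc_range_mM"]),
            lod_mM=None if doc.get("lod_mM") is None else float(doc["lod_mM"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"model document lacks field {exc}") from exc


_CONFIG_FIELDS = {f: t for f, t in [
    ("concentrations_mM", list),
    ("slope_a", float),
    ("intercept_b", float),
    ("x0_mm", float),
    ("first_scan_clock_min", float),
    ("scan_interval_min", float),
    ("n_scans", int),
    ("scan_speed_mm_s", float),
    ("sample_rate_hz", float),
    ("sigma1", float),
    ("sigma2", float),
    ("D", float),
    ("depletion_amp", float),
    ("depletion_width_mm", float),
    ("depletion_offset_mm", float),
    ("accumulation_amp", float),
    ("noise_sd", float),
    ("drift_coeffs", list),
    ("spike_prob", float),
    ("spike_amp", float),
    ("seed", int),
    ("grid_dx_mm", float),
]}


def load_experiment_config(path: str | Path, seed: int | None = None) -> ExperimentConfig:
    """Load and validate an experiment config YAML, naming any offending field."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must hold a mapping")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in _CONFIG_FIELDS:
            raise ConfigurationError(f"unknown config field {key!r}")
        typ = _CONFIG_FIELDS[key]
        try:
            if typ is list:
                kwargs[key] = tuple(float(v) for v in value)
            elif typ is int:
                if isinstance(value, float) and not value.is_integer():
                    raise ValueError
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        except (TypeError, ValueError):
            raise ConfigurationError(
                f"config field {key!r} has invalid value {value!r}"
            ) from None
    if seed is not None:
        kwargs["seed"] = seed
    try:
        return ExperimentConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
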