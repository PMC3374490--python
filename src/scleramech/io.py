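"""File formats, run configuration and the batch pipeline entry point.

All tables are CSV (data volumes are small); configuration and QC
reports are YAML/JSON.  Coordinates are mm internally; edge-trace files
may declare um columns, converted at ingest.  Every output table
carries provenance columns (dataset id, config hash), and a run is
byte-reproducible given the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .edge_geometry import EdgeTrace
from .pipeline import (
    AnalysisConfig,
    PressureSchedule,
    ScleralInflationModel,
    aggregate_groups,
)

__all__ = [
    "SchemaError",
    "read_edge_traces",
    "write_edge_traces",
    "traces_from_dataframe",
    "traces_to_dataframe",
    "RunConfig",
    "run_pipeline",
]

FLOAT_FORMAT = "%.17g"  # exact double round-trip


class SchemaError(ValueError):
    """Input file or configuration violates the documented schema."""


# ---------------------------------------------------------------------------
# Edge-trace CSV dialect
# ---------------------------------------------------------------------------

_TRACE_BASE_COLUMNS = ("eye_id", "pressure_mmHg", "point_index")


def traces_to_dataframe(traces, units: str = "mm") -> pd.DataFrame:
    """Serialize traces to the documented CSV dialect.

    Columns: eye_id, side, pressure_mmHg, point_index, x_<unit>, y_<unit>.
    """
    if units not in ("mm", "um"):
        raise SchemaError(f"unsupported units {units!r} (use 'mm' or 'um')")
    factor = 1.0 if units == "mm" else 1e3
    rows = []
    for tr in traces:
        for i, (x, y) in enumerate(tr.points):
            rows.append(
                {
                    "eye_id": tr.eye_id,
                    "side": tr.side,
                    "pressure_mmHg": tr.pressure,
                    "point_index": i,
                    f"x_{units}": x * factor,
                    f"y_{units}": y * factor,
                }
            )
    return pd.DataFrame(rows)


def traces_from_dataframe(df: pd.DataFrame) -> list[EdgeTrace]:
    """Parse the edge-trace dialect; validates columns, units and
    duplicate (eye, pressure, point_index) keys.  Point order within a
    trace follows ``point_index`` regardless of row order."""
    missing = [c for c in _TRACE_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"edge-trace table missing columns: {missing}")
    has_mm = {"x_mm", "y_mm"} <= set(df.columns)
    has_um = {"x_um", "y_um"} <= set(df.columns)
    if has_mm and has_um:
        raise SchemaError("edge-trace table mixes mm and um coordinate columns")
    if not (has_mm or has_um):
        raise SchemaError(
            "edge-trace table missing coordinate columns: ['x_mm', 'y_mm'] "
            "(or ['x_um', 'y_um'])"
        )
    xcol, ycol = ("x_mm", "y_mm") if has_mm else ("x_um", "y_um")
    factor = 1.0 if has_mm else 1e-3
    if df.duplicated(subset=["eye_id", "pressure_mmHg", "point_index"]).any():
        raise SchemaError("duplicate (eye_id, pressure_mmHg, point_index) rows")
    traces = []
    for (eye_id, pressure), grp in df.groupby(["eye_id", "pressure_mmHg"], sort=True):
        grp = grp.sort_values("point_index")
        idx = grp["point_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            raise SchemaError(
                f"eye {eye_id} at {pressure:g} mmHg: point_index must be 0..n-1"
            )
        side = str(grp["side"].iloc[0]) if "side" in grp.columns else "right"
        pts = grp[[xcol, ycol]].to_numpy(dtype=float) * factor
        traces.append(
            EdgeTrace(eye_id=str(eye_id), pressure=float(pressure), points=pts, side=side)
        )
    return traces


def write_edge_traces(traces, path, units: str = "mm") -> None:
    df = traces_to_dataframe(traces, units=units)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_edge_traces(path) -> list[EdgeTrace]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - passthrough context
        raise SchemaError(f"cannot read edge-trace CSV {path}: {exc}") from exc
    return traces_from_dataframe(df)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Complete, explicit configuration of a batch analysis run."""

    traces: str = "traces.csv"
    out_dir: str = "results"
    dataset_id: str = "dataset"
    seed: int = 0
    reference_pressure: float = 7.0
    steps: tuple = (10.0, 14.0, 18.0, 22.0, 26.0, 30.0)
    region_boundaries: tuple = (0.2, 0.4, 0.6, 0.8)
    n_eval_r23: int = 8
    n_eval_r4: int = 4
    poly_degree: int = 4
    noise_floor_um: float = 0.46
    qc_rms_factor: float = 3.0
    qc_gross_factor: float = 50.0
    qc_max_invalid_fraction: float = 0.5
    ratio_epsilon: float = 1e-4
    alpha: float = 0.05
    groups: dict | None = None  # eye_id -> group label (optional)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise SchemaError("run config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise SchemaError(f"unknown config keys: {unknown}")
        for key in ("steps", "region_boundaries"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"invalid run config: {exc}") from exc

    def schedule(self) -> PressureSchedule:
        return PressureSchedule(self.reference_pressure, self.steps)

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            region_boundaries=tuple(self.region_boundaries),
            n_eval_r23=self.n_eval_r23,
            n_eval_r4=self.n_eval_r4,
            poly_degree=self.poly_degree,
            noise_floor_um=self.noise_floor_um,
            qc_rms_factor=self.qc_rms_factor,
            qc_gross_factor=self.qc_gross_factor,
            qc_max_invalid_fraction=self.qc_max_invalid_fraction,
            ratio_epsilon=self.ratio_epsilon,
        )

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Batch pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Analyze every eye in the trace file and write the result bundle.

    Outputs (under ``config.out_dir``): region_curves.csv, samples.csv,
    qc.json, run_log.json and, when group labels are configured,
    group_comparison.csv.  Deterministic given config + seed; the run
    log records the seed, config hash and every exclusion with reason.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces = read_edge_traces(config.traces)
    schedule = config.schedule()
    analysis = config.analysis_config()
    chash = config.config_hash()

    by_eye: dict[str, list[EdgeTrace]] = {}
    for tr in traces:
        by_eye.setdefault(tr.eye_id, []).append(tr)

    curve_parts, sample_parts, qc_reports = [], [], []
    for eye_id in sorted(by_eye):
        model = ScleralInflationModel(by_eye[eye_id], schedule, analysis)
        res = model.fit()
        qc_reports.append(res.qc.to_dict())
        if res.qc.status == "analyzed" and not res.region_curves.empty:
            curve_parts.append(res.region_curves)
            sample_parts.append(res.samples)

    if not curve_parts:
        raise RuntimeError("all eyes excluded by QC")

    curves = pd.concat(curve_parts, ignore_index=True)
    samples = pd.concat(sample_parts, ignore_index=True)
    for df in (curves, samples):
        df.insert(0, "dataset_id", config.dataset_id)
        df.insert(1, "config_hash", chash)
    curves.to_csv(out / "region_curves.csv", index=False, float_format=FLOAT_FORMAT)
    samples.to_csv(out / "samples.csv", index=False, float_format=FLOAT_FORMAT)

    outputs = {
        "region_curves": out / "region_curves.csv",
        "samples": out / "samples.csv",
        "qc": out / "qc.json",
        "run_log": out / "run_log.json",
    }

    if config.groups:
        analyzed = set(curves["eye_id"])
        labels = {k: v for k, v in config.groups.items() if k in analyzed}
        comparison = aggregate_groups(
            curves, labels, alpha=config.alpha
        ).table
        comparison.insert(0, "dataset_id", config.dataset_id)
        comparison.insert(1, "config_hash", chash)
        comparison.to_csv(
            out / "group_comparison.csv", index=False, float_format=FLOAT_FORMAT
        )
        outputs["group_comparison"] = out / "group_comparison.csv"

    qc_blob = {"dataset_id": config.dataset_id, "config_hash": chash, "eyes": qc_reports}
    (out / "qc.json").write_text(json.dumps(qc_blob, indent=2, sort_keys=True) + "\n")

    exclusions = [r for r in qc_reports if r["status"] == "excluded"]
    log = {
        "dataset_id": config.dataset_id,
        "config_hash": chash,
        "seed": config.seed,
        "config": json.loads(config.canonical_json()),
        "n_eyes": len(by_eye),
        "n_analyzed": len(by_eye) - len(exclusions),
        "exclusions": exclusions,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return outputs
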