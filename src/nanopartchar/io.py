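"""Readers and writers for the delimited-text interchange formats.

Traces are CSV files with columns ``time_s,counts``; acquisition metadata
lives in a YAML sidecar; particle descriptor tables are CSV/TSV with
``fmin_nm,fmax_nm,ar`` columns or a JSON list of vertex outlines.  Reports
are JSON with units spelled out in the key names and enough provenance
(version, config hash, seed) to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .spicpms import ParticleResult, TimeTrace
from .tem_sizing import ParticleProjection

__all__ = [
    "read_trace",
    "read_trace_config",
    "write_trace",
    "read_particle_table",
    "write_report",
]

_TRACE_CONFIG_KEYS = {"dwell_time_ms", "flow_mL_min", "duration_s", "dilution_factor", "sample_id"}


def read_trace(path: str | Path, dwell_time_s: Optional[float] = None,
               sample_id: str = "", dilution_factor: float = 1.0) -> TimeTrace:
    """Read a ``time_s,counts`` CSV trace.

    The dwell time is inferred from the time column; when ``dwell_time_s``
    is supplied the inferred value must agree within 1 %.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "counts"}.issubset(df.columns):
        raise ValueError(f"{path}: expected header 'time_s,counts'")
    bad = df.index[df["counts"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative count at data row {bad[0] + 1}")
    if len(df) > 1:
        deltas = np.diff(df["time_s"].to_numpy())
        inferred = float(np.median(deltas))
        if inferred <= 0:
            raise ValueError(f"{path}: time column is not strictly increasing")
        if dwell_time_s is not None and abs(inferred - dwell_time_s) > 0.01 * dwell_time_s:
            raise ValueError(
                f"{path}: inferred dwell {inferred:.6g}s disagrees with configured "
                f"{dwell_time_s:.6g}s by more than 1%"
            )
    else:
        inferred = dwell_time_s if dwell_time_s is not None else 1.0
    return TimeTrace(
        readings=df["counts"].to_numpy(dtype=float),
        dwell_time=dwell_time_s if dwell_time_s is not None else inferred,
        sample_id=sample_id,
        dilution_factor=dilution_factor,
    )


def write_trace(trace: TimeTrace, path: str | Path) -> None:
    """Write a trace as a ``time_s,counts`` CSV (inverse of :func:`read_trace`)."""
    t = np.arange(trace.readings.size) * trace.dwell_time
    pd.DataFrame({"time_s": t, "counts": trace.readings}).to_csv(Path(path), index=False)


def read_trace_config(path: str | Path) -> dict[str, Any]:
    """Read the YAML acquisition sidecar; unknown keys are errors."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping")
    unknown = set(cfg) - _TRACE_CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    return cfg


def read_particle_table(path: str | Path, ar_rtol: float = 0.01) -> pd.DataFrame:
    """Read a particle descriptor table (CSV/TSV) or JSON outline list.

    Descriptor tables need columns ``fmin_nm,fmax_nm`` (``ar`` optional; when
    present it is checked against fmax/fmin within ``ar_rtol``).  A JSON file
    is a list of outlines (each an [[x, y], ...] vertex list in nm) from
    which descriptors are computed.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        outlines = json.loads(path.read_text())
        records = []
        for i, outline in enumerate(outlines):
            proj = ParticleProjection.from_outline(np.asarray(outline, dtype=float))
            records.append(
                {"particle_id": i, "fmin_nm": proj.fmin, "fmax_nm": proj.fmax, "ar": proj.ar}
            )
        return pd.DataFrame(records)

    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if not {"fmin_nm", "fmax_nm"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns fmin_nm,fmax_nm")
    bad = df.index[df["fmin_nm"] > df["fmax_nm"]]
    if len(bad):
        raise ValueError(f"{path}: fmin > fmax at data row {bad[0] + 1}")
    recomputed = df["fmax_nm"] / df["fmin_nm"]
    if "ar" in df.columns:
        off = np.abs(df["ar"] - recomputed) > ar_rtol * recomputed
        if off.any():
            row = int(df.index[off][0]) + 1
            raise ValueError(f"{path}: stored AR disagrees with fmax/fmin at data row {row}")
    else:
        df["ar"] = recomputed
    return df


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and (obj != obj):  # NaN
        return None
    return obj


def particle_result_to_dict(result: ParticleResult) -> dict[str, Any]:
    """Flatten a ParticleResult into unit-suffixed report fields."""
    return {
        "n_events": result.n_events,
        "median_esd_nm": result.median_esd_nm,
        "fraction_below_100nm": result.fraction_below_100nm,
        "number_concentration_per_L": result.number_concentration_per_L,
        "mass_concentration_g_per_L": result.mass_concentration_g_per_L,
        "number_concentration_per_kg_powder": result.number_concentration_per_kg_powder,
        "mass_concentration_kg_per_kg_powder": result.mass_concentration_kg_per_kg_powder,
        "size_lod_nm": result.size_lod_nm,
        "size_loq_nm": result.size_loq_nm,
        "low_size_peak_flag": result.low_size_peak_flag,
    }


def write_report(result: Any, path: str | Path, config: Optional[dict] = None,
                 seed: Optional[int] = None) -> dict[str, Any]:
    """Serialize a stage result (ParticleResult or mapping) to a JSON report.

    The report embeds the package version, a SHA-256 hash of the
    configuration, and the seed, so identical configurations produce
    identical reports.
    """
    if isinstance(result, ParticleResult):
        payload = particle_result_to_dict(result)
    elif isinstance(result, dict):
        payload = dict(result)
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")
    config_json = json.dumps(_jsonify(config or {}), sort_keys=True)
    doc = {
        "software_version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": seed,
        "results": _jsonify(payload),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc
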