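"""File formats: parameter sets, pulse profiles, feature tables, recordings.

Parameter sets are YAML/JSON with explicit unit tags so rates quoted in
1/s and 1/ms cannot be confused; array recordings use HDF5 with the
voltage as a (time, rows, cols) dataset and acquisition attributes.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .lfp import ArrayRecording
from .params import RateParams

__all__ = [
    "save_params",
    "load_params",
    "save_profile_csv",
    "load_feature_table",
    "save_feature_table",
    "save_recording",
    "load_recording",
]

_RATE_FIELDS = ("alpha", "delta")


def _params_doc(params: RateParams, unit: str) -> dict:
    doc = {}
    per_s = params.to_per_second()
    for name in _RATE_FIELDS:
        value = per_s[name] if unit == "1/s" else getattr(params, name)
        doc[name] = {"value": value, "unit": unit}
    doc["beta0"] = {"value": params.beta0, "unit": "dimensionless"}
    doc["sigma"] = {"value": params.sigma, "unit": "um"}
    if params.k is not None:
        doc["k"] = {"value": params.k, "unit": "dimensionless"}
    return doc


def save_params(params: RateParams, path: str | Path, *, unit: str = "1/s") -> None:
    """Write a parameter set as YAML (or JSON for .json paths)."""
    if unit not in ("1/s", "1/ms"):
        raise ValueError("unit must be '1/s' or '1/ms'")
    doc = _params_doc(params, unit)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path: str | Path) -> RateParams:
    """Read a parameter set, honoring the per-field unit tags."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    vals = {}
    for name, entry in doc.items():
        if isinstance(entry, dict):
            value, unit = entry["value"], entry.get("unit", "")
        else:
            value, unit = entry, ""
        if name in _RATE_FIELDS and unit == "1/s":
            value = value / 1000.0
        vals[name] = value
    return RateParams(**vals)


def save_profile_csv(z_um: np.ndarray, u: np.ndarray, path: str | Path) -> None:
    """Two-column CSV (z_um, u) export of a pulse profile."""
    pd.DataFrame({"z_um": z_um, "u": u}).to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    """Wave-feature CSV: wave_id, speed_um_per_ms, width_um, tau_ms."""
    df = pd.read_csv(path)
    required = {"speed_um_per_ms", "width_um", "tau_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table is missing columns: {sorted(missing)}")
    return df


def save_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def save_recording(rec: ArrayRecording, path: str | Path) -> None:
    """HDF5: dataset voltage[t, row, col] plus fs/pitch/mask and metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=rec.voltage, compression="gzip")
        f.create_dataset("mask", data=rec.mask)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["pitch"] = rec.pitch
        if rec.meta:
            f.attrs["meta_json"] = json.dumps(rec.meta)


def load_recording(path: str | Path) -> ArrayRecording:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta_json"]) if "meta_json" in f.attrs else {}
        return ArrayRecording(
            voltage=f["voltage"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            pitch=float(f.attrs["pitch"]),
            mask=f["mask"][...],
            meta=meta,
        )
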