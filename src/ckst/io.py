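"""Readers, writers and configuration validation shared by the CLI.

Tables are comma-separated text with a header row ('.' decimal, UTF-8);
configurations and coefficient sets are JSON.  Every CLI run writes a small
machine-readable manifest (input hashes, seed, package and library versions)
next to its outputs so results can be traced to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import CorrectionCoefficients, STSignals
from .spectra import SliceSet, Spectrum

__all__ = [
    "ConfigError",
    "validate_keys",
    "read_signals_table",
    "write_signals_table",
    "signals_to_row",
    "row_to_signals",
    "load_coefficients",
    "save_coefficients",
    "write_spectrum",
    "read_spectrum",
    "read_slice_manifest",
    "write_manifest",
    "load_json",
]

SIGNAL_COLUMNS = ("m0", "m0_control", "m_long", "m_short", "tr_control", "tr_long", "tr_short")


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def validate_keys(data: Mapping, allowed: Iterable[str], context: str, required: Iterable[str] = ()) -> None:
    """Reject unknown keys and report missing required ones with their path."""
    allowed = set(allowed)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}; allowed: {sorted(allowed)}")
    missing = set(required) - set(data)
    if missing:
        raise ConfigError(f"{context}: missing required keys {sorted(missing)}")


def load_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def signals_to_row(s: STSignals, **extra) -> Dict[str, float]:
    row = {
        "m0": s.m0,
        "m0_control": s.m0_control,
        "m_long": s.m_long,
        "m_short": s.m_short,
        "tr_control": s.tr_control,
        "tr_long": s.tr_long,
        "tr_short": s.tr_short,
    }
    row.update(extra)
    return row


def row_to_signals(row: Mapping) -> STSignals:
    def _opt(v):
        if v is None:
            return None
        v = float(v)
        return None if not np.isfinite(v) else v

    return STSignals(
        m0=_opt(row.get("m0")),
        m0_control=float(row["m0_control"]),
        m_long=float(row["m_long"]),
        m_short=_opt(row.get("m_short")),
        tr_control=float(row.get("tr_control", 16.0)),
        tr_long=float(row.get("tr_long", 10.0)),
        tr_short=float(row.get("tr_short", 1.7)),
    )


def read_signals_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"m0_control", "m_long"} - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: signal table lacks required columns {sorted(missing)}")
    return frame


def write_signals_table(rows, path) -> None:
    frame = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows
    frame.to_csv(path, index=False)


def load_coefficients(path: Optional[str]) -> CorrectionCoefficients:
    if path is None:
        return CorrectionCoefficients()
    return CorrectionCoefficients.from_dict(load_json(path))


def save_coefficients(coeffs: CorrectionCoefficients, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(coeffs.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ------------------------------------------------------------------ spectra files


def write_spectrum(spec: Spectrum, path) -> None:
    """Spectrum as CSV (frequency_hz, real, imag) plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {
            "frequency_hz": spec.frequency_hz,
            "real": spec.values.real,
            "imag": spec.values.imag,
        }
    ).to_csv(path, index=False)
    meta = {"label": spec.label, "slice_index": spec.slice_index}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta), encoding="utf-8")


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    frame = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
    return Spectrum(
        frequency_hz=frame["frequency_hz"].to_numpy(),
        values=frame["real"].to_numpy() + 1j * frame["imag"].to_numpy(),
        label=meta.get("label", ""),
        slice_index=meta.get("slice_index"),
    )


def read_slice_manifest(path) -> Dict[str, SliceSet]:
    """Load the four acquisitions of a quantification run.

    The manifest is JSON: ``{"acquisitions": {label: {"files": [...],
    "weights": [...]}}}`` with per-slice spectrum CSV paths relative to the
    manifest location; weights default to one per slice.
    """
    path = Path(path)
    data = load_json(path)
    validate_keys(data, {"acquisitions"}, str(path), required={"acquisitions"})
    out = {}
    for label, entry in data["acquisitions"].items():
        validate_keys(entry, {"files", "weights"}, f"{path}:{label}", required={"files"})
        spectra = tuple(read_spectrum(path.parent / f) for f in entry["files"])
        weights = tuple(entry.get("weights", [1.0] * len(spectra)))
        out[label] = SliceSet(spectra=spectra, weights=weights)
    return out


# ---------------------------------------------------------------------- manifest


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_manifest(out_dir, subcommand: str, params: Mapping, seed: Optional[int], inputs: Sequence = ()) -> Path:
    """Record what a run consumed: parameter values, seed, input hashes, versions."""
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes = {}
    for p in inputs:
        p = Path(p)
        hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "subcommand": subcommand,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "seed": seed,
        "input_sha256": hashes,
        "versions": {
            "ckst": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    target = out_dir / f"{subcommand}_manifest.json"
    target.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8")
    return target
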