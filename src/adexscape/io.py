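"""Reading and writing the trace CSV dialect, metadata, and JSON stores.

Traces travel as plain two-column CSV (time in ms, voltage in mV; comma
separator, period decimal, one optional header row).  Protocol metadata,
feature sets and ranked-model ensembles are JSON documents with an explicit
``schema_version``; dialect variants and schema mismatches are rejected
loudly rather than guessed at.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import FeatureSet, Trace
from .fitting import FitConfig, RankedModels
from .model import AdExParameters, StimulusProtocol

__all__ = [
    "SCHEMA_VERSION",
    "read_trace_csv",
    "write_trace_csv",
    "load_protocol_metadata",
    "write_protocol_metadata",
    "store_features",
    "load_features",
    "store_ranked_models",
    "load_ranked_models",
    "load_condition_manifest",
]

SCHEMA_VERSION = 1

_REQUIRED_METADATA = (
    "curr",
    "stim_delay",
    "stim_end",
    "duration",
    "holding_current",
    "holding_voltage",
    "V_th",
)


class SchemaError(ValueError):
    """A JSON store does not match the expected versioned schema."""


def read_trace_csv(path) -> Trace:
    """Parse a two-column (time ms, voltage mV) CSV into a Trace.

    A single non-numeric header row is tolerated; any other non-numeric row,
    fewer than two columns, or non-increasing times raise a parse error that
    names the offending row (1-based, including the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            header=None,
            comment="#",
            skip_blank_lines=True,
            float_precision="round_trip",
        )
    except Exception as exc:
        raise ValueError(f"{path}: not parseable as CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    if df.shape[1] > 2:
        df = df.iloc[:, :2]

    offset = 1  # 1-based row numbers for messages
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.iloc[0].isna().any():
        # first row is a header: re-read so floats are parsed exactly
        df = pd.read_csv(
            path,
            header=None,
            skiprows=1,
            comment="#",
            skip_blank_lines=True,
            float_precision="round_trip",
        ).iloc[:, :2]
        numeric = df.apply(pd.to_numeric, errors="coerce")
        offset = 2
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + offset
        raise ValueError(f"{path}: non-numeric value at row {row}")
    times = numeric.iloc[:, 0].to_numpy(dtype=float)
    voltages = numeric.iloc[:, 1].to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError(f"{path}: a trace needs at least 2 data rows")
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 1 + offset
        raise ValueError(f"{path}: non-monotonic time at row {row}")
    return Trace(times=times, voltages=voltages)


def write_trace_csv(trace: Trace, path, header: bool = True) -> None:
    """Write a trace at full precision; inverse of :func:`read_trace_csv`."""
    df = pd.DataFrame({"time_ms": trace.times, "voltage_mv": trace.voltages})
    df.to_csv(path, index=False, header=header, float_format="%.17g")


def load_protocol_metadata(path):
    """Load one trace's metadata JSON.

    Returns ``(protocol, detection_threshold, flags)`` where ``flags`` carries
    the optional entries (``volt_stimend`` inclusion flag, measured
    ``V_reset``, free-text annotations).  The stimulus duration is derived as
    ``stim_end - stim_delay`` by the protocol itself.
    """
    path = Path(path)
    with open(path) as fh:
        meta = json.load(fh)
    for fieldname in _REQUIRED_METADATA:
        if fieldname not in meta:
            raise ValueError(f"{path}: missing required metadata field {fieldname!r}")
    if not meta["stim_delay"] < meta["stim_end"]:
        raise ValueError(
            f"{path}: stim_end ({meta['stim_end']}) must exceed "
            f"stim_delay ({meta['stim_delay']})"
        )
    protocol = StimulusProtocol(
        step_amplitude=float(meta["curr"]),
        stim_delay=float(meta["stim_delay"]),
        stim_end=float(meta["stim_end"]),
        duration=float(meta["duration"]),
        initial_voltage=float(meta["holding_voltage"]),
        holding_current=float(meta["holding_current"]),
    )
    flags = {
        "volt_stimend": bool(meta.get("volt_stimend", False)),
        "V_reset": meta.get("V_reset"),
        "annotations": meta.get("annotations", {}),
    }
    return protocol, float(meta["V_th"]), flags


def write_protocol_metadata(
    protocol: StimulusProtocol,
    detection_threshold: float,
    path,
    volt_stimend: bool = False,
    V_reset: float | None = None,
    annotations: dict | None = None,
) -> None:
    meta = {
        "curr": protocol.step_amplitude,
        "stim_delay": protocol.stim_delay,
        "stim_end": protocol.stim_end,
        "duration": protocol.duration,
        "holding_current": protocol.holding_current,
        "holding_voltage": protocol.initial_voltage,
        "V_th": detection_threshold,
        "volt_stimend": volt_stimend,
    }
    if V_reset is not None:
        meta["V_reset"] = V_reset
    if annotations:
        meta["annotations"] = annotations
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def store_features(features: FeatureSet, path, condition: str = "") -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "condition": condition,
        "features": features.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_features(path):
    doc = _load_versioned(path)
    if "features" not in doc:
        raise SchemaError(f"{path}: feature store missing 'features'")
    return FeatureSet.from_dict(doc["features"]), doc.get("condition", "")


def store_ranked_models(models: RankedModels, path) -> None:
    """Persist an ensemble losslessly, including the fit configuration."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "condition": models.condition,
        "config": models.config.to_dict() if models.config else None,
        "models": [
            {"parameters": p.to_dict(), "error": e} for p, e in models.models
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_ranked_models(path) -> RankedModels:
    doc = _load_versioned(path)
    if "models" not in doc or "condition" not in doc:
        raise SchemaError(f"{path}: model store missing 'models'/'condition'")
    models = []
    for entry in doc["models"]:
        try:
            params = AdExParameters.from_dict(entry["parameters"])
            err = float(entry["error"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed model entry: {exc}") from exc
        models.append((params, err))
    config = None
    if doc.get("config"):
        cfg = dict(doc["config"])
        config = FitConfig(
            n_samples=cfg["n_samples"],
            n_keep=cfg["n_keep"],
            weights=cfg.get("weights", {}),
            penalty=cfg.get("penalty", 3.0),
            dt=cfg.get("dt", 0.01),
            scramble_seed=cfg.get("scramble_seed"),
        )
    return RankedModels(condition=doc["condition"], models=models, config=config)


def load_condition_manifest(path):
    """A condition manifest lists the (trace, metadata) file pairs of one
    experimental condition plus free-text annotations.

    Returns ``(label, [(trace_path, metadata_path), ...], annotations)``;
    paths are resolved relative to the manifest location and must exist.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if "condition" not in doc or "traces" not in doc:
        raise SchemaError(f"{path}: manifest requires 'condition' and 'traces'")
    pairs = []
    for entry in doc["traces"]:
        trace_path = (path.parent / entry["trace"]).resolve()
        meta_path = (path.parent / entry["metadata"]).resolve()
        for p in (trace_path, meta_path):
            if not p.exists():
                raise FileNotFoundError(f"{path}: referenced file not found: {p}")
        pairs.append((trace_path, meta_path))
    return doc["condition"], pairs, doc.get("annotations", {})


def _load_versioned(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise SchemaError(f"{path}: missing schema_version")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema_version {doc['schema_version']} is not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    return doc
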