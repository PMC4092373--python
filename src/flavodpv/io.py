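"""Delimited-text I/O for voltammograms, traces and titration series.

No community exchange format exists for DPV data, so files are plain CSV
with a ``#``-prefixed ``key: value`` header carrying the acquisition
metadata (reference scale, temperature, electrode area, pulse settings,
provenance).  Free-form metadata is stored under ``meta.<key>`` with
JSON-encoded values so arbitrary nested provenance survives a round trip.
A shim accepts headerless two-column instrument exports when the metadata is
supplied as a sidecar dict.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AdditionEvent, CurrentTrace, Voltammogram
from .exceptions import FormatError
from .model import PulseParams

__all__ = [
    "read_voltammogram",
    "write_voltammogram",
    "read_trace",
    "write_trace",
    "read_titration_series",
    "write_titration_series",
]

FORMAT_VERSION = "1"

_PULSE_KEYS = (
    "increment_mV",
    "amplitude_mV",
    "pulse_width_ms",
    "pulse_period_ms",
    "sampling_delay_ms",
    "scan_direction",
)
_MANDATORY = {
    "dpv": ["kind", "reference_scale", "temperature_K", "electrode_area_cm2"]
    + [f"pulse.{k}" for k in _PULSE_KEYS],
    "trace": ["kind", "potential_V", "pH", "strain", "flavin"],
    "titration": ["kind"],
}


def _write_file(path, header: dict, df: pd.DataFrame):
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# flavodpv_format: {FORMAT_VERSION}\n")
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _parse_header(path):
    header = {}
    n_skip = 0
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                header[key.strip()] = val.strip()
    return header, n_skip


def _require(header, kind):
    for key in _MANDATORY[kind]:
        if key not in header:
            raise FormatError(f"missing mandatory header key {key!r}")


def _meta_to_header(metadata: dict) -> dict:
    return {f"meta.{k}": json.dumps(v) for k, v in metadata.items()}


def _meta_from_header(header: dict) -> dict:
    meta = {}
    for key, val in header.items():
        if key.startswith("meta."):
            try:
                meta[key[5:]] = json.loads(val)
            except json.JSONDecodeError:
                meta[key[5:]] = val
    return meta


# -- voltammograms ---------------------------------------------------------

def write_voltammogram(v: Voltammogram, path):
    header = {
        "kind": "dpv",
        "reference_scale": v.reference_scale,
        "temperature_K": repr(v.temperature_K),
        "electrode_area_cm2": repr(v.electrode_area_cm2),
    }
    for key in _PULSE_KEYS:
        header[f"pulse.{key}"] = getattr(v.pulse, key)
    header.update(_meta_to_header(v.metadata))
    df = pd.DataFrame(
        {"potential_V": v.potentials_V, "current_uA_cm2": v.currents}
    )
    _write_file(path, header, df)


def read_voltammogram(path, metadata: dict | None = None) -> Voltammogram:
    """Read a voltammogram file.

    ``metadata`` supplies the header (same keys as the file format) for
    headerless two-column exports; file header keys take precedence when
    both are present.
    """
    header, n_skip = _parse_header(path)
    if metadata:
        header = {**{k: v for k, v in metadata.items()}, **header}
    header.setdefault("kind", "dpv")
    _require(header, "dpv")
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError("expected two data columns (potential, current)")
    cols = list(df.columns)
    pot_col = "potential_V" if "potential_V" in cols else cols[0]
    cur_col = "current_uA_cm2" if "current_uA_cm2" in cols else cols[1]
    pulse = PulseParams(
        increment_mV=float(header["pulse.increment_mV"]),
        amplitude_mV=float(header["pulse.amplitude_mV"]),
        pulse_width_ms=float(header["pulse.pulse_width_ms"]),
        pulse_period_ms=float(header["pulse.pulse_period_ms"]),
        sampling_delay_ms=float(header["pulse.sampling_delay_ms"]),
        scan_direction=str(header["pulse.scan_direction"]),
    )
    return Voltammogram(
        df[pot_col].to_numpy(dtype=float),
        df[cur_col].to_numpy(dtype=float),
        pulse=pulse,
        temperature_K=float(header["temperature_K"]),
        electrode_area_cm2=float(header["electrode_area_cm2"]),
        reference_scale=str(header["reference_scale"]),
        metadata=_meta_from_header(header),
    )


# -- chronoamperometry traces ----------------------------------------------

def write_trace(trace: CurrentTrace, path):
    header = {
        "kind": "trace",
        "potential_V": repr(trace.potential_V),
        "pH": repr(trace.pH),
        "strain": trace.strain,
        "flavin": trace.flavin,
        "flavin_conc_uM": repr(trace.flavin_conc_uM),
        "events": json.dumps([asdict(e) for e in trace.events]),
    }
    header.update(_meta_to_header(trace.metadata))
    df = pd.DataFrame({"time_s": trace.times_s, "current_uA_cm2": trace.currents})
    _write_file(path, header, df)


def read_trace(path, metadata: dict | None = None) -> CurrentTrace:
    header, n_skip = _parse_header(path)
    if metadata:
        header = {**metadata, **header}
    header.setdefault("kind", "trace")
    _require(header, "trace")
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    events_raw = header.get("events", "[]")
    events = [
        AdditionEvent(e["time_s"], e["kind"], e.get("payload", {}))
        for e in (json.loads(events_raw) if isinstance(events_raw, str) else events_raw)
    ]
    cols = list(df.columns)
    t_col = "time_s" if "time_s" in cols else cols[0]
    c_col = "current_uA_cm2" if "current_uA_cm2" in cols else cols[1]
    return CurrentTrace(
        df[t_col].to_numpy(dtype=float),
        df[c_col].to_numpy(dtype=float),
        events=events,
        potential_V=float(header["potential_V"]),
        pH=float(header["pH"]),
        strain=str(header["strain"]),
        flavin=str(header["flavin"]),
        flavin_conc_uM=float(header.get("flavin_conc_uM", 0.0)),
        metadata=_meta_from_header(header),
    )


# -- titration series ------------------------------------------------------

def write_titration_series(series: pd.DataFrame, path, metadata: dict | None = None):
    header = {"kind": "titration"}
    header.update(_meta_to_header(metadata or {}))
    _write_file(path, header, series)


def read_titration_series(path) -> pd.DataFrame:
    header, n_skip = _parse_header(path)
    header.setdefault("kind", "titration")
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    if not {"concentration_uM", "peak_current_uA_cm2"} <= set(df.columns):
        raise FormatError(
            "titration file needs concentration_uM and peak_current_uA_cm2 columns"
        )
    return df
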