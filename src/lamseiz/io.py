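"""Recording container and on-disk formats.

The native container is HDF5 (``/lfp``, ``/mua``, ``/events/<name>``, scalar
root attributes) because dual-rate multichannel recordings do not fit
row-oriented text formats.  EDF export (LFP band only) is provided for
interoperability with clinical viewers; it quantizes to 16-bit integers with
per-channel physical ranges and is therefore lossy.  All on-disk times are
seconds from recording start.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

EVENT_COLUMNS = ["time_s", "duration_ms", "peak_channel", "peak_amplitude", "label"]


class SchemaError(ValueError):
    """A container file is missing a required field."""


@dataclass
class LaminarRecording:
    """Multichannel laminar recording (LFP band, optional MUA band).

    ``lfp`` rows are ordered superficial -> deep (row 0 = contact 1, the most
    superficial).  ``signal_kind`` distinguishes monopolar potentials from
    successive-contact potential gradients (n_contacts - 1 rows).
    """

    lfp: np.ndarray
    fs_lfp_hz: float
    spacing_um: float
    mua: np.ndarray | None = None
    fs_mua_hz: float | None = None
    signal_kind: str = "monopolar"
    zone: str = "unknown"
    line_freq_hz: float = 60.0
    annotations: dict[str, tuple[float, float]] = field(default_factory=dict)
    channel_status: np.ndarray | None = None  # True = good

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=np.float64)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be a 2-D (channels x samples) array")
        if self.fs_lfp_hz <= 0:
            raise ValueError("fs_lfp_hz must be > 0")
        if self.mua is not None and (self.fs_mua_hz is None or self.fs_mua_hz <= 0):
            raise ValueError("fs_mua_hz must be > 0 when an MUA band is present")
        if self.signal_kind not in ("monopolar", "gradient"):
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")
        if self.channel_status is None:
            self.channel_status = np.ones(self.n_contacts, dtype=bool)
        for name, (t0, t1) in self.annotations.items():
            if not (0.0 <= t0 <= t1 <= self.duration_s + 1e-9):
                raise ValueError(f"annotation {name!r} outside recording")

    @property
    def n_contacts(self) -> int:
        n = self.lfp.shape[0]
        return n + 1 if self.signal_kind == "gradient" else n

    @property
    def n_samples(self) -> int:
        return self.lfp.shape[1]

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs_lfp_hz

    def copy_with(self, **kwargs) -> "LaminarRecording":
        return replace(self, **kwargs)

    def lfp_slice(self, t0: float, t1: float) -> np.ndarray:
        i0 = max(0, int(round(t0 * self.fs_lfp_hz)))
        i1 = min(self.n_samples, int(round(t1 * self.fs_lfp_hz)))
        return self.lfp[:, i0:i1]


def make_event_table(
    time_s, duration_ms=None, peak_channel=None, peak_amplitude=None, label="event"
) -> pd.DataFrame:
    """Build a sorted event table with the canonical column set."""
    time_s = np.atleast_1d(np.asarray(time_s, dtype=float))
    n = time_s.size
    if np.any(time_s < 0):
        raise ValueError("event times must be non-negative")

    def _col(x, default):
        if x is None:
            return np.full(n, default)
        return np.broadcast_to(np.asarray(x), (n,)).copy()

    df = pd.DataFrame(
        {
            "time_s": time_s,
            "duration_ms": _col(duration_ms, np.nan),
            "peak_channel": _col(peak_channel, -1),
            "peak_amplitude": _col(peak_amplitude, np.nan),
            "label": _col(label, "event"),
        }
    )
    return df.sort_values("time_s", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_REQUIRED_ATTRS = ("fs_lfp_hz", "spacing_um", "signal_kind", "zone", "line_freq_hz")


def write_recording(rec: LaminarRecording, path, events: dict[str, pd.DataFrame] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs_lfp_hz"] = float(rec.fs_lfp_hz)
        f.attrs["spacing_um"] = float(rec.spacing_um)
        f.attrs["signal_kind"] = str(rec.signal_kind)
        f.attrs["zone"] = str(rec.zone)
        f.attrs["line_freq_hz"] = float(rec.line_freq_hz)
        f.create_dataset("lfp", data=rec.lfp)
        if rec.mua is not None:
            f.attrs["fs_mua_hz"] = float(rec.fs_mua_hz)
            f.create_dataset("mua", data=rec.mua)
        f.create_dataset("channel_status", data=rec.channel_status.astype(np.uint8))
        ann = f.create_group("annotations")
        for name, (t0, t1) in rec.annotations.items():
            ann.attrs[name] = (float(t0), float(t1))
        if events:
            for name, table in events.items():
                _write_events_group(f, name, table)


def _write_events_group(f: h5py.File, name: str, table: pd.DataFrame) -> None:
    g = f.require_group("events").create_group(name)
    for col in EVENT_COLUMNS:
        data = table[col].to_numpy()
        if data.dtype.kind in "OU":
            data = data.astype("S64")
        g.create_dataset(col, data=data)


def read_recording(path) -> tuple[LaminarRecording, dict[str, pd.DataFrame]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for a in _REQUIRED_ATTRS:
            if a not in f.attrs:
                raise SchemaError(f"container missing required attribute {a!r}")
        if float(f.attrs["fs_lfp_hz"]) <= 0:
            raise ValueError("fs_lfp_hz must be > 0")
        annotations = {
            k: (float(v[0]), float(v[1])) for k, v in f["annotations"].attrs.items()
        } if "annotations" in f else {}
        rec = LaminarRecording(
            lfp=f["lfp"][()],
            fs_lfp_hz=float(f.attrs["fs_lfp_hz"]),
            spacing_um=float(f.attrs["spacing_um"]),
            mua=f["mua"][()] if "mua" in f else None,
            fs_mua_hz=float(f.attrs["fs_mua_hz"]) if "fs_mua_hz" in f.attrs else None,
            signal_kind=str(f.attrs["signal_kind"]),
            zone=str(f.attrs["zone"]),
            line_freq_hz=float(f.attrs["line_freq_hz"]),
            annotations=annotations,
            channel_status=f["channel_status"][()].astype(bool),
        )
        events: dict[str, pd.DataFrame] = {}
        if "events" in f:
            for name, g in f["events"].items():
                cols = {}
                for col in EVENT_COLUMNS:
                    data = g[col][()]
                    if data.dtype.kind == "S":
                        data = data.astype(str)
                    cols[col] = data
                events[name] = pd.DataFrame(cols)
    return rec, events


# ---------------------------------------------------------------------------
# Event tables as CSV
# ---------------------------------------------------------------------------

def write_event_csv(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6f")


def read_event_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event CSV missing columns {missing}")
    return df


def write_provenance(path, config: dict, seed: int, extra: dict | None = None) -> dict:
    """Write a JSON provenance record (config hash, seed, package version)."""
    import hashlib

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "lamseiz_version": __version__,
    }
    if extra:
        record.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(record, indent=2))
    return record


# ---------------------------------------------------------------------------
# EDF export (16-bit, lossy)
# ---------------------------------------------------------------------------

def export_edf(rec: LaminarRecording, path, record_duration_s: float = 0.1) -> int:
    """Export the LFP band to EDF. Returns the number of samples written
    per channel (the final data record is zero-padded to a whole record).
    """
    if rec.signal_kind != "monopolar":
        raise ValueError("EDF export expects monopolar LFP")
    fs = rec.fs_lfp_hz
    spr = int(round(fs * record_duration_s))
    if abs(spr - fs * record_duration_s) > 1e-9 or spr <= 0:
        raise ValueError("record_duration_s must give an integer samples-per-record")
    nch, n = rec.lfp.shape
    n_rec = int(np.ceil(n / spr))
    data = np.zeros((nch, n_rec * spr))
    data[:, :n] = rec.lfp

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    same = phys_max - phys_min < 1e-12
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def _pad(s: str, width: int) -> bytes:
        return s.encode("ascii")[:width].ljust(width)

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (nch + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad(f"{record_duration_s:g}", 8),
            _pad(str(nch), 4),
        ]
    )
    fields = [
        [_pad(f"ch{i + 1}", 16) for i in range(nch)],
        [_pad("AgAgCl electrode", 80)] * nch,
        [_pad("uV", 8)] * nch,
        [_pad(f"{phys_min[i]:.6g}"[:8], 8) for i in range(nch)],
        [_pad(f"{phys_max[i]:.6g}"[:8], 8) for i in range(nch)],
        [_pad(str(dig_min), 8)] * nch,
        [_pad(str(dig_max), 8)] * nch,
        [_pad("", 80)] * nch,
        [_pad(str(spr), 8)] * nch,
        [_pad("", 32)] * nch,
    ]
    with open(path, "wb") as f:
        f.write(header)
        for block in fields:
            f.write(b"".join(block))
        for r in range(n_rec):
            chunk = digital[:, r * spr : (r + 1) * spr]
            f.write(struct.pack(f"<{nch * spr}h", *chunk.ravel().tolist()))
    return n_rec * spr
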