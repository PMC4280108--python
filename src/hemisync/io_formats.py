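"""Reading and writing the formats the pipeline touches.

Two recording dialects are supported: ``raw_matrix`` (64-bit little-endian
float binary plus a YAML sidecar - lossless, used for exact fixtures) and
16-bit ``edf`` for interoperability (European Data Format; quantized).  EDF
files are read through :mod:`mne`; writing uses a minimal EDF writer
implemented here.  Event, gaze and ground-truth tables are tab-separated
text; assembled results live in an HDF5 container with provenance
attributes (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    AnalysisConfig,
    ChannelLayout,
    EventStream,
    EVENT_LABELS,
    Recording,
    default_layout,
)

__all__ = [
    "FormatError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_gaze",
    "write_gaze",
    "write_layout",
    "read_layout_table",
    "ResultsContainer",
    "config_hash",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# recordings


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_recording(rec: Recording, path, dialect: str = "raw_matrix") -> Path:
    """Write a recording; returns the main data path."""
    path = Path(path)
    if dialect == "raw_matrix":
        rec.data.astype("<f8").tofile(path)
        meta = {
            "rate": float(rec.rate),
            "n_channels": int(rec.n_channels),
            "n_samples": int(rec.n_samples),
            "channel_names": list(rec.layout.names) if rec.layout else None,
            "units": "uV",
            "dtype": "<f8",
            "session": rec.session,
            "condition": rec.condition,
            "rs_index": rec.rs_index,
        }
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        return path
    if dialect == "edf":
        _write_edf(rec, path)
        return path
    raise ValueError("dialect must be 'raw_matrix' or 'edf'")


def read_recording(
    path, dialect: str = "raw_matrix", layout: Optional[ChannelLayout] = None
) -> Recording:
    """Read a recording; µV units are enforced on the way in."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "raw_matrix":
        side = _sidecar_path(path)
        if not side.exists():
            raise FormatError(f"missing sidecar: {side}")
        with open(side) as fh:
            meta = yaml.safe_load(fh)
        for key in ("rate", "n_channels", "n_samples", "dtype"):
            if key not in meta:
                raise FormatError(f"sidecar missing required field {key!r}")
        data = np.fromfile(path, dtype=meta["dtype"])
        n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
        if data.size != n_ch * n_s:
            raise FormatError(
                f"truncated or oversized data: expected {n_ch * n_s} values, got {data.size}"
            )
        data = data.reshape(n_ch, n_s)
        layout = layout or (default_layout() if n_ch == 31 else None)
        if layout is not None and layout.n_channels != n_ch:
            raise FormatError(
                f"layout declares {layout.n_channels} channels, file has {n_ch}"
            )
        return Recording(
            data=data,
            rate=float(meta["rate"]),
            layout=layout,
            session=meta.get("session"),
            condition=meta.get("condition"),
            rs_index=meta.get("rs_index"),
        )
    if dialect == "edf":
        return _read_edf(path, layout)
    raise ValueError("dialect must be 'raw_matrix' or 'edf'")


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 1 s data records, 16-bit, physical units µV."""
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise FormatError("EDF writing requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    pad = n_rec * spr - rec.n_samples
    data = rec.data
    if pad:
        data = np.concatenate([data, np.repeat(data[:, -1:], pad, axis=1)], axis=1)

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / gain[:, None] + dmin).astype("<i2")

    names = rec.layout.names if rec.layout else [f"ch{i}" for i in range(n_ch)]
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X", 80)
    header += _edf_field("hemisync", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field("1", 8)
    header += _edf_field(n_ch, 4)

    def sig(field, width):
        return b"".join(_edf_field(field(i), width) for i in range(n_ch))

    header += sig(lambda i: names[i], 16)
    header += sig(lambda i: "", 80)
    header += sig(lambda i: "uV", 8)
    header += sig(lambda i: f"{pmin[i]:.8g}"[:8], 8)
    header += sig(lambda i: f"{pmax[i]:.8g}"[:8], 8)
    header += sig(lambda i: dmin, 8)
    header += sig(lambda i: dmax, 8)
    header += sig(lambda i: "", 80)
    header += sig(lambda i: spr, 8)
    header += sig(lambda i: "", 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def _read_edf(path: Path, layout: Optional[ChannelLayout]) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for malformed files
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    rate = float(raw.info["sfreq"])
    n_ch = data_uv.shape[0]
    layout = layout or (default_layout() if n_ch == 31 else None)
    if layout is not None and layout.n_channels != n_ch:
        raise FormatError(
            f"layout declares {layout.n_channels} channels, file has {n_ch}"
        )
    return Recording(data=data_uv, rate=rate, layout=layout)


# ---------------------------------------------------------------------------
# events and gaze


def write_events(events: EventStream, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s\tlabel\n")
        for t, lab in events:
            fh.write(f"{t:.6f}\t{lab}\n")
    return path


def read_events(path) -> EventStream:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("time_s"):
            raise FormatError("events file must start with a 'time_s\\tlabel' header")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {ln}: expected two tab-separated fields")
            t_str, lab = parts
            if lab not in EVENT_LABELS:
                raise FormatError(
                    f"line {ln}: unknown label {lab!r}; allowed: {sorted(EVENT_LABELS)}"
                )
            rows.append((float(t_str), lab))
    try:
        return EventStream(rows)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_gaze(trace, path) -> Path:
    from .eyetracking import GazeTrace  # local import to avoid cycles

    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "x_deg": trace.x,
            "y_deg": trace.y,
            "blink": trace.blink_mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = {"rate": float(trace.rate), "units": "deg"}
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_gaze(path):
    from .eyetracking import GazeTrace

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar: {side}")
    with open(side) as fh:
        meta = yaml.safe_load(fh)
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "x_deg", "y_deg"):
        if col not in df.columns:
            raise FormatError(f"gaze table missing column {col!r}")
    blink = df["blink"].to_numpy(bool) if "blink" in df else None
    return GazeTrace(
        time=df["time_s"].to_numpy(),
        x=df["x_deg"].to_numpy(),
        y=df["y_deg"].to_numpy(),
        rate=float(meta["rate"]),
        blink_mask=blink,
    )


# ---------------------------------------------------------------------------
# layout tables


def write_layout(layout: ChannelLayout, path) -> Path:
    """Serialize a layout as a delimited table plus pair/adjacency listing."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("name\tx\ty\themisphere\n")
        for i, name in enumerate(layout.names):
            x, y = layout.positions[i]
            fh.write(f"{name}\t{x:.6f}\t{y:.6f}\t{layout.hemispheres[i]}\n")
        fh.write("#pairs\n")
        for k, (li, ri) in enumerate(layout.pairs):
            poi = "*" if k == layout.pair_of_interest else ""
            fh.write(f"{layout.names[li]}\t{layout.names[ri]}\t{poi}\n")
        fh.write("#adjacency\n")
        for i, nbrs in enumerate(layout.adjacency):
            names = ",".join(layout.names[j] for j in sorted(nbrs))
            fh.write(f"{layout.names[i]}\t{names}\n")
    return path


def read_layout_table(path) -> pd.DataFrame:
    """Read back the channel table section of a serialized layout."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.startswith("#"):
                break
            name, x, y, hemi = line.rstrip("\n").split("\t")
            rows.append({"name": name, "x": float(x), "y": float(y), "hemisphere": hemi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# results container


def config_hash(cfg: AnalysisConfig) -> str:
    blob = yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class ResultsContainer:
    """Hierarchical HDF5 store for pipeline outputs with provenance.

    Numeric payloads round-trip losslessly (float64/complex128/int64);
    DataFrames are stored as column arrays with a column-order attribute.
    """

    def __init__(self, path, mode: str = "a", cfg: Optional[AnalysisConfig] = None):
        import h5py

        self._h5 = h5py.File(path, mode)
        if cfg is not None:
            self._h5.attrs["config_hash"] = config_hash(cfg)
            self._h5.attrs["seed"] = int(cfg.seed)
            from . import __version__

            self._h5.attrs["version"] = __version__

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def close(self):
        self._h5.close()

    @property
    def provenance(self) -> dict:
        return dict(self._h5.attrs)

    def save_array(self, name: str, arr: np.ndarray) -> None:
        if name in self._h5:
            del self._h5[name]
        self._h5.create_dataset(name, data=np.asarray(arr))

    def load_array(self, name: str) -> np.ndarray:
        return self._h5[name][()]

    def save_table(self, name: str, df: pd.DataFrame) -> None:
        grp_name = f"{name}__table"
        if grp_name in self._h5:
            del self._h5[grp_name]
        grp = self._h5.create_group(grp_name)
        grp.attrs["columns"] = [str(c) for c in df.columns]
        for col in df.columns:
            vals = df[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            grp.create_dataset(str(col), data=vals)

    def load_table(self, name: str) -> pd.DataFrame:
        grp = self._h5[f"{name}__table"]
        cols = {}
        for col in grp.attrs["columns"]:
            vals = grp[col][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[col] = vals
        return pd.DataFrame(cols)

    def __contains__(self, name: str) -> bool:
        return name in self._h5 or f"{name}__table" in self._h5
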