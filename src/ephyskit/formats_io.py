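"""Readers and writers for the toolkit's containers and interchange formats.

Binary container
----------------
All three signal containers (continuous, event-locked, time-frequency) share
one self-describing binary layout:

* bytes 0..7   — magic ``EPHYSKT1``
* bytes 8..11  — little-endian uint32, byte length ``H`` of the JSON header
* bytes 12..12+H — UTF-8 JSON header: ``{"kind": ..., "meta": {...},
  "arrays": {name: {"dtype": "<f8", "shape": [...], "offset": n}}}``
* remainder    — raw little-endian array bytes at the stated offsets

Arrays are written with their in-memory dtype (float64 by default; float32 on
request at write time), so write-then-read is bit-exact, including NaN
payloads. There is no attempt at byte compatibility with any historical
format; the layout above is the documentation of record.

Text formats
------------
* Event files: whitespace-delimited ``sample code [reject]`` lines,
  ``#`` comments; a missing third column means "kept".
* Montage files: ``label azimuth elevation`` (degrees) or ``label x y z``;
  positions are normalised to the unit sphere.
* Parameter files: ``key = value`` lines with ``#`` comments.
* Delimited ASCII signal tables, channels as columns or rows.

EDF import goes through MNE's reader; all signals must share one sampling
rate. Values are returned in each channel's native header unit (MNE's SI
conversion is undone using the recorded original units).
"""

from __future__ import annotations

import json
import logging
import struct
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .containers import (
    ContinuousRecord,
    EventList,
    EvokedRecord,
    Montage,
    ParamSet,
    TFRecord,
)
from .errors import ConsistencyError, FormatError, ParameterError, ParseError

logger = logging.getLogger(__name__)

MAGIC = b"EPHYSKT1"

__all__ = [
    "read_continuous", "write_continuous",
    "read_events", "write_events",
    "read_evoked", "write_evoked",
    "read_tf", "write_tf",
    "import_edf", "import_ascii", "export_ascii",
    "read_montage", "read_params", "write_params",
]


# ---------------------------------------------------------------- container

def _write_blocks(path, kind: str, meta: dict, arrays: Mapping[str, np.ndarray],
                  dtype: str | None = None) -> None:
    blobs = {}
    offset = 0
    header_arrays = {}
    for name, arr in arrays.items():
        arr = np.ascontiguousarray(arr)
        if dtype is not None and arr.dtype.kind == "f":
            arr = arr.astype(dtype)
        if arr.dtype.byteorder == ">":
            arr = arr.astype(arr.dtype.newbyteorder("<"))
        buf = arr.tobytes()
        header_arrays[name] = {
            "dtype": arr.dtype.str,
            "shape": list(arr.shape),
            "offset": offset,
        }
        blobs[name] = buf
        offset += len(buf)
    header = json.dumps({"kind": kind, "meta": meta, "arrays": header_arrays},
                        ensure_ascii=False).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", len(header)))
        fh.write(header)
        for name in arrays:
            fh.write(blobs[name])


def _read_blocks(path, expect_kind: str):
    path = Path(path)
    raw = path.read_bytes()
    if raw[:8] != MAGIC:
        raise FormatError(f"{path}: bad magic {raw[:8]!r}, not an ephyskit container")
    (hlen,) = struct.unpack("<I", raw[8:12])
    try:
        header = json.loads(raw[12:12 + hlen].decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: corrupt JSON header ({exc})") from None
    for key in ("kind", "meta", "arrays"):
        if key not in header:
            raise FormatError(f"{path}: header missing field {key!r}")
    if header["kind"] != expect_kind:
        raise FormatError(
            f"{path}: container holds {header['kind']!r}, expected {expect_kind!r}"
        )
    base = 12 + hlen
    arrays = {}
    for name, spec in header["arrays"].items():
        dt = np.dtype(spec["dtype"])
        shape = tuple(spec["shape"])
        nbytes = dt.itemsize * int(np.prod(shape, dtype=np.int64))
        start = base + spec["offset"]
        if start + nbytes > len(raw):
            raise FormatError(f"{path}: array {name!r} truncated")
        arrays[name] = np.frombuffer(
            raw[start:start + nbytes], dtype=dt
        ).reshape(shape).copy()
    return header["meta"], arrays


def write_continuous(rec: ContinuousRecord, path, dtype: str | None = None) -> None:
    """Write a ContinuousRecord; ``dtype`` may force float32 storage."""
    meta = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "channel_units": rec.channel_units,
    }
    arrays = {
        "data": rec.data,
        "event_samples": rec.events.samples,
        "event_codes": rec.events.codes,
        "event_rejects": rec.events.rejects,
    }
    _write_blocks(path, "continuous", meta, arrays, dtype=dtype)


def read_continuous(path) -> ContinuousRecord:
    meta, arrays = _read_blocks(path, "continuous")
    events = EventList(arrays["event_samples"], arrays["event_codes"],
                       arrays["event_rejects"])
    try:
        return ContinuousRecord(arrays["data"], meta["fs"],
                                meta["channel_names"], meta["channel_units"],
                                events)
    except ConsistencyError as exc:
        raise ConsistencyError(f"{path}: {exc}") from None


def write_evoked(ev: EvokedRecord, path, dtype: str | None = None) -> None:
    meta = {
        "fs": ev.fs, "t0": ev.t0, "event_code": ev.event_code,
        "n_trials": ev.n_trials,
        "channel_names": ev.channel_names, "channel_units": ev.channel_units,
    }
    _write_blocks(path, "evoked", meta, {"data": ev.data}, dtype=dtype)


def read_evoked(path) -> EvokedRecord:
    meta, arrays = _read_blocks(path, "evoked")
    try:
        return EvokedRecord(arrays["data"], meta["fs"], meta["t0"],
                            meta["event_code"], meta["n_trials"],
                            meta["channel_names"], meta["channel_units"])
    except ConsistencyError as exc:
        raise ConsistencyError(f"{path}: {exc}") from None


def write_tf(tfr: TFRecord, path, dtype: str | None = None) -> None:
    # validate against the freshest state (data may have been mutated)
    check = TFRecord(tfr.data, tfr.freqs, tfr.fs, tfr.t0, tfr.event_code,
                     tfr.n_trials, tfr.quantity, tfr.channel_names,
                     tfr.channel_units, dict(tfr.extra))
    meta = {
        "fs": check.fs, "t0": check.t0, "event_code": check.event_code,
        "n_trials": check.n_trials, "quantity": check.quantity,
        "channel_names": check.channel_names,
        "channel_units": check.channel_units,
        "extra": check.extra,
    }
    _write_blocks(path, "tf", meta,
                  {"data": check.data, "freqs": check.freqs}, dtype=dtype)


def read_tf(path) -> TFRecord:
    meta, arrays = _read_blocks(path, "tf")
    try:
        return TFRecord(arrays["data"], arrays["freqs"], meta["fs"],
                        meta["t0"], meta["event_code"], meta["n_trials"],
                        meta["quantity"], meta["channel_names"],
                        meta["channel_units"], meta.get("extra", {}))
    except ConsistencyError as exc:
        raise ConsistencyError(f"{path}: {exc}") from None


# ------------------------------------------------------------------ events

def write_events(ev: EventList, path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample code reject\n")
        for e in ev:
            fh.write(f"{e.sample} {e.code} {1 if e.reject else 0}\n")


def read_events(path) -> EventList:
    samples, codes, rejects = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ParseError(
                    f"expected 'sample code [reject]', got {line!r}", lineno)
            try:
                vals = [int(p) for p in parts]
            except ValueError:
                raise ParseError(f"non-integer field in {line!r}", lineno) from None
            if vals[0] < 0:
                raise ParseError(f"negative sample {vals[0]}", lineno)
            samples.append(vals[0])
            codes.append(vals[1])
            rejects.append(bool(vals[2]) if len(vals) == 3 else False)
    return EventList(samples, codes, rejects)


# ----------------------------------------------------------------- montage

def read_montage(path) -> Montage:
    labels, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ParseError(
                    "expected 'label az el' or 'label x y z', got "
                    f"{line!r}", lineno)
            try:
                nums = [float(p) for p in parts[1:]]
            except ValueError:
                raise ParseError(f"non-numeric coordinate in {line!r}", lineno) from None
            labels.append(parts[0])
            rows.append(nums)
    spherical = [r for r in rows if len(r) == 2]
    if spherical and len(spherical) != len(rows):
        raise ParseError("montage mixes spherical and Cartesian rows")
    if spherical:
        az = [r[0] for r in rows]
        el = [r[1] for r in rows]
        return Montage.from_spherical(labels, az, el)
    return Montage(labels, np.asarray(rows))


def write_montage(montage: Montage, path) -> None:
    with open(path, "w") as fh:
        fh.write("# label x y z (unit sphere; +x nose, +z vertex)\n")
        for lab, pos in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {pos[0]:.9f} {pos[1]:.9f} {pos[2]:.9f}\n")


# ------------------------------------------------------------------ params

def read_params(path) -> ParamSet:
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"expected 'key = value', got {line!r}", lineno)
            key, val = line.split("=", 1)
            values[key.strip()] = val.strip()
    return ParamSet(values)


def write_params(params: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for key, val in params.items():
            fh.write(f"{key} = {val}\n")


# ------------------------------------------------------------------- ASCII

def import_ascii(path, fs: float, layout: str = "columns",
                 delimiter: str | None = None,
                 channel_names: Sequence[str] | None = None,
                 unit: str = "a.u.") -> ContinuousRecord:
    """Import a delimited numeric table as a continuous recording.

    ``layout`` declares whether channels run along *columns* (one row per
    sample) or *rows* (one line per channel).
    """
    if layout not in ("columns", "rows"):
        raise ParameterError("layout must be 'columns' or 'rows'")
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ParseError(f"non-numeric value in {line!r}", lineno) from None
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ParseError(
                    f"ragged row: {len(vals)} values, expected {width}", lineno)
            rows.append(vals)
    if not rows:
        raise ParseError("no numeric rows found")
    table = np.asarray(rows, dtype=np.float64)
    data = table.T if layout == "columns" else table
    n_ch = data.shape[0]
    if channel_names is None:
        channel_names = [f"ch{i + 1}" for i in range(n_ch)]
    return ContinuousRecord(data, fs, list(channel_names), [unit] * n_ch)


def export_ascii(rec: ContinuousRecord, path, layout: str = "columns",
                 delimiter: str = "\t") -> None:
    """Export a recording as delimited text with >= 9 significant digits."""
    if layout not in ("columns", "rows"):
        raise ParameterError("layout must be 'columns' or 'rows'")
    table = rec.data.T if layout == "columns" else rec.data
    header = delimiter.join(rec.channel_names) if layout == "columns" else ""
    np.savetxt(path, table, fmt="%.12e", delimiter=delimiter,
               header=header, comments="# ")


# --------------------------------------------------------------------- EDF

#: scale back to the native header unit from MNE's SI-converted values
_SI_FACTORS = {
    "v": 1.0, "mv": 1e-3, "uv": 1e-6, "µv": 1e-6, "μv": 1e-6,
    "nv": 1e-9,
    "t": 1.0, "ft": 1e-15, "pt": 1e-12,
}


def _edf_sample_rates(path) -> list[float]:
    """Peek at the fixed-width EDF header for per-signal sampling rates."""
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            duration = float(hdr[244:252].decode("ascii").strip())
            n_sig = int(hdr[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError):
            raise FormatError(f"{path}: malformed EDF header") from None
        sig_hdr = fh.read(n_sig * 256)
    labels_raw = [
        sig_hdr[i * 16:(i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(n_sig)
    ]
    off = n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = []
    for i in range(n_sig):
        field = sig_hdr[off + i * 8: off + (i + 1) * 8]
        spr = int(field.decode("ascii").strip())
        if labels_raw[i] == "EDF Annotations":
            continue
        rates.append(spr / duration)
    return rates


def import_edf(path, annotation_codes: Mapping[str, int] | None = None
               ) -> ContinuousRecord:
    """Import an EDF/EDF+ file as a ContinuousRecord.

    All data signals must share one sampling rate. Values are returned in
    each channel's native header unit. EDF+ annotations are converted to
    events via the ``annotation_codes`` description->code mapping; unmapped
    annotations are dropped with a warning.
    """
    rates = _edf_sample_rates(path)
    if len(set(rates)) > 1:
        raise FormatError(
            f"{path}: signals have mixed sampling rates {sorted(set(rates))}; "
            "only single-rate EDF files are supported")
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_si = raw.get_data()
    fs = float(raw.info["sfreq"])
    orig_units = getattr(raw, "_orig_units", {}) or {}
    names = list(raw.ch_names)
    units, data = [], np.empty_like(data_si)
    types = raw.get_channel_types()
    for i, name in enumerate(names):
        unit = orig_units.get(name, "a.u.")
        factor = _SI_FACTORS.get(unit.lower())
        if factor is not None and types[i] != "misc":
            data[i] = data_si[i] / factor
        else:
            data[i] = data_si[i]
        units.append(unit if unit != "n/a" else "a.u.")

    samples, codes = [], []
    for ann in raw.annotations:
        desc = ann["description"]
        if annotation_codes and desc in annotation_codes:
            samples.append(int(round(ann["onset"] * fs)))
            codes.append(int(annotation_codes[desc]))
        else:
            logger.warning("dropping unmapped EDF annotation %r", desc)
    events = EventList(samples, codes)
    return ContinuousRecord(data, fs, names, units, events)
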