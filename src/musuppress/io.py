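"""Readers and writers: EDF/BDF, an internal HDF5 container, montage and
study-manifest files.

EDF stores 16-bit samples against a per-channel physical range, so EDF
round trips are exact only up to that quantization; the internal HDF5
container preserves float64 and is the format of record for intermediate
artifacts.  BDF is the 24-bit BioSemi dialect of EDF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    InvalidInputError,
    Recording,
    SourceModel,
)

_EDF_HEADER = 256

#: channels whose labels start with these prefixes are not scalp EEG
NON_EEG_PREFIXES = ("EOG", "EXG", "STATUS", "TRIG", "EMG", "ECG")


def is_eeg_channel(label: str) -> bool:
    return not label.upper().startswith(NON_EEG_PREFIXES)


# ---------------------------------------------------------------------------
# EDF / BDF
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt8(v: float, up: bool | None = None) -> str:
    """g-format of v fitting an 8-char EDF header field.

    up=True/False requests directed rounding (result >= v / <= v), needed
    so a stored physical range always encloses the data it scales.
    """
    import math

    for p in range(8, 0, -1):
        s = f"{v:.{p}g}"
        if len(s) > 8:
            continue
        f = float(s)
        if up is None or (up and f >= v) or (not up and f <= v):
            return s
        exp = math.floor(math.log10(abs(f))) if f != 0 else 0
        ulp = 10.0 ** (exp - p + 1)
        s2 = f"{f + ulp if up else f - ulp:.{p}g}"
        if len(s2) <= 8:
            f2 = float(s2)
            if (up and f2 >= v) or (not up and f2 <= v):
                return s2
    return f"{v:.1g}"


def _phys_range(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel [min, max] rounded outward to the 8-char precision the
    EDF header will store, so the digital scaling matches the file."""
    pmin = np.array([float(_fmt8(v, up=False)) for v in data.min(axis=1)])
    pmax = np.array([float(_fmt8(v, up=True)) for v in data.max(axis=1)])
    pmax = np.where(pmax - pmin <= 0, pmin + 1.0, pmax)
    return pmin, pmax


def write_edf(path, rec: Recording) -> None:
    """Write a Recording as EDF (16-bit).

    One data record per second; requires an integer sampling rate and an
    integral number of seconds.  Each channel is scaled linearly from its
    [min, max] physical range onto digital [-32768, 32767], so values are
    quantized to (max - min)/65535.
    """
    fs = int(round(rec.fs))
    if fs != rec.fs:
        raise InvalidInputError("EDF writer requires an integer sampling rate")
    if rec.n_samples % fs != 0:
        raise InvalidInputError("EDF writer requires whole seconds of data")
    n_records = rec.n_samples // fs
    ns = rec.n_channels
    phys_min, phys_max = _phys_range(rec.data)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((rec.data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    meta = f"subject={rec.subject} session={rec.session} condition={rec.condition}"
    header = b"".join([
        _ascii("0", 8), _ascii("X", 80), _ascii(meta, 80),
        _ascii("01.01.00", 8), _ascii("00.00.00", 8),
        _ascii(_EDF_HEADER * (ns + 1), 8), _ascii("", 44),
        _ascii(n_records, 8), _ascii(1, 8), _ascii(ns, 4),
    ])
    sig = b"".join([
        b"".join(_ascii(lbl, 16) for lbl in rec.ch_names),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii("uV", 8) for _ in range(ns)),
        b"".join(_ascii(_fmt8(v), 8) for v in phys_min),
        b"".join(_ascii(_fmt8(v), 8) for v in phys_max),
        b"".join(_ascii(dig_min, 8) for _ in range(ns)),
        b"".join(_ascii(dig_max, 8) for _ in range(ns)),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii(fs, 8) for _ in range(ns)),
        b"".join(_ascii("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def write_bdf(path, rec: Recording) -> None:
    """Write a Recording as BDF (BioSemi 24-bit EDF dialect)."""
    fs = int(round(rec.fs))
    if fs != rec.fs or rec.n_samples % fs != 0:
        raise InvalidInputError("BDF writer requires integer fs, whole seconds")
    n_records = rec.n_samples // fs
    ns = rec.n_channels
    phys_min, phys_max = _phys_range(rec.data)
    dig_min, dig_max = -8388608, 8388607
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round(
        (rec.data - phys_min[:, None]) * scale[:, None] + dig_min
    ), dig_min, dig_max).astype("<i4")

    meta = f"subject={rec.subject} session={rec.session} condition={rec.condition}"
    header = b"".join([
        b"\xffBIOSEMI", _ascii("X", 80), _ascii(meta, 80),
        _ascii("01.01.00", 8), _ascii("00.00.00", 8),
        _ascii(_EDF_HEADER * (ns + 1), 8), _ascii("24BIT", 44),
        _ascii(n_records, 8), _ascii(1, 8), _ascii(ns, 4),
    ])
    sig = b"".join([
        b"".join(_ascii(lbl, 16) for lbl in rec.ch_names),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii("uV", 8) for _ in range(ns)),
        b"".join(_ascii(_fmt8(v), 8) for v in phys_min),
        b"".join(_ascii(_fmt8(v), 8) for v in phys_max),
        b"".join(_ascii(dig_min, 8) for _ in range(ns)),
        b"".join(_ascii(dig_max, 8) for _ in range(ns)),
        b"".join(_ascii("", 80) for _ in range(ns)),
        b"".join(_ascii(fs, 8) for _ in range(ns)),
        b"".join(_ascii("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            as32 = block.astype("<i4").tobytes()
            # drop the high byte of each little-endian int32 -> 24-bit
            fh.write(np.frombuffer(as32, dtype=np.uint8).reshape(-1, 4)[:, :3]
                     .tobytes())


def _parse_edf_header(raw: bytes, path):
    def fld(off, width):
        return raw[off:off + width].decode("latin-1").strip()

    try:
        n_records = int(fld(236, 8))
        ns = int(fld(252, 4))
    except ValueError as exc:
        raise InvalidInputError(
            f"{path}: malformed EDF header near byte 236: {exc}"
        ) from None
    return n_records, ns, fld(88, 80)


def _read_edf_like(path, sample_bytes: int) -> Recording:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _EDF_HEADER:
        raise InvalidInputError(f"{path}: truncated header ({len(raw)} bytes)")
    n_records, ns, meta = _parse_edf_header(raw[:_EDF_HEADER], path)
    off = _EDF_HEADER
    sig_raw = raw[off:off + _EDF_HEADER * ns]
    if len(sig_raw) < _EDF_HEADER * ns:
        raise InvalidInputError(f"{path}: truncated signal header at byte {off}")

    def sig_fld(block_off, width, idx):
        start = block_off * ns + idx * width
        return sig_raw[start:start + width].decode("latin-1").strip()

    labels = [sig_fld(0, 16, i) for i in range(ns)]
    phys_min = np.array([float(sig_fld(16 + 80 + 8, 8, i)) for i in range(ns)])
    phys_max = np.array([float(sig_fld(16 + 80 + 8 + 8, 8, i)) for i in range(ns)])
    dig_min = np.array([float(sig_fld(16 + 80 + 8 + 16, 8, i)) for i in range(ns)])
    dig_max = np.array([float(sig_fld(16 + 80 + 8 + 24, 8, i)) for i in range(ns)])
    spr = [int(sig_fld(216, 8, i)) for i in range(ns)]
    if len(set(spr)) != 1:
        raise InvalidInputError(f"{path}: per-channel sampling rates unsupported")
    spr = spr[0]

    data_off = _EDF_HEADER * (ns + 1)
    rec_bytes = ns * spr * sample_bytes
    need = data_off + n_records * rec_bytes
    if len(raw) < need:
        raise InvalidInputError(
            f"{path}: truncated data at byte {len(raw)} (expected {need})"
        )
    if sample_bytes == 2:
        digital = np.frombuffer(
            raw, dtype="<i2", count=n_records * ns * spr, offset=data_off
        ).astype(float)
    else:
        u8 = np.frombuffer(
            raw, dtype=np.uint8, count=n_records * rec_bytes, offset=data_off
        ).reshape(-1, 3)
        digital = (u8[:, 0].astype(np.int32)
                   | (u8[:, 1].astype(np.int32) << 8)
                   | (u8[:, 2].astype(np.int32) << 16))
        digital = np.where(digital >= 1 << 23, digital - (1 << 24),
                           digital).astype(float)
    digital = digital.reshape(n_records, ns, spr).transpose(1, 0, 2).reshape(ns, -1)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]

    tags = dict(
        tok.split("=", 1) for tok in meta.split() if "=" in tok
    )
    return Recording(
        data, float(spr), labels,
        condition=tags.get("condition", ""), subject=tags.get("subject", ""),
        session=tags.get("session", ""),
    )


def read_edf(path) -> Recording:
    return _read_edf_like(path, sample_bytes=2)


def read_bdf(path) -> Recording:
    return _read_edf_like(path, sample_bytes=3)


# ---------------------------------------------------------------------------
# Internal HDF5 container (lossless float64)
# ---------------------------------------------------------------------------

def write_internal(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["fs"] = rec.fs
        d.attrs["ch_names"] = [n.encode() for n in rec.ch_names]
        for k in ("condition", "subject", "session"):
            d.attrs[k] = getattr(rec, k)


def read_internal(path) -> Recording:
    with h5py.File(path, "r") as f:
        d = f["data"]
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in d.attrs["ch_names"]]
        return Recording(
            d[()], float(d.attrs["fs"]), names,
            condition=str(d.attrs["condition"]), subject=str(d.attrs["subject"]),
            session=str(d.attrs["session"]),
        )


def read_recording(path, fmt: str | None = None) -> Recording:
    """Dispatch on format (edf, bdf, internal), inferred from the extension
    when fmt is None."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InvalidInputError(f"no such file: {path}")
    if fmt is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        fmt = {"edf": "edf", "bdf": "bdf", "h5": "internal",
               "hdf5": "internal"}.get(ext)
        if fmt is None:
            raise ConfigurationError(f"cannot infer format of {path}")
    if fmt == "edf":
        return read_edf(path)
    if fmt == "bdf":
        return read_bdf(path)
    if fmt == "internal":
        return read_internal(path)
    raise ConfigurationError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Montage, manifest, source model persistence
# ---------------------------------------------------------------------------

def write_montage(path, labels: list[str], positions: np.ndarray) -> None:
    """Whitespace-delimited "label x y z" text file."""
    with open(path, "w") as fh:
        for lbl, (x, y, z) in zip(labels, positions):
            fh.write(f"{lbl} {x:.8g} {y:.8g} {z:.8g}\n")


def read_montage(path) -> tuple[list[str], np.ndarray]:
    labels, rows = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise InvalidInputError(f"{path}:{ln + 1}: expected 'label x y z'")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return labels, np.asarray(rows)


MANIFEST_COLUMNS = ["subject", "session", "condition", "path", "role"]


@dataclass
class StudyManifest:
    """Rows mapping (subject, session, condition) to recording files."""

    table: pd.DataFrame
    base_dir: str = "."

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"manifest missing columns {sorted(missing)}")
        dup = self.table.duplicated(["subject", "session", "condition"])
        if dup.any():
            raise InvalidInputError(
                "duplicate (subject, session, condition) rows in manifest"
            )

    def resolve(self, row) -> str:
        p = row.path
        return p if os.path.isabs(p) else os.path.join(self.base_dir, p)

    @classmethod
    def from_csv(cls, path) -> "StudyManifest":
        df = pd.read_csv(path, dtype=str)
        return cls(df, base_dir=os.path.dirname(os.path.abspath(path)))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def export_study(
    recordings, model: SourceModel | None, out_dir, fmt: str = "internal"
) -> StudyManifest:
    """Write a simulated study to disk: one file per recording, a manifest
    CSV, a montage file, and (optionally) the source model."""
    os.makedirs(out_dir, exist_ok=True)
    writer = {"internal": (write_internal, "h5"), "edf": (write_edf, "edf"),
              "bdf": (write_bdf, "bdf")}.get(fmt)
    if writer is None:
        raise ConfigurationError(f"unknown export format {fmt!r}")
    write_fn, ext = writer
    rows = []
    for rec in recordings:
        name = f"{rec.subject}_{rec.session}_{rec.condition}.{ext}"
        write_fn(os.path.join(out_dir, name), rec)
        role = "rest" if rec.condition.startswith("rest") else "action"
        rows.append({"subject": rec.subject, "session": rec.session,
                     "condition": rec.condition, "path": name, "role": role})
    manifest = StudyManifest(pd.DataFrame(rows), base_dir=os.fspath(out_dir))
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"))
    if model is not None:
        write_montage(os.path.join(out_dir, "montage.txt"),
                      model.ch_names, model.channels)
        write_source_model(os.path.join(out_dir, "source_model.h5"), model)
    return manifest


def write_source_model(path, model: SourceModel) -> None:
    with h5py.File(path, "w") as f:
        for name in ("vertices", "channels", "triangles", "adjacency", "leadfield"):
            f.create_dataset(name, data=getattr(model, name))
        f.attrs["ch_names"] = [n.encode() for n in model.ch_names]


def read_source_model(path) -> SourceModel:
    with h5py.File(path, "r") as f:
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs["ch_names"]]
        return SourceModel(
            f["vertices"][()], f["channels"][()], names,
            f["triangles"][()].astype(int), f["adjacency"][()], f["leadfield"][()],
        )
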