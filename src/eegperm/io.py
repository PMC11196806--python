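"""Recording container and on-disk formats.

Two interchange formats are supported:

* **EDF** (16-bit European Data Format, physical dimension µV).  Reading is
  delegated to MNE's EDF reader; writing uses a minimal self-contained EDF
  writer (fixed-width ASCII header + int16 data records) sufficient for the
  continuous single-session recordings produced here.
* **raw-matrix**: a float32 little-endian channels×samples binary next to a
  JSON sidecar carrying ``fs``, ``labels`` and optional ``coords``.

Voltages are always expressed in µV in memory, whatever the on-disk units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import Montage, assign_regions

__all__ = ["Recording", "read_recording", "write_recording"]


@dataclass
class Recording:
    """One subject/condition multichannel EEG signal in µV."""

    data: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    labels: tuple[str, ...]
    coords: np.ndarray | None = None  # (n_channels, 3), unit head sphere
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            ch, smp = bad[0]
            raise ValueError(
                f"non-finite sample in channel {self.labels[ch]!r} at index {smp}"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def montage(self) -> Montage:
        return assign_regions(self.labels)


# ---------------------------------------------------------------------------
# raw-matrix format


def _write_raw_matrix(rec: Recording, path: Path) -> None:
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    sidecar = {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "units": "uV",
    }
    if rec.coords is not None:
        sidecar["coords"] = rec.coords.tolist()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def _read_raw_matrix(path: Path) -> Recording:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    raw = np.fromfile(path, dtype="<f4")
    n_ch, n_smp = sidecar["n_channels"], sidecar["n_samples"]
    if raw.size != n_ch * n_smp:
        raise ValueError(
            f"{path}: expected {n_ch}x{n_smp} samples, found {raw.size}"
        )
    coords = sidecar.get("coords")
    return Recording(
        data=raw.reshape(n_ch, n_smp).astype(float),
        fs=float(sidecar["fs"]),
        labels=tuple(sidecar["labels"]),
        coords=np.asarray(coords, dtype=float) if coords is not None else None,
    )


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Write a continuous 16-bit EDF file with 1-second data records."""
    if rec.fs != int(rec.fs):
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(rec.fs)
    ns = rec.n_channels
    n_full = rec.n_samples // fs
    data = rec.data[:, : n_full * fs]
    if data.shape[1] < rec.n_samples:
        warnings.warn("EDF export trims a trailing partial second", stacklevel=2)

    # Per-channel physical scaling onto the int16 digital range.
    pmin = np.floor(data.min(axis=1)) - 1.0
    pmax = np.ceil(data.max(axis=1)) + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None]) + dmin
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join(
        [
            _edf_field(0, 8),  # version
            _edf_field("X X X X", 80),  # patient id (anonymous)
            _edf_field("Startdate X X X X", 80),  # recording id
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (1 + ns), 8),
            _edf_field("", 44),
            _edf_field(n_full, 8),
            _edf_field(1, 8),  # record duration, seconds
            _edf_field(ns, 4),
        ]
    )
    fields = [
        (16, [lb for lb in rec.labels]),
        (80, ["EEG" for _ in rec.labels]),
        (8, ["uV" for _ in rec.labels]),
        (8, [f"{v:.8g}"[:8] for v in pmin]),
        (8, [f"{v:.8g}"[:8] for v in pmax]),
        (8, [dmin for _ in rec.labels]),
        (8, [dmax for _ in rec.labels]),
        (80, ["" for _ in rec.labels]),
        (8, [fs for _ in rec.labels]),
        (32, ["" for _ in rec.labels]),
    ]
    sig_header = b"".join(
        b"".join(_edf_field(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        # data records: for each second, all samples of ch1, then ch2, ...
        for r in range(n_full):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    mne.set_log_level("ERROR")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # MNE holds volts; recordings are µV
    return Recording(
        data=data, fs=float(raw.info["sfreq"]), labels=tuple(raw.ch_names)
    )


# ---------------------------------------------------------------------------
# public surface


def _infer_format(path: Path) -> str:
    return "edf" if path.suffix.lower() == ".edf" else "raw-matrix"


def read_recording(path, format: str | None = None) -> Recording:
    """Load a recording from EDF or raw-matrix, attaching template coordinates.

    Channels whose names are absent from the 10-10 montage template keep
    their data but are flagged with a warning: they carry no coordinates and
    are excluded from spatial analyses downstream.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "raw-matrix":
        rec = _read_raw_matrix(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if rec.coords is None:
        from .montage import _template_positions

        try:
            rec.coords = _template_positions(rec.labels)
        except KeyError as err:
            warnings.warn(
                f"{path.name}: {err}; coordinate-less channels are excluded "
                "from spatial analyses",
                stacklevel=2,
            )
    return rec


def write_recording(rec: Recording, path, format: str | None = None) -> Path:
    """Write a recording as EDF or raw-matrix (chosen from the extension)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "raw-matrix":
        _write_raw_matrix(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
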