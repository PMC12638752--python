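"""Recording container and file I/O.

Two on-disk dialects are supported:

* a plain-text dialect — a CSV matrix (channels as columns, header row of
  channel names, UTF-8, ``.`` decimal) plus a JSON sidecar holding the
  sampling rate, montage and annotations;
* EDF (16-bit European Data Format).  Reading goes through MNE's EDF
  reader; writing uses a minimal EDF writer implemented here.

Amplitudes are microvolts throughout.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import Montage, generate_montage

__all__ = ["Recording", "FormatError", "read_recording", "write_recording"]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass
class Recording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    montage : Montage
        Channel names and positions; its order matches the rows of ``data``.
    annotations : list of (start_s, end_s, label)
        Behavioural intervals in seconds, e.g. ``(0.0, 12.5, "inactive")``.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self, data: np.ndarray | None = None) -> "Recording":
        return Recording(
            self.data.copy() if data is None else data,
            self.fs,
            self.montage,
            list(self.annotations),
        )


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to ``path`` (.csv + .json sidecar, or .edf)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
        return
    if path.suffix.lower() != ".csv":
        raise FormatError(f"unsupported extension: {path.suffix}")
    header = ",".join(rec.montage.channel_names)
    np.savetxt(path, rec.data.T, delimiter=",", header=header, comments="",
               fmt="%.10g", encoding="utf-8")
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.montage.channel_names),
        "positions": rec.montage.positions.tolist(),
        "annotations": [list(a) for a in rec.annotations],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar), encoding="utf-8")


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` (or any EDF)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix.lower() != ".csv":
        raise FormatError(f"unsupported extension: {path.suffix}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2).T
    names = meta["channel_names"]
    if data.shape[0] != len(names):
        raise FormatError(
            f"CSV has {data.shape[0]} columns but sidecar lists "
            f"{len(names)} channels"
        )
    montage = Montage(tuple(names), np.asarray(meta["positions"], dtype=float))
    annotations = [(float(a[0]), float(a[1]), str(a[2]))
                   for a in meta.get("annotations", [])]
    return Recording(data, float(meta["fs"]), montage, annotations)


# ---------------------------------------------------------------------------
# EDF

def _fmt8(value: float, down: bool) -> str:
    """Widest decimal representation of ``value`` fitting 8 ASCII chars,
    nudged outward (down for minima, up for maxima) so the stated physical
    range always covers the data."""
    for prec in (10, 8, 7, 6, 5, 4, 3, 2, 1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            parsed = float(s)
            if (down and parsed <= value) or (not down and parsed >= value):
                return s
            # nudge one representable step outward
            step = abs(parsed) * 10.0 ** (1 - prec) + 10.0 ** (1 - prec)
            s2 = f"{parsed - step if down else parsed + step:.{prec}g}"
            if len(s2) <= 8:
                return s2
    raise FormatError(f"cannot represent {value} in an EDF header field")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal 16-bit EDF writer (data records of 1 s; final record padded).

    Physical dimension is microvolts; per-channel physical min/max are the
    observed data range, so quantization error is (range / 2^16) / 2.
    """
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9 or spr < 1:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    # round limits to their 8-char header representation before scaling,
    # otherwise reconstruction uses different limits than quantization did
    pmin = np.array([float(_fmt8(v, down=True)) for v in pmin])
    pmax = np.array([float(_fmt8(v, down=False)) for v in pmax])
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    header = b"".join([
        pad("0", 8),                       # version
        pad("X X X X", 80),                # patient id
        pad("Startdate X X X X", 80),      # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8),     # header bytes
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),                       # record duration (s)
        pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(pad(name, 16) for name in rec.montage.channel_names),
        b"".join(pad("", 80) for _ in range(n_ch)),       # transducer
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(_fmt8(v, down=True), 8) for v in pmin),
        b"".join(pad(_fmt8(v, down=False), 8) for v in pmax),
        b"".join(pad(str(dmin), 8) for _ in range(n_ch)),
        b"".join(pad(str(dmax), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),       # prefiltering
        b"".join(pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * spr: (r + 1) * spr]
            fh.write(struct.pack(f"<{n_ch * spr}h", *block.ravel()))


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE holds EEG in volts
    names = tuple(raw.ch_names)
    fs = float(raw.info["sfreq"])
    if len(names) in (19, 21):
        base = generate_montage(len(names))
        montage = Montage(names, base.positions)
    else:
        montage = Montage(names, generate_montage(len(names)).positions)
    return Recording(data_uv, fs, montage)
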