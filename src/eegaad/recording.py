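"""Multichannel EEG recording container and file readers.

Supported on-disk forms:

* CSV or ``.npy`` matrix (channels x samples) plus a JSON sidecar holding
  ``fs``, ``channel_names`` and optionally ``label`` / ``subject_id`` /
  ``trial_id``.
* Uncompressed EDF/EDF+ and BDF (BioSemi 24-bit) files via a minimal
  built-in reader (all signals must share one sampling rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["EEGRecording", "load_recording", "read_edf"]

VALID_LABELS = ("left", "right")


@dataclass
class EEGRecording:
    """A channels x samples EEG matrix with provenance metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (or arbitrary consistent units).
    fs : float
        Sampling rate in Hz, > 0.
    channel_names : list of str
        Unique channel names, one per row of ``data``.
    subject_id, trial_id : str
        Free-form identifiers.
    label : str or None
        Attended direction, ``"left"`` or ``"right"``, if known.
    window_index : int or None
        Set on segments produced by :func:`eegaad.ssf.segment_windows`.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = "S0"
    trial_id: str = "T0"
    label: str | None = None
    window_index: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in EEG data")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EEGRecording":
        """Shallow-copy the recording, replacing the given fields."""
        return replace(self, **kwargs)


def load_recording(path: str | Path, sidecar: str | Path | None = None) -> EEGRecording:
    """Load an EEG recording from disk, dispatching on file extension.

    ``.edf``/``.bdf`` are read directly. ``.csv``/``.npy`` matrices need a
    JSON sidecar (default: same stem with ``.json`` suffix).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        return read_edf(path)
    if suffix == ".npy":
        data = np.load(path)
    elif suffix in (".csv", ".txt"):
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        raise ValueError(f"unsupported EEG file type: {path.suffix}")
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar}")
    info = json.loads(sidecar.read_text())
    return EEGRecording(
        data=data,
        fs=float(info["fs"]),
        channel_names=list(info["channel_names"]),
        subject_id=str(info.get("subject_id", "S0")),
        trial_id=str(info.get("trial_id", "T0")),
        label=info.get("label"),
    )


def _edf_field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def read_edf(path: str | Path) -> EEGRecording:
    """Minimal EDF/EDF+/BDF reader (uniform sampling rate, no annotations).

    EDF stores 16-bit little-endian samples, BDF 24-bit; both use fixed-width
    ASCII headers. Values are rescaled to physical units via the per-signal
    digital/physical min/max calibration.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError("truncated EDF header")
    is_bdf = raw[0] == 255 and raw[1:8] == b"BIOSEMI"
    header_bytes = int(_edf_field(raw, 184, 8))
    n_records = int(_edf_field(raw, 236, 8))
    record_dur = float(_edf_field(raw, 244, 8))
    ns = int(_edf_field(raw, 252, 4))

    # signal header layout: label16, transducer80, dim8, pmin8, pmax8,
    # dmin8, dmax8, prefilter80, samples-per-record8
    off = 0
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8]
    fields = []
    for w in widths:
        base = 256 + off
        fields.append([_edf_field(raw, base + i * w, w) for i in range(ns)])
        off += w * ns
    labels = fields[0]
    phys_min = np.array([float(v) for v in fields[3]])
    phys_max = np.array([float(v) for v in fields[4]])
    dig_min = np.array([float(v) for v in fields[5]])
    dig_max = np.array([float(v) for v in fields[6]])
    n_samp = np.array([int(v) for v in fields[8]])

    keep = [i for i, lab in enumerate(labels) if "annotation" not in lab.lower()]
    if len(set(n_samp[keep])) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr = int(n_samp[keep[0]])
    fs = spr / record_dur

    bps = 3 if is_bdf else 2
    rec_len = int(np.sum(n_samp)) * bps
    body = raw[header_bytes:]
    if n_records < 0:  # EDF+ allows -1: infer from file size
        n_records = len(body) // rec_len
    data = np.zeros((len(keep), n_records * spr))
    offsets = np.concatenate([[0], np.cumsum(n_samp)]) * bps
    for r in range(n_records):
        rec = body[r * rec_len : (r + 1) * rec_len]
        for j, i in enumerate(keep):
            chunk = rec[offsets[i] : offsets[i] + n_samp[i] * bps]
            if is_bdf:
                b = np.frombuffer(chunk, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
                dig = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
                dig[dig >= 1 << 23] -= 1 << 24
            else:
                dig = np.frombuffer(chunk, dtype="<i2").astype(np.int32)
            data[j, r * spr : (r + 1) * spr] = dig
    gain = (phys_max[keep] - phys_min[keep]) / (dig_max[keep] - dig_min[keep])
    offset = phys_min[keep] - gain * dig_min[keep]
    data = data * gain[:, None] + offset[:, None]
    names = [labels[i] for i in keep]
    return EEGRecording(data=data, fs=fs, channel_names=names,
                        subject_id=_edf_field(raw, 8, 80).split() [0] if _edf_field(raw, 8, 80) else "S0")
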