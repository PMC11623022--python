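"""Spectro-spatial feature maps: windowed EEG -> 28x28 band-power images.

The pipeline is: per-trial high-pass + downsample + z-score, sliding-window
segmentation, per-channel FFT band power, azimuthal-equidistant electrode
projection, Clough-Tocher interpolation onto a square grid, and per-map
min-max normalization to [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal
from scipy.interpolate import CloughTocher2DInterpolator

from .montage import ElectrodeMontage, project_montage
from .recording import EEGRecording

__all__ = [
    "DecisionWindowSpec", "FrequencyBand", "SSFMap",
    "preprocess_recording", "segment_windows", "band_power",
    "interpolate_map", "extract_ssf", "normalize_map",
    "save_maps", "load_maps", "hemifield_means", "LABEL_TO_INT", "INT_TO_LABEL",
]

LABEL_TO_INT = {"left": 0, "right": 1}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


@dataclass(frozen=True)
class DecisionWindowSpec:
    """Sliding decision-window geometry: duration in seconds and overlap
    fraction in [0, 1)."""

    length_s: float
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    def n_samples(self, fs: float) -> int:
        return int(round(self.length_s * fs))

    def step(self, fs: float) -> int:
        return max(1, int(round(self.n_samples(fs) * (1 - self.overlap))))


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval in Hz; the default is the alpha band."""

    low_hz: float = 8.0
    high_hz: float = 13.0

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass
class SSFMap:
    """A 28x28 topographic band-power image for one decision window."""

    grid: np.ndarray
    label: str | None = None
    subject_id: str = "S0"
    trial_id: str = "T0"
    window_index: int = 0
    synthetic: bool = False
    scale_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be a square 2-D array")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("non-finite values in SSF map")

    @property
    def label_int(self) -> int:
        if self.label is None:
            raise ValueError("map has no label")
        return LABEL_TO_INT[self.label]


def preprocess_recording(
    rec: EEGRecording,
    hp_cutoff_hz: float = 0.5,
    target_fs: float = 70.0,
) -> EEGRecording:
    """High-pass filter, downsample and z-score a recording per channel.

    A zero-phase 4th-order Butterworth high-pass at ``hp_cutoff_hz`` is
    applied at the native rate, the signal is polyphase-resampled to
    ``target_fs`` (anti-aliasing built in), and each channel is z-scored
    over the whole trial. A zero-variance channel is returned as all zeros
    with a warning rather than NaN.
    """
    if target_fs > rec.fs:
        raise ValueError("upsampling not supported: target_fs exceeds recording fs")
    if hp_cutoff_hz >= target_fs / 2:
        raise ValueError("hp_cutoff_hz must be below target Nyquist")
    data = rec.data
    if hp_cutoff_hz > 0:
        sos = signal.butter(4, hp_cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    if target_fs != rec.fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    flat = sd[:, 0] < 1e-15
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance channel(s) set to zeros",
            stacklevel=2,
        )
        sd[flat] = 1.0
    out = (data - mu) / sd
    out[flat] = 0.0
    return rec.copy_with(data=out, fs=float(target_fs))


def segment_windows(rec: EEGRecording, spec: DecisionWindowSpec) -> list[EEGRecording]:
    """Cut a recording into sliding decision windows.

    Window length ``L = round(length_s * fs)``; step
    ``round(L * (1 - overlap))`` (at least 1). The number of windows is
    ``floor((n_samples - L) / step) + 1``.
    """
    L = spec.n_samples(rec.fs)
    if L < 1:
        raise ValueError("window shorter than one sample")
    if L > rec.n_samples:
        raise ValueError(
            f"window of {L} samples longer than recording ({rec.n_samples})"
        )
    step = spec.step(rec.fs)
    n_win = (rec.n_samples - L) // step + 1
    return [
        rec.copy_with(data=rec.data[:, i * step : i * step + L], window_index=i)
        for i in range(n_win)
    ]


def _power_spectrum(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided per-bin power with the Parseval convention.

    Returns (freqs, p) where p sums over all bins to the mean squared
    signal; interior bins are doubled to fold in negative frequencies.
    """
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1) / n
    p = np.abs(X) ** 2
    if n % 2 == 0:
        p[..., 1:-1] *= 2.0
    else:
        p[..., 1:] *= 2.0
    return np.fft.rfftfreq(n, d=1.0), p  # d set by caller via fs scaling


def band_power(window: EEGRecording, band: FrequencyBand) -> np.ndarray:
    """Per-channel power in a frequency band.

    The FFT is normalized so that the per-bin powers sum to the
    time-domain mean square (Parseval); the band power is the sum of bins
    with ``low_hz <= f <= high_hz`` inclusive, so band powers over a
    disjoint cover of [0, fs/2] add up to the total power.
    """
    if window.n_samples < 2:
        raise ValueError("window must have at least 2 samples")
    if band.high_hz >= window.fs / 2 + 1e-9:
        raise ValueError("band exceeds Nyquist frequency")
    n = window.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / window.fs)
    _, p = _power_spectrum(window.data)
    mask = (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
    if not np.any(mask):
        raise ValueError(
            f"no FFT bins inside [{band.low_hz}, {band.high_hz}] Hz at "
            f"resolution {window.fs / n:.4f} Hz"
        )
    return p[:, mask].sum(axis=1)


def interpolate_map(
    values: np.ndarray,
    montage: ElectrodeMontage,
    grid_n: int = 28,
    fill: float = 0.0,
) -> np.ndarray:
    """Clough-Tocher interpolation of per-electrode values onto a grid.

    The grid is a regular ``grid_n x grid_n`` mesh on the square
    ``[-r, r]^2`` with ``r = 1.05 * max projected radius``. Nodes outside
    the electrode convex hull get ``fill``. Row 0 is the most positive v
    (left hemisphere for the packaged convention), columns run with u.
    """
    if montage.pos2d is None:
        raise ValueError("montage has no 2-D positions; call project_montage first")
    values = np.asarray(values, dtype=float)
    if values.shape != (len(montage),):
        raise ValueError("one value per electrode required")
    pts = montage.pos2d
    if len(pts) < 4:
        raise ValueError("need at least 4 electrodes to interpolate")
    r = 1.05 * np.max(np.linalg.norm(pts, axis=1))
    u = np.linspace(-r, r, grid_n)
    v = np.linspace(r, -r, grid_n)
    uu, vv = np.meshgrid(u, v)
    try:
        interp = CloughTocher2DInterpolator(pts, values)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"electrode triangulation failed: {exc}") from exc
    grid = interp(uu, vv)
    grid = np.where(np.isnan(grid), fill, grid)
    return grid


def normalize_map(grid: np.ndarray) -> tuple[np.ndarray, dict]:
    """Min-max scale a map to [-1, 1]; returns (scaled, scale_info).

    A constant map cannot be scaled; it is returned as all zeros with
    ``scale_info["degenerate"] = True`` so the transform stays invertible
    where defined.
    """
    vmin = float(np.min(grid))
    vmax = float(np.max(grid))
    if vmax - vmin < 1e-300:
        return np.zeros_like(grid), {"vmin": vmin, "vmax": vmax, "degenerate": True}
    scaled = 2.0 * (grid - vmin) / (vmax - vmin) - 1.0
    return scaled, {"vmin": vmin, "vmax": vmax, "degenerate": False}


def extract_ssf(
    rec: EEGRecording,
    spec: DecisionWindowSpec,
    band: FrequencyBand,
    montage: ElectrodeMontage,
    grid_n: int = 28,
    normalize: bool = True,
) -> list[SSFMap]:
    """Convert a (preprocessed) recording into a sequence of SSF maps."""
    if montage.pos2d is None:
        montage = project_montage(montage)
    if montage.names != rec.channel_names:
        if set(montage.names) == set(rec.channel_names):
            montage = montage.subset(rec.channel_names)
        else:
            raise ValueError("montage channels do not match recording channels")
    maps = []
    for win in segment_windows(rec, spec):
        power = band_power(win, band)
        grid = interpolate_map(power, montage, grid_n=grid_n)
        if normalize:
            grid, scale_info = normalize_map(grid)
        else:
            scale_info = {}
        maps.append(
            SSFMap(
                grid=grid,
                label=rec.label,
                subject_id=rec.subject_id,
                trial_id=rec.trial_id,
                window_index=win.window_index,
                scale_info=scale_info,
            )
        )
    return maps


def hemifield_means(grid: np.ndarray) -> tuple[float, float]:
    """Mean intensity of the left (top rows) and right (bottom rows)
    hemifield pixels of a map, excluding the middle if odd-sized."""
    n = grid.shape[0]
    half = n // 2
    return float(grid[:half].mean()), float(grid[-half:].mean())


def save_maps(maps: list[SSFMap], path: str | Path) -> None:
    """Write a collection of SSF maps to an HDF5 container."""
    path = Path(path)
    n = len(maps)
    if n == 0:
        raise ValueError("no maps to save")
    side = maps[0].grid.shape[0]
    arr = np.stack([m.grid for m in maps])
    labels = np.array([-1 if m.label is None else m.label_int for m in maps])
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=arr)
        f.create_dataset("labels", data=labels)
        f.create_dataset("subject_id", data=np.array([m.subject_id for m in maps], dtype=object), dtype=str_dt)
        f.create_dataset("trial_id", data=np.array([m.trial_id for m in maps], dtype=object), dtype=str_dt)
        f.create_dataset("window_index", data=np.array([m.window_index for m in maps]))
        f.create_dataset("synthetic", data=np.array([m.synthetic for m in maps], dtype=bool))
        f.attrs["side"] = side


def load_maps(path: str | Path) -> list[SSFMap]:
    """Read SSF maps back from :func:`save_maps` output."""
    with h5py.File(path, "r") as f:
        arr = f["maps"][:]
        labels = f["labels"][:]
        subjects = [s.decode() if isinstance(s, bytes) else s for s in f["subject_id"][:]]
        trials = [s.decode() if isinstance(s, bytes) else s for s in f["trial_id"][:]]
        widx = f["window_index"][:]
        synth = f["synthetic"][:]
    return [
        SSFMap(
            grid=arr[i],
            label=None if labels[i] < 0 else INT_TO_LABEL[int(labels[i])],
            subject_id=subjects[i],
            trial_id=trials[i],
            window_index=int(widx[i]),
            synthetic=bool(synth[i]),
        )
        for i in range(len(arr))
    ]
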