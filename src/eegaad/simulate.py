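"""Synthetic multichannel EEG with class-dependent alpha lateralization.

Each channel is 1/f^beta background noise (unit variance) plus an alpha
sinusoid with a random phase. The sinusoid amplitude is boosted by the
``lateralization`` factor on the hemisphere keyed to the attention label,
so the ground truth behind every generated map is known exactly. The
direction convention is configurable; by default a "left" label boosts
the left hemisphere (electrodes with y > 0 in the packaged montage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .montage import ElectrodeMontage, packaged_montage
from .recording import EEGRecording
from .ssf import DecisionWindowSpec, FrequencyBand, SSFMap, extract_ssf

__all__ = ["SimulationConfig", "simulate_recording", "make_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated recording.

    ``snr`` is the alpha-to-background power ratio of an un-boosted
    channel; ``lateralization`` is the amplitude ratio applied on the
    attended hemisphere (power scales with its square).
    """

    n_channels: int = 64
    fs: float = 70.0
    duration_s: float = 10.0
    label: str = "left"
    alpha_freq_hz: float = 10.0
    lateralization: float = 3.0
    snr: float = 5.0
    background_exponent: float = 1.0
    boost_same_side: bool = True  # label "left" boosts the left hemisphere
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lateralization < 1:
            raise ValueError("lateralization must be >= 1")
        if self.snr <= 0 or self.duration_s <= 0:
            raise ValueError("snr and duration_s must be positive")
        if not 8.0 <= self.alpha_freq_hz <= 13.0:
            raise ValueError("alpha_freq_hz must lie in [8, 13]")
        if self.label not in ("left", "right"):
            raise ValueError("label must be 'left' or 'right'")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                beta: float) -> np.ndarray:
    """Unit-variance 1/f^beta noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-beta / 2.0)
    shape[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def simulate_recording(cfg: SimulationConfig,
                       montage: ElectrodeMontage | None = None) -> EEGRecording:
    """Simulate one labeled EEG recording; deterministic given cfg.seed."""
    montage = montage or packaged_montage(cfg.n_channels)
    if len(montage) != cfg.n_channels:
        raise ValueError(
            f"montage has {len(montage)} channels, config wants {cfg.n_channels}"
        )
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    noise = _pink_noise(rng, cfg.n_channels, n, cfg.background_exponent)

    # un-boosted alpha amplitude A: A^2 / 2 = snr * background variance (=1)
    amp = np.sqrt(2.0 * cfg.snr)
    hemi = montage.hemisphere  # +1 left, -1 right, 0 midline
    attended = 1 if (cfg.label == "left") == cfg.boost_same_side else -1
    gains = np.where(hemi == attended, cfg.lateralization, 1.0)
    phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
    alpha = (amp * gains)[:, None] * np.sin(
        2 * np.pi * cfg.alpha_freq_hz * t[None, :] + phases[:, None]
    )
    return EEGRecording(
        data=noise + alpha,
        fs=cfg.fs,
        channel_names=list(montage.names),
        subject_id=f"SIM{cfg.seed}",
        trial_id=f"sim-{cfg.label}-{cfg.seed}",
        label=cfg.label,
        meta={"simulation": True, "lateralization": cfg.lateralization,
              "snr": cfg.snr},
    )


def make_dataset(
    n_per_class: int,
    cfg_template: SimulationConfig | None = None,
    window_spec: DecisionWindowSpec | None = None,
    band: FrequencyBand | None = None,
    montage: ElectrodeMontage | None = None,
    seed: int = 0,
) -> tuple[list[SSFMap], list[dict]]:
    """Build a balanced two-class SSF-map collection with a manifest.

    One recording is simulated per (class, replicate) with a distinct
    derived seed, run through the feature extractor, and every resulting
    map inherits the recording's label. The manifest records each
    recording's full ground-truth config for recovery experiments.
    """
    cfg_template = cfg_template or SimulationConfig()
    window_spec = window_spec or DecisionWindowSpec(length_s=cfg_template.duration_s, overlap=0.0)
    band = band or FrequencyBand()
    montage = montage or packaged_montage(cfg_template.n_channels)
    maps: list[SSFMap] = []
    manifest: list[dict] = []
    seq = np.random.SeedSequence(entropy=seed)
    child_seeds = seq.generate_state(2 * n_per_class)
    i = 0
    for label in ("left", "right"):
        for _ in range(n_per_class):
            cfg = replace(cfg_template, label=label, seed=int(child_seeds[i]))
            rec = simulate_recording(cfg, montage=montage)
            rec_maps = extract_ssf(rec, window_spec, band, montage)
            maps.extend(rec_maps)
            manifest.append({
                "trial_id": rec.trial_id,
                "label": label,
                "n_maps": len(rec_maps),
                "config": cfg.__dict__.copy(),
            })
            i += 1
    return maps, manifest
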