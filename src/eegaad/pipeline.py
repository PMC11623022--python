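"""End-to-end orchestration: simulate/ingest -> feature maps -> GAN ->
generate/augment -> evaluate, with a serializable run configuration.

Trials are split into train/test *before* windowing so that overlapping
training windows can never leak into the test set; every map carries its
trial provenance and the split is recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import gan
from .montage import packaged_montage
from .simulate import SimulationConfig, simulate_recording
from .ssf import (DecisionWindowSpec, FrequencyBand, SSFMap, extract_ssf,
                  preprocess_recording, save_maps)

__all__ = ["RunConfig", "run_pipeline", "augmentation_sweep", "split_trials"]


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run (YAML/JSON round-trips)."""

    # simulation
    n_trials_per_class: int = 10
    trial_duration_s: float = 20.0
    n_channels: int = 64
    lateralization: float = 3.0
    snr: float = 5.0
    alpha_freq_hz: float = 10.0
    background_exponent: float = 1.0
    # preprocessing
    hp_cutoff_hz: float = 0.5
    target_fs: float = 70.0
    raw_fs: float = 140.0
    # windowing: training windows overlap, test windows do not
    window_s: float = 2.0
    train_overlap: float = 0.5
    test_overlap: float = 0.0
    band_low_hz: float = 8.0
    band_high_hz: float = 13.0
    # split
    train_fraction: float = 0.8
    # GAN
    epochs: int = 5
    batch_size: int = 8
    lr_generator: float = 2e-4
    lr_discriminator: float = 1e-4
    width_scale: int = 8
    n_generated: int = 32
    # evaluation
    noise_levels: tuple = ev.NOISE_LEVELS
    seed: int = 0

    def train_config(self) -> gan.TrainConfig:
        return gan.TrainConfig(
            lr_generator=self.lr_generator,
            lr_discriminator=self.lr_discriminator,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
        )

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        doc = asdict(self)
        doc["noise_levels"] = list(doc["noise_levels"])
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "noise_levels" in doc:
            doc["noise_levels"] = tuple(doc["noise_levels"])
        return cls(**doc)


def split_trials(trials: list, train_fraction: float,
                 rng: np.random.Generator) -> tuple[list, list]:
    """Shuffle trials within each class and split by ``train_fraction``.

    The split unit is the whole trial, so no window from a test trial can
    share samples with a training window.
    """
    by_label: dict = {}
    for t in trials:
        by_label.setdefault(t.label, []).append(t)
    train, test = [], []
    for label in sorted(by_label):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    return train, test


def _simulate_trials(cfg: RunConfig, rng: np.random.Generator) -> list:
    montage = packaged_montage(cfg.n_channels)
    trials = []
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_trials_per_class + 1)[1:]
    i = 0
    for label in ("left", "right"):
        for _ in range(cfg.n_trials_per_class):
            sim = SimulationConfig(
                n_channels=cfg.n_channels, fs=cfg.raw_fs,
                duration_s=cfg.trial_duration_s, label=label,
                alpha_freq_hz=cfg.alpha_freq_hz,
                lateralization=cfg.lateralization, snr=cfg.snr,
                background_exponent=cfg.background_exponent,
                seed=int(seeds[i]),
            )
            rec = simulate_recording(sim, montage=montage)
            trials.append(rec.copy_with(trial_id=f"{label}-{i:03d}"))
            i += 1
    return trials


def _extract(trials: list, cfg: RunConfig, overlap: float) -> list[SSFMap]:
    montage = packaged_montage(cfg.n_channels)
    spec = DecisionWindowSpec(length_s=cfg.window_s, overlap=overlap)
    band = FrequencyBand(cfg.band_low_hz, cfg.band_high_hz)
    maps: list[SSFMap] = []
    for rec in trials:
        pre = preprocess_recording(rec, cfg.hp_cutoff_hz, cfg.target_fs)
        maps.extend(extract_ssf(pre, spec, band, montage))
    return maps


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run the full workflow and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "config.yaml")
    rng = np.random.default_rng(config.seed)

    trials = _simulate_trials(config, rng)
    train_trials, test_trials = split_trials(trials, config.train_fraction, rng)
    train_maps = _extract(train_trials, config, config.train_overlap)
    test_maps = _extract(test_trials, config, config.test_overlap)
    save_maps(train_maps, outdir / "train_maps.h5")
    save_maps(test_maps, outdir / "test_maps.h5")

    gen_spec = gan.GeneratorSpec(width_scale=config.width_scale)
    disc_spec = gan.DiscriminatorSpec(width_scale=config.width_scale)
    gen, disc, history = gan.train(
        train_maps, config.train_config(), gen_spec, disc_spec,
        log_path=outdir / "training_log.csv",
    )
    gan.save_checkpoint(outdir / "checkpoint", gen, disc, config.train_config(), history)

    generated = gan.generate(gen, config.n_generated,
                             seed=np.random.default_rng(config.seed + 1))
    save_maps(generated, outdir / "generated_maps.h5")

    preds, _ = gan.classify(disc, test_maps)
    truth = np.array([m.label_int for m in test_maps])
    rep = ev.classification_metrics(
        ev.confusion_from_predictions(preds, truth, positive=0)
    )
    pd.DataFrame([asdict(rep)]).to_csv(outdir / "classification_metrics.csv", index=False)

    sim = ev.similarity_metrics(train_maps, generated)
    pd.DataFrame([asdict(sim)]).to_csv(outdir / "similarity_metrics.csv", index=False)

    curve = ev.robustness_curve(disc, test_maps, levels=config.noise_levels,
                                seed=config.seed)
    curve.to_csv(outdir / "robustness_curve.csv", index=False)

    manifest = {
        "n_train_maps": len(train_maps),
        "n_test_maps": len(test_maps),
        "train_trials": sorted(t.trial_id for t in train_trials),
        "test_trials": sorted(t.trial_id for t in test_trials),
        "test_accuracy": rep.accuracy,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def augmentation_sweep(
    config: RunConfig,
    generated_counts: list[int],
    real_fractions: list[float],
    classifier_epochs: int = 10,
) -> pd.DataFrame:
    """Accuracy grid over (real-data fraction x generated-sample count).

    For each real fraction a GAN is trained on that subset; classifiers
    are then fit on the real subset plus the requested number of generated
    maps and scored on the held-out test maps. The zero-generated rows are
    the un-augmented baselines.
    """
    rng = np.random.default_rng(config.seed)
    trials = _simulate_trials(config, rng)
    train_trials, test_trials = split_trials(trials, config.train_fraction, rng)
    train_maps = _extract(train_trials, config, config.train_overlap)
    test_maps = _extract(test_trials, config, config.test_overlap)
    truth = np.array([m.label_int for m in test_maps])
    disc_spec = gan.DiscriminatorSpec(width_scale=config.width_scale)
    gen_spec = gan.GeneratorSpec(width_scale=config.width_scale)

    rows = []
    for frac in real_fractions:
        sub_rng = np.random.default_rng((config.seed, int(frac * 1000)))
        y = np.array([m.label_int for m in train_maps])
        keep: list[int] = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            n_keep = max(2, int(round(frac * len(idx))))
            keep.extend(sub_rng.permutation(idx)[:n_keep])
        subset = [train_maps[i] for i in sorted(keep)]
        gen, _, _ = gan.train(subset, config.train_config(), gen_spec, disc_spec)
        for count in generated_counts:
            aug = list(subset)
            if count > 0:
                aug += gan.generate(gen, count, seed=np.random.default_rng(
                    (config.seed, int(frac * 1000), count)))
            clf = gan.fit_classifier(aug, disc_spec, epochs=classifier_epochs,
                                     seed=config.seed)
            preds, _ = gan.classify(clf, test_maps)
            rows.append({
                "real_fraction": frac,
                "n_real": len(subset),
                "n_generated": count,
                "accuracy": float(np.mean(preds == truth)),
            })
    return pd.DataFrame(rows)
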