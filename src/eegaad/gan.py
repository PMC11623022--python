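"""Auxiliary-classifier GAN over 28x28 feature maps.

The generator maps a 100-dim uniform(-1, 1) latent vector, gated by a
learned per-class embedding, through a dense + transposed-convolution
stack to a tanh image. The discriminator shares a strided-convolution
trunk between a real/fake sigmoid head and a left/right softmax head.
Channel widths can be divided by ``width_scale`` for desk-scale runs; at
``width_scale=1`` the per-layer parameter counts are the reference ones.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .ssf import INT_TO_LABEL, LABEL_TO_INT, SSFMap

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "TrainConfig", "LossBreakdown",
    "Generator", "Discriminator", "build_generator", "build_discriminator",
    "condition_latent", "source_loss", "class_loss",
    "train", "generate", "classify", "save_checkpoint", "load_checkpoint",
]

EPS = 1e-7  # probability clamp in both losses


@dataclass(frozen=True)
class GeneratorSpec:
    """Generator architecture; defaults reproduce the reference layer
    parameter counts (FC 1,266,944; transposed convs 819,328 / 73,792 /
    18,464 / 289)."""

    latent_dim: int = 100
    n_classes: int = 2
    base_channels: int = 256      # channels after the dense reshape (7x7)
    first_kernel: int = 5
    kernel: int = 3
    dropout: float = 0.4
    width_scale: int = 1

    def channels(self) -> list[int]:
        s = self.width_scale
        return [max(1, c // s) for c in (self.base_channels,
                                         self.base_channels // 2,
                                         self.base_channels // 4,
                                         self.base_channels // 8)]


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Discriminator architecture; defaults reproduce the reference
    counts (convs 640 / 73,856 / 295,168 / 1,180,160; source head 8,193)."""

    n_classes: int = 2
    base_channels: int = 64
    kernel: int = 3
    leaky_slope: float = 0.2
    dropout: float = 0.25
    width_scale: int = 1

    def channels(self) -> list[int]:
        s = self.width_scale
        return [max(1, c // s) for c in (self.base_channels,
                                         self.base_channels * 2,
                                         self.base_channels * 4,
                                         self.base_channels * 8)]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults follow the best reported row
    (generator lr 2e-4, discriminator lr 1e-4, batch 8, 200 epochs)."""

    lr_generator: float = 2e-4
    lr_discriminator: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_generator, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class LossBreakdown:
    """Per-epoch mean loss components for both players."""

    epoch: int
    d_source: float
    d_class: float
    g_source: float
    g_class: float
    wall_time_s: float = 0.0

    def as_row(self) -> list:
        return [self.epoch, self.d_source, self.d_class,
                self.g_source, self.g_class, self.wall_time_s]


class Generator:
    """Class-conditional image generator: latent * embedding -> 28x28x1."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        c0, c1, c2, c3 = spec.channels()
        # multiplicative class gates around 1 with anti-correlated offsets,
        # so conditioning has a coherent direction from the first epoch
        offsets = rng.standard_normal((1, spec.latent_dim))
        signs = np.linspace(1.0, -1.0, spec.n_classes)[:, None]
        self.embedding = 1.0 + 0.5 * signs * offsets
        self.d_embedding = np.zeros_like(self.embedding)
        self.net = nn.Sequential([
            nn.Dense(spec.latent_dim, 7 * 7 * c0, rng=rng),
            nn.BatchNorm(7 * 7 * c0),
            nn.ReLU(),
            nn.Reshape((7, 7, c0)),
            nn.Dropout(spec.dropout),
            nn.ConvTranspose2D(c0, c1, spec.first_kernel, rng=rng),
            nn.BatchNorm(c1),
            nn.ReLU(),
            nn.Upsample2x(),
            nn.ConvTranspose2D(c1, c2, spec.kernel, rng=rng),
            nn.BatchNorm(c2),
            nn.ReLU(),
            nn.Upsample2x(),
            nn.ConvTranspose2D(c2, c3, spec.kernel, rng=rng),
            nn.BatchNorm(c3),
            nn.ReLU(),
            nn.ConvTranspose2D(c3, 1, spec.kernel, rng=rng),
            nn.Tanh(),
        ])
        self.net.set_rng(rng)

    def forward(self, latent: np.ndarray, labels: np.ndarray, train: bool = True) -> np.ndarray:
        self._latent = latent
        self._labels = labels
        cond = condition_latent(latent, labels, self.embedding)
        return self.net.forward(cond, train=train)

    def backward(self, grad: np.ndarray) -> None:
        gcond = self.net.backward(grad)
        self.d_embedding[...] = 0.0
        np.add.at(self.d_embedding, self._labels, gcond * self._latent)

    def params(self) -> list[np.ndarray]:
        return [self.embedding] + self.net.params()

    def grads(self) -> list[np.ndarray]:
        return [self.d_embedding] + self.net.grads()

    def layer_param_counts(self) -> list[tuple[str, int]]:
        out = []
        for layer in self.net.layers:
            out.append((type(layer).__name__, layer.param_count()))
        return out

    def sample_latent(self, count: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-1.0, 1.0, size=(count, self.spec.latent_dim))


class Discriminator:
    """Shared conv trunk with a real/fake head and an auxiliary class head."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        c1, c2, c3, c4 = spec.channels()
        k, a, p = spec.kernel, spec.leaky_slope, spec.dropout
        self.trunk = nn.Sequential([
            nn.Conv2D(1, c1, k, stride=2, rng=rng), nn.LeakyReLU(a), nn.Dropout(p),
            nn.Conv2D(c1, c2, k, stride=2, rng=rng), nn.LeakyReLU(a), nn.Dropout(p),
            nn.Conv2D(c2, c3, k, stride=2, rng=rng), nn.LeakyReLU(a), nn.Dropout(p),
            nn.Conv2D(c3, c4, k, stride=1, rng=rng), nn.LeakyReLU(a), nn.Dropout(p),
            nn.Flatten(),
        ])
        self.flat_dim = 4 * 4 * c4
        self.source_head = nn.Dense(self.flat_dim, 1, rng=rng)
        self.source_act = nn.Sigmoid()
        self.class_head = nn.Dense(self.flat_dim, spec.n_classes, rng=rng)
        self.class_act = nn.Softmax()
        self.trunk.set_rng(rng)

    def forward(self, x: np.ndarray, train: bool = True) -> tuple[np.ndarray, np.ndarray]:
        h = self.trunk.forward(x, train=train)
        p_source = self.source_act.forward(self.source_head.forward(h, train=train))[:, 0]
        p_class = self.class_act.forward(self.class_head.forward(h, train=train))
        return p_source, p_class

    def backward(self, g_source: np.ndarray, g_class: np.ndarray) -> np.ndarray:
        gh = self.source_head.backward(self.source_act.backward(g_source[:, None]))
        gh += self.class_head.backward(self.class_act.backward(g_class))
        return self.trunk.backward(gh)

    def params(self) -> list[np.ndarray]:
        return self.trunk.params() + self.source_head.params() + self.class_head.params()

    def grads(self) -> list[np.ndarray]:
        return self.trunk.grads() + self.source_head.grads() + self.class_head.grads()

    def layer_param_counts(self) -> list[tuple[str, int]]:
        out = [(type(layer).__name__, layer.param_count()) for layer in self.trunk.layers]
        out.append(("SourceHead", self.source_head.param_count()))
        out.append(("ClassHead", self.class_head.param_count()))
        return out


def build_generator(spec: GeneratorSpec | None = None,
                    rng: np.random.Generator | int | None = None) -> Generator:
    """Construct a generator; validates the output shape on a probe batch."""
    spec = spec or GeneratorSpec()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    gen = Generator(spec, rng)
    probe = gen.forward(np.zeros((1, spec.latent_dim)), np.zeros(1, dtype=int), train=False)
    if probe.shape != (1, 28, 28, 1):
        raise ValueError(f"generator produced shape {probe.shape}, expected (1, 28, 28, 1)")
    return gen


def build_discriminator(spec: DiscriminatorSpec | None = None,
                        rng: np.random.Generator | int | None = None) -> Discriminator:
    """Construct a discriminator; validates head shapes on a probe batch."""
    spec = spec or DiscriminatorSpec()
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    disc = Discriminator(spec, rng)
    ps, pc = disc.forward(np.zeros((1, 28, 28, 1)), train=False)
    if ps.shape != (1,) or pc.shape != (1, spec.n_classes):
        raise ValueError("discriminator head shape mismatch")
    return disc


def condition_latent(latent: np.ndarray, labels: np.ndarray,
                     embedding: np.ndarray) -> np.ndarray:
    """Gate latent vectors by their class embedding, element-wise.

    Keeps the conditioned vector at the latent dimension, so the first
    dense layer's parameter count is unchanged by conditioning.
    """
    latent = np.atleast_2d(latent)
    labels = np.asarray(labels, dtype=int)
    if np.any(labels < 0) or np.any(labels >= embedding.shape[0]):
        raise ValueError("unknown label index")
    return latent * embedding[labels]


def source_loss(real_probs: np.ndarray, fake_probs: np.ndarray) -> float:
    """Real/fake discrimination loss (negated log-likelihood).

    ``-[mean log p_real + mean log (1 - p_fake)]`` with probabilities
    clamped to [EPS, 1 - EPS]; zero only at perfect discrimination.
    """
    pr = np.clip(np.asarray(real_probs, dtype=float), EPS, 1 - EPS)
    pf = np.clip(np.asarray(fake_probs, dtype=float), EPS, 1 - EPS)
    return float(-(np.mean(np.log(pr)) + np.mean(np.log(1.0 - pf))))


def class_loss(class_probs: np.ndarray, true_labels: np.ndarray) -> float:
    """Cross-entropy of the auxiliary class head against true labels."""
    p = np.clip(np.asarray(class_probs, dtype=float), EPS, 1 - EPS)
    y = np.asarray(true_labels, dtype=int)
    return float(-np.mean(np.log(p[np.arange(len(y)), y])))


def _maps_to_arrays(maps: list[SSFMap]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([m.grid for m in maps])[..., None]
    y = np.array([m.label_int for m in maps], dtype=int)
    return X, y


def train(
    maps: list[SSFMap],
    config: TrainConfig | None = None,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    log_path: str | Path | None = None,
) -> tuple[Generator, Discriminator, list[LossBreakdown]]:
    """Adversarial training of the generator/discriminator pair.

    Each step: (1) generate a fake batch with sampled labels, (2) mix it
    with a real batch, (3) update the discriminator on the source + class
    losses with the generator frozen, then (4) update the generator on
    class loss minus source credit with the discriminator frozen.
    Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    gen_spec = gen_spec or GeneratorSpec()
    disc_spec = disc_spec or DiscriminatorSpec()
    X, y = _maps_to_arrays(maps)
    counts = np.bincount(y, minlength=2)
    if np.any(counts < 2):
        raise ValueError("need at least 2 maps per class for training")
    if np.min(X) < -1 - 1e-9 or np.max(X) > 1 + 1e-9:
        raise ValueError("maps must be normalized to [-1, 1]")

    rng = np.random.default_rng(config.seed)
    gen = build_generator(gen_spec, rng)
    disc = build_discriminator(disc_spec, rng)
    opt_d = nn.Adam(disc.params(), lr=config.lr_discriminator,
                    beta1=config.beta1, beta2=config.beta2)
    opt_g = nn.Adam(gen.params(), lr=config.lr_generator,
                    beta1=config.beta1, beta2=config.beta2)

    n = len(X)
    B = min(config.batch_size, n)
    history: list[LossBreakdown] = []
    writer = None
    if log_path is not None:
        log_file = open(log_path, "w", newline="")
        writer = csv.writer(log_file)
        writer.writerow(["epoch", "L_source_D", "L_class_D", "L_source_G",
                         "L_class_G", "wall_time_s"])
    t0 = time.perf_counter()
    try:
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            ep = np.zeros(4)
            n_batches = 0
            for start in range(0, n - B + 1, B):
                idx = order[start : start + B]
                x_real, y_real = X[idx], y[idx]

                # --- discriminator step (generator frozen) ---
                z = gen.sample_latent(B, rng)
                y_fake = rng.integers(0, 2, size=B)
                x_fake = gen.forward(z, y_fake, train=True)
                x_mix = np.concatenate([x_real, x_fake])
                y_mix = np.concatenate([y_real, y_fake])
                ps, pc = disc.forward(x_mix, train=True)
                ls = source_loss(ps[:B], ps[B:])
                lc = class_loss(pc, y_mix)
                if not np.isfinite(ls + lc):
                    raise FloatingPointError(
                        f"non-finite discriminator loss at epoch {epoch}"
                    )
                psc = np.clip(ps, EPS, 1 - EPS)
                g_source = np.concatenate([
                    -1.0 / (B * psc[:B]),
                    1.0 / (B * (1.0 - psc[B:])),
                ])
                pcc = np.clip(pc, EPS, 1 - EPS)
                g_class = np.zeros_like(pc)
                g_class[np.arange(2 * B), y_mix] = -1.0 / (2 * B * pcc[np.arange(2 * B), y_mix])
                disc.backward(g_source, g_class)
                opt_d.step(disc.grads())

                # --- generator step (discriminator frozen) ---
                z = gen.sample_latent(B, rng)
                y_fake = rng.integers(0, 2, size=B)
                x_fake = gen.forward(z, y_fake, train=True)
                ps_f, pc_f = disc.forward(x_fake, train=True)
                psc_f = np.clip(ps_f, EPS, 1 - EPS)
                lg_source = float(np.mean(np.log(1.0 - psc_f)))
                lg_class = class_loss(pc_f, y_fake)
                if not np.isfinite(lg_source + lg_class):
                    raise FloatingPointError(
                        f"non-finite generator loss at epoch {epoch}"
                    )
                # minimize class CE + log(1 - p_fake): the negation of the
                # generator's maximized class-minus-source log-likelihood
                g_source_f = -1.0 / (B * (1.0 - psc_f))
                pcc_f = np.clip(pc_f, EPS, 1 - EPS)
                g_class_f = np.zeros_like(pc_f)
                g_class_f[np.arange(B), y_fake] = -1.0 / (B * pcc_f[np.arange(B), y_fake])
                dx = disc.backward(g_source_f, g_class_f)
                gen.backward(dx)
                opt_g.step(gen.grads())

                ep += [ls, lc, lg_source, lg_class]
                n_batches += 1
            ep /= max(n_batches, 1)
            entry = LossBreakdown(epoch, *ep, wall_time_s=time.perf_counter() - t0)
            history.append(entry)
            if writer is not None:
                writer.writerow(entry.as_row())
    finally:
        if writer is not None:
            log_file.close()
    return gen, disc, history


def fit_classifier(
    maps: list[SSFMap],
    disc_spec: DiscriminatorSpec | None = None,
    epochs: int = 10,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
) -> Discriminator:
    """Train the discriminator's auxiliary class head alone (supervised).

    Used when only the left/right classifier is needed — cross-validation
    folds, recovery experiments — without the adversarial loop.
    """
    disc_spec = disc_spec or DiscriminatorSpec()
    rng = np.random.default_rng(seed)
    disc = build_discriminator(disc_spec, rng)
    X, y = _maps_to_arrays(maps)
    opt = nn.Adam(disc.params(), lr=lr)
    n = len(X)
    B = min(batch_size, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n - B + 1, B):
            idx = order[start : start + B]
            _, pc = disc.forward(X[idx], train=True)
            pcc = np.clip(pc, EPS, 1 - EPS)
            g_class = np.zeros_like(pc)
            g_class[np.arange(len(idx)), y[idx]] = -1.0 / (len(idx) * pcc[np.arange(len(idx)), y[idx]])
            disc.backward(np.zeros(len(idx)), g_class)
            opt.step(disc.grads())
    return disc


def generate(gen: Generator, count: int, labels=None,
             seed: int | np.random.Generator = 0) -> list[SSFMap]:
    """Draw class-conditional samples from the generator (eval mode)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = np.arange(count) % gen.spec.n_classes
    labels = np.asarray(labels, dtype=int)
    if len(labels) != count:
        raise ValueError("labels length must equal count")
    if np.any(labels < 0) or np.any(labels >= gen.spec.n_classes):
        raise ValueError("unknown label")
    z = gen.sample_latent(count, rng)
    imgs = gen.forward(z, labels, train=False)
    return [
        SSFMap(grid=imgs[i, :, :, 0], label=INT_TO_LABEL[int(labels[i])],
               subject_id="GAN", trial_id="GAN", window_index=i, synthetic=True)
        for i in range(count)
    ]


def classify(disc: Discriminator, maps: list[SSFMap] | np.ndarray,
             batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Left/right prediction from the auxiliary head (eval mode).

    Returns (labels, probabilities); ties break toward class 0 ("left").
    """
    if isinstance(maps, np.ndarray):
        X = maps if maps.ndim == 4 else maps[..., None]
    else:
        X = np.stack([m.grid for m in maps])[..., None]
    probs = []
    for start in range(0, len(X), batch_size):
        _, pc = disc.forward(X[start : start + batch_size], train=False)
        probs.append(pc)
    probs = np.concatenate(probs)
    # argmax returns the first maximum, i.e. class 0 on exact ties
    return probs.argmax(axis=1), probs


def save_checkpoint(path: str | Path, gen: Generator, disc: Discriminator,
                    config: TrainConfig, history: list[LossBreakdown]) -> None:
    """Write weights (npz) plus a JSON manifest into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "generator.npz", *gen.params())
    np.savez(path / "discriminator.npz", *disc.params())
    manifest = {
        "generator_spec": asdict(gen.spec),
        "discriminator_spec": asdict(disc.spec),
        "config": asdict(config),
        "epochs_trained": len(history),
        "final_losses": asdict(history[-1]) if history else None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> tuple[Generator, Discriminator, TrainConfig]:
    """Restore models and config written by :func:`save_checkpoint`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    gen = build_generator(GeneratorSpec(**manifest["generator_spec"]))
    disc = build_discriminator(DiscriminatorSpec(**manifest["discriminator_spec"]))
    for model, fn in ((gen, "generator.npz"), (disc, "discriminator.npz")):
        with np.load(path / fn) as arch:
            for p, key in zip(model.params(), arch.files):
                p[...] = arch[key]
    return gen, disc, TrainConfig(**manifest["config"])
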