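"""Evaluation battery: classification metrics, generated-image similarity,
noise-robustness curves, classical augmentation baselines, McNemar's test
and intra-subject cross-validation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .ssf import SSFMap

__all__ = [
    "ConfusionCounts", "MetricReport", "classification_metrics",
    "confusion_from_predictions", "SimilarityReport", "similarity_metrics",
    "NoiseSpec", "perturb", "to_intensity", "from_intensity",
    "robustness_curve", "traditional_augment", "mcnemar",
    "crossval_intra_subject", "ROTATION_ANGLES", "SCALE_FACTOR",
]

ROTATION_ANGLES = (45.0, 90.0, 135.0, 180.0, 220.0)
SCALE_FACTOR = 0.85
NOISE_LEVELS = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0)


# ---------------------------------------------------------------- metrics

@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for a designated positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    f_score: float
    accuracy: float
    degenerate: bool = False


def confusion_from_predictions(pred, truth, positive: int = 0) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    pp = pred == positive
    tp = truth == positive
    return ConfusionCounts(
        tp=int(np.sum(pp & tp)), fp=int(np.sum(pp & ~tp)),
        fn=int(np.sum(~pp & tp)), tn=int(np.sum(~pp & ~tp)),
    )


def classification_metrics(counts: ConfusionCounts) -> MetricReport:
    """Precision, recall, F-score and total accuracy from confusion counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    F = 2*precision*recall/(precision+recall);
    accuracy = sum of per-class true positives / total items
    (= (TP+TN)/total in the binary case). A zero denominator yields 0
    with the ``degenerate`` flag set.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f_score, degenerate = 0.0, True
    else:
        f_score = 2 * precision * recall / (precision + recall)
    accuracy = (counts.tp + counts.tn) / counts.total
    return MetricReport(precision, recall, f_score, accuracy, degenerate)


# ----------------------------------------------------- similarity metrics

@dataclass(frozen=True)
class SimilarityReport:
    """Distance/correlation/divergence between real and generated maps."""

    ed: float
    pcc: float
    kld: float

    def __post_init__(self) -> None:
        if self.ed < 0 or self.kld < -1e-12 or not -1 - 1e-9 <= self.pcc <= 1 + 1e-9:
            raise ValueError("similarity metrics out of range")


def _class_means(maps: list[SSFMap]) -> dict:
    by_class: dict = {}
    for m in maps:
        by_class.setdefault(m.label, []).append(m.grid)
    return {k: np.mean(v, axis=0) for k, v in sorted(by_class.items(), key=lambda kv: str(kv[0]))}


def similarity_metrics(real: list[SSFMap], generated: list[SSFMap],
                       n_bins: int = 64, eps: float = 1e-8) -> SimilarityReport:
    """Compare generated maps to real ones.

    ED: Euclidean distance between per-class mean images, averaged over
    classes and divided by the pixel count. PCC: Pearson correlation of
    the flattened per-class mean images, averaged. KLD: Kullback-Leibler
    divergence of pooled ``n_bins``-bin intensity histograms
    (real || generated) with epsilon smoothing.
    """
    if not real or not generated:
        raise ValueError("both map sets must be non-empty")
    if real[0].grid.shape != generated[0].grid.shape:
        raise ValueError("map shape mismatch")
    means_r = _class_means(real)
    means_g = _class_means(generated)
    classes = sorted(set(means_r) & set(means_g), key=str)
    if not classes:
        raise ValueError("no common classes between real and generated sets")
    n_pix = real[0].grid.size
    eds, pccs = [], []
    for c in classes:
        diff = means_r[c] - means_g[c]
        eds.append(np.linalg.norm(diff) / n_pix)
        a, b = means_r[c].ravel(), means_g[c].ravel()
        if a.std() == 0 or b.std() == 0:
            pccs.append(1.0 if np.allclose(a, b - (b.mean() - a.mean())) else 0.0)
        else:
            pccs.append(float(np.corrcoef(a, b)[0, 1]))
    all_r = np.concatenate([m.grid.ravel() for m in real])
    all_g = np.concatenate([m.grid.ravel() for m in generated])
    lo = min(all_r.min(), all_g.min())
    hi = max(all_r.max(), all_g.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(all_r, bins=edges)[0].astype(float) + eps
    q = np.histogram(all_g, bins=edges)[0].astype(float) + eps
    p /= p.sum()
    q /= q.sum()
    kld = float(np.sum(p * np.log(p / q)))
    return SimilarityReport(ed=float(np.mean(eds)), pcc=float(np.mean(pccs)),
                            kld=max(kld, 0.0))


# ------------------------------------------------------ noise perturbation

@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative level n and additive Gaussian level m on the
    [0, 255] intensity scale."""

    n: float = 0.5
    m: float = 1.0
    seed: int = 0


def to_intensity(grid: np.ndarray) -> np.ndarray:
    """[-1, 1] map -> [0, 255] intensity image."""
    return (np.asarray(grid) + 1.0) * 127.5


def from_intensity(img: np.ndarray) -> np.ndarray:
    """[0, 255] intensity image -> [-1, 1] map."""
    return np.asarray(img) / 127.5 - 1.0


def perturb(image: np.ndarray, spec: NoiseSpec,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Corrupt an intensity image: ``n*X + m*randn``, clipped to [0, 255].

    The Gaussian field is drawn per actual pixel grid (single channel
    here), one draw per pixel, seeded via ``spec.seed`` unless an rng is
    passed in.
    """
    rng = rng or np.random.default_rng(spec.seed)
    image = np.asarray(image, dtype=float)
    noisy = spec.n * image + spec.m * rng.standard_normal(image.shape)
    return np.clip(noisy, 0.0, 255.0)


def robustness_curve(disc, maps: list[SSFMap], levels=NOISE_LEVELS,
                     n: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Classification accuracy on the same test set at increasing additive
    noise levels; the m=0 row is the clean, unperturbed accuracy."""
    from .gan import classify

    truth = np.array([m.label_int for m in maps])
    rows = []
    preds, _ = classify(disc, maps)
    rows.append({"m": 0.0, "accuracy": float(np.mean(preds == truth))})
    for m_level in levels:
        rng = np.random.default_rng((seed, int(m_level * 1000)))
        spec = NoiseSpec(n=n, m=m_level, seed=seed)
        X = np.stack([
            from_intensity(perturb(to_intensity(sm.grid), spec, rng=rng))
            for sm in maps
        ])
        preds, _ = classify(disc, X)
        rows.append({"m": float(m_level), "accuracy": float(np.mean(preds == truth))})
    return pd.DataFrame(rows)


# ------------------------------------------------- classical augmentation

def _rotate(grid: np.ndarray, angle: float) -> np.ndarray:
    return ndimage.rotate(grid, angle, reshape=False, order=0, mode="constant", cval=0.0)


def _scale(grid: np.ndarray, factor: float = SCALE_FACTOR) -> np.ndarray:
    small = ndimage.zoom(grid, factor, order=0, mode="constant", cval=0.0)
    n = grid.shape[0]
    out = np.zeros_like(grid)
    k = small.shape[0]
    if k > n:
        small = small[:n, :n]
        k = n
    lo = (n - k) // 2
    out[lo : lo + k, lo : lo + small.shape[1]] = small
    return out


def traditional_augment(maps: list[SSFMap], mode: str = "both") -> list[SSFMap]:
    """Rotation/scaling augmentation with nearest-neighbour resampling.

    ``rotate``: five copies per map at 45/90/135/180/220 degrees.
    ``scale``: one copy zoomed by 0.85 and centre-padded back.
    ``both``: the originals plus all rotated and scaled copies.
    Labels and shapes are never altered.
    """
    if mode not in ("rotate", "scale", "both"):
        raise ValueError("mode must be rotate, scale or both")
    out: list[SSFMap] = []
    if mode == "both":
        out.extend(maps)
    for m in maps:
        if mode in ("rotate", "both"):
            for angle in ROTATION_ANGLES:
                out.append(SSFMap(grid=_rotate(m.grid, angle), label=m.label,
                                  subject_id=m.subject_id, trial_id=m.trial_id,
                                  window_index=m.window_index, synthetic=m.synthetic))
        if mode in ("scale", "both"):
            out.append(SSFMap(grid=_scale(m.grid), label=m.label,
                              subject_id=m.subject_id, trial_id=m.trial_id,
                              window_index=m.window_index, synthetic=m.synthetic))
    return out


# --------------------------------------------------------- McNemar's test

def mcnemar(pred_a, pred_b, truth) -> tuple[float, float]:
    """Paired McNemar test on two classifiers' correctness patterns.

    Uses the exact two-sided binomial test when the discordant count
    b + c < 25, otherwise the continuity-corrected chi-square. Returns
    (statistic, p_value); with no discordant pairs p = 1.0.
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    truth = np.asarray(truth)
    if not pred_a.shape == pred_b.shape == truth.shape:
        raise ValueError("prediction vectors must have equal length")
    ok_a = pred_a == truth
    ok_b = pred_b == truth
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    if b + c == 0:
        return 0.0, 1.0
    table = np.array([[int(np.sum(ok_a & ok_b)), b],
                      [c, int(np.sum(~ok_a & ~ok_b))]])
    exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# --------------------------------------------------- intra-subject 5-fold

def crossval_intra_subject(
    maps_by_subject: dict[str, list[SSFMap]],
    train_fn,
    predict_fn,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation run independently per subject.

    ``train_fn(maps, seed) -> model`` and ``predict_fn(model, maps) ->
    int labels`` plug in the classifier. Returns one row per subject with
    fold-averaged precision/recall/F-score/accuracy.
    """
    rows = []
    for subject, maps in maps_by_subject.items():
        y = np.array([m.label_int for m in maps])
        if np.any(np.bincount(y, minlength=2) < k):
            raise ValueError(f"subject {subject}: need >= {k} maps per class")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_metrics = []
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            model = train_fn([maps[i] for i in tr], seed + fold)
            preds = np.asarray(predict_fn(model, [maps[i] for i in te]))
            rep = classification_metrics(
                confusion_from_predictions(preds, y[te], positive=0)
            )
            fold_metrics.append([rep.precision, rep.recall, rep.f_score, rep.accuracy])
        avg = np.mean(fold_metrics, axis=0)
        rows.append({"subject": subject, "precision": avg[0], "recall": avg[1],
                     "f_score": avg[2], "accuracy": avg[3]})
    return pd.DataFrame(rows)
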