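"""Segmentation metrics, confidence flagging and the robustness harness.

Per-class Jaccard ``JC = tp / (tp + fp + fn)`` and Dice
``DSC = 2 tp / (2 tp + fp + fn)`` are computed from pixel confusion
counts.  For dataset-level numbers, counts are pooled over all images
before the division (per-image averaging is available as an option); a
class whose union is empty (absent from both masks) is excluded from
class means.  Image-level segmentation confidence is the mean softmax
margin (top-1 minus top-2 class probability), with a review flag when a
test image falls below the 5th percentile of validation confidences.
The perturbation harness applies Gaussian noise, salt-and-pepper noise
and Gaussian blur at controlled severities and re-scores the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantom import SegmentationSample
from .stem import StemConfig

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PerturbationSpec",
    "TABLE3_SPECS",
    "confusion_counts",
    "jaccard",
    "dsc",
    "pixel_accuracy",
    "mean_metrics",
    "evaluate_model",
    "confidence_score",
    "calibrate_flag_threshold",
    "flag",
    "perturb",
    "robustness_sweep",
]


@dataclass
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative pixels."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    @classmethod
    def zeros(cls, n_classes: int = 5) -> "ConfusionCounts":
        z = np.zeros(n_classes, dtype=np.int64)
        return cls(z.copy(), z.copy(), z.copy())


@dataclass
class MetricsReport:
    per_class_jc: np.ndarray  # NaN where the class union is empty
    per_class_dsc: np.ndarray
    mean_jc: float
    mean_dsc: float
    pixel_accuracy: float
    confidence: float | None = None
    flagged: bool | None = None


def confusion_counts(pred: np.ndarray, true: np.ndarray, n_classes: int = 5) -> ConfusionCounts:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    if pred.min() < 0 or pred.max() >= n_classes or true.min() < 0 or true.max() >= n_classes:
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    cm = np.bincount(
        (true.ravel() * n_classes + pred.ravel()).astype(np.int64),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)
    tp = np.diag(cm).astype(np.int64)
    fn = cm.sum(axis=1) - tp  # true class c, predicted otherwise
    fp = cm.sum(axis=0) - tp  # predicted c, true otherwise
    return ConfusionCounts(tp.copy(), fp, fn)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(len(num), np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def jaccard(counts: ConfusionCounts, cls: int | None = None):
    jc = _safe_ratio(counts.tp.astype(float), (counts.tp + counts.fp + counts.fn).astype(float))
    return jc if cls is None else float(jc[cls])


def dsc(counts: ConfusionCounts, cls: int | None = None):
    d = _safe_ratio(2.0 * counts.tp, (2 * counts.tp + counts.fp + counts.fn).astype(float))
    return d if cls is None else float(d[cls])


def pixel_accuracy(counts: ConfusionCounts) -> float:
    total = int(counts.tp.sum() + counts.fn.sum())
    return float(counts.tp.sum() / total) if total else float("nan")


def mean_metrics(
    counts_per_image: list[ConfusionCounts], aggregation: str = "pooled"
) -> MetricsReport:
    """Dataset-level report from per-image confusion counts.

    ``pooled`` (default) sums counts over images before dividing —
    standard for this benchmark lineage and stable for small classes;
    ``per_image`` averages each class's per-image scores instead.
    """
    if not counts_per_image:
        raise ValueError("no confusion counts supplied")
    pooled = counts_per_image[0]
    for c in counts_per_image[1:]:
        pooled = pooled + c
    if aggregation == "pooled":
        jc, d = jaccard(pooled), dsc(pooled)
    elif aggregation == "per_image":
        jc_all = np.stack([jaccard(c) for c in counts_per_image])
        d_all = np.stack([dsc(c) for c in counts_per_image])
        with np.errstate(invalid="ignore"):
            jc, d = np.nanmean(jc_all, axis=0), np.nanmean(d_all, axis=0)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if np.isnan(jc).all():
        raise ValueError("no class has a nonempty union")
    return MetricsReport(
        per_class_jc=jc,
        per_class_dsc=d,
        mean_jc=float(np.nanmean(jc)),
        mean_dsc=float(np.nanmean(d)),
        pixel_accuracy=pixel_accuracy(pooled),
    )


def evaluate_model(
    net,
    samples: list[SegmentationSample],
    stem_config: StemConfig = StemConfig(),
    aggregation: str = "pooled",
) -> MetricsReport:
    """Predict every sample and report pooled JC/DSC plus mean confidence."""
    counts, confs = [], []
    for s in samples:
        pred, probs = net.predict(s.image, stem_config)
        counts.append(confusion_counts(pred, s.mask, net.config.n_classes))
        confs.append(confidence_score(probs))
    report = mean_metrics(counts, aggregation)
    report.confidence = float(np.mean(confs))
    return report


# ---------------------------------------------------------------------------
# confidence flagging


def confidence_score(prob_map: np.ndarray) -> float:
    """Mean softmax margin (top-1 minus top-2 probability) over pixels."""
    p = np.asarray(prob_map, dtype=np.float64)
    if p.ndim != 3:
        raise ValueError(f"expected (C, H, W) probabilities, got {p.shape}")
    top2 = np.partition(p, -2, axis=0)[-2:]
    return float((top2[1] - top2[0]).mean())


def calibrate_flag_threshold(validation_scores, percentile: float = 5.0) -> float:
    """Linear-interpolation percentile of validation confidence scores."""
    scores = np.asarray(list(validation_scores), dtype=np.float64)
    if scores.size == 0:
        raise ValueError("no validation scores supplied")
    return float(np.percentile(scores, percentile, method="linear"))


def flag(score: float, threshold: float) -> bool:
    """True when an image's confidence falls strictly below the threshold."""
    return bool(score < threshold)


# ---------------------------------------------------------------------------
# perturbation robustness


@dataclass(frozen=True)
class PerturbationSpec:
    """One robustness condition.

    kind 'gaussian_noise' (parameter = variance), 'salt_pepper'
    (parameter = corrupted-pixel density, half set to 0 and half to 1) or
    'gaussian_blur' (parameter = sigma in pixels).
    """

    kind: str
    parameter: float
    seed: int = 0

    def label(self) -> str:
        names = {
            "gaussian_noise": "variance",
            "salt_pepper": "density",
            "gaussian_blur": "sigma",
        }
        return f"{self.kind} ({names[self.kind]}={self.parameter:g})"


#: the published robustness sweep conditions
TABLE3_SPECS: tuple[PerturbationSpec, ...] = (
    PerturbationSpec("salt_pepper", 0.0075),
    PerturbationSpec("salt_pepper", 0.015),
    PerturbationSpec("gaussian_noise", 0.0005),
    PerturbationSpec("gaussian_noise", 0.001),
    PerturbationSpec("gaussian_noise", 0.002),
    PerturbationSpec("gaussian_blur", 0.5),
    PerturbationSpec("gaussian_blur", 1.0),
)


def perturb(img: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Apply one perturbation to a [0,1] grayscale image."""
    img = np.asarray(img, dtype=np.float64)
    if spec.parameter < 0:
        raise ValueError("perturbation parameter must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian_noise":
        out = img + rng.normal(0.0, np.sqrt(spec.parameter), img.shape)
        return np.clip(out, 0.0, 1.0).astype(np.float32)
    if spec.kind == "salt_pepper":
        out = img.copy()
        hit = rng.random(img.shape) < spec.parameter
        salt = rng.random(img.shape) < 0.5
        out[hit & salt] = 1.0
        out[hit & ~salt] = 0.0
        return out.astype(np.float32)
    if spec.kind == "gaussian_blur":
        if spec.parameter == 0:
            return img.astype(np.float32)
        return gaussian_filter(img, spec.parameter, mode="reflect").astype(np.float32)
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")


def robustness_sweep(
    net,
    samples: list[SegmentationSample],
    specs: tuple[PerturbationSpec, ...] = TABLE3_SPECS,
    stem_config: StemConfig = StemConfig(),
) -> list[tuple[str, float]]:
    """Mean JC under each perturbation, clean baseline first."""
    rows = [("clean", evaluate_model(net, samples, stem_config).mean_jc)]
    for spec in specs:
        counts = []
        for i, s in enumerate(samples):
            per_image = PerturbationSpec(spec.kind, spec.parameter, seed=spec.seed + 997 * i)
            pred, _ = net.predict(perturb(s.image, per_image), stem_config)
            counts.append(confusion_counts(pred, s.mask, net.config.n_classes))
        rows.append((spec.label(), mean_metrics(counts).mean_jc))
    return rows
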