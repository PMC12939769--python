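"""Paired image/mask augmentation: a 16-fold geometric expansion.

Each source pair yields exactly 16 variants — the grid of 4 flip states
{identity, horizontal, vertical, both} x 4 spatial operations {identity,
translation, crop-resize, translation+crop} — the only orthogonal design
that reaches the stated 16x yield (200 training pairs -> 3200) with the
four named operation families.  Image and mask always receive the
identical geometric map; masks are resampled nearest-neighbor so no new
labels can appear; translations are integer-pixel with reflective fill;
crops are resized back to the source size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .phantom import SegmentationSample

__all__ = ["AugmentationPlan", "AppliedTransform", "augment_pair", "augment_dataset", "apply_transform"]

VARIANTS_PER_PAIR = 16


@dataclass(frozen=True)
class AugmentationPlan:
    """Sampling ranges for the 16-variant grid.

    ``translation_px`` is the (min, max) magnitude of each integer shift
    component; ``crop_fraction`` the (min, max) side fraction of a crop
    window.  Defaults are calibrated for 400x400 inputs; use
    :meth:`for_size` to rescale the translation range.
    """

    translation_px: tuple[int, int] = (5, 20)
    crop_fraction: tuple[float, float] = (0.7, 0.95)
    seed: int = 0

    @classmethod
    def for_size(cls, size: int, seed: int = 0) -> "AugmentationPlan":
        s = size / 400.0
        lo, hi = max(1, round(5 * s)), max(2, round(20 * s))
        return cls(translation_px=(lo, hi), crop_fraction=(0.7, 0.95), seed=seed)


@dataclass(frozen=True)
class AppliedTransform:
    """A fully determined geometric map (replayable on image or mask)."""

    flip_h: bool
    flip_v: bool
    shift: tuple[int, int]  # (rows, cols), 0 = no translation
    crop: tuple[int, int, int] | None  # (row0, col0, side), None = no crop
    out_size: int


def _reflect_shift(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer translation with reflective padding (no void fill class)."""
    h, w = arr.shape
    pad = max(abs(dr), abs(dc))
    if pad == 0:
        return arr.copy()
    if pad >= min(h, w):
        raise ValueError(f"translation {dr, dc} too large for {h}x{w}")
    p = np.pad(arr, pad, mode="reflect")
    return p[pad - dr : pad - dr + h, pad - dc : pad - dc + w].copy()


def apply_transform(arr: np.ndarray, t: AppliedTransform, is_mask: bool) -> np.ndarray:
    """Replay a transform on an image (bilinear) or mask (nearest)."""
    out = arr
    if t.flip_h:
        out = out[:, ::-1]
    if t.flip_v:
        out = out[::-1, :]
    out = _reflect_shift(np.ascontiguousarray(out), *t.shift)
    if t.crop is not None:
        r0, c0, side = t.crop
        out = out[r0 : r0 + side, c0 : c0 + side]
    if out.shape != (t.out_size, t.out_size):
        order = 0 if is_mask else 1
        res = resize(
            out.astype(np.float64),
            (t.out_size, t.out_size),
            order=order,
            mode="reflect",
            anti_aliasing=False,
            preserve_range=True,
        )
        out = np.rint(res).astype(arr.dtype) if is_mask else res.astype(arr.dtype)
    return np.ascontiguousarray(out)


def plan_transforms(size: int, plan: AugmentationPlan, sample_index: int = 0) -> list[AppliedTransform]:
    """The 16 deterministic transforms for one source pair."""
    rng = np.random.default_rng((plan.seed, sample_index))
    lo, hi = plan.translation_px
    if hi < lo or lo < 0:
        raise ValueError(f"bad translation range {plan.translation_px}")
    out = []
    for flip_h, flip_v in ((False, False), (True, False), (False, True), (True, True)):
        for do_shift, do_crop in ((False, False), (True, False), (False, True), (True, True)):
            shift = (0, 0)
            if do_shift and hi > 0:
                mag = rng.integers(lo, hi + 1, size=2)
                sign = rng.choice((-1, 1), size=2)
                shift = (int(mag[0] * sign[0]), int(mag[1] * sign[1]))
            crop = None
            if do_crop:
                frac = rng.uniform(*plan.crop_fraction)
                side = int(round(size * frac))
                if side < 8:
                    raise ValueError(f"crop window {side} px degenerate (< 8 px)")
                r0 = int(rng.integers(0, size - side + 1))
                c0 = int(rng.integers(0, size - side + 1))
                crop = (r0, c0, side)
            out.append(AppliedTransform(flip_h, flip_v, shift, crop, size))
    return out


def augment_pair(
    sample: SegmentationSample, plan: AugmentationPlan, sample_index: int = 0
) -> list[SegmentationSample]:
    """All 16 variants of one image/mask pair (deterministic given seed)."""
    if sample.image.shape != sample.mask.shape:
        raise ValueError("image and mask must be aligned")
    size = sample.image.shape[0]
    out = []
    for t in plan_transforms(size, plan, sample_index):
        img = apply_transform(sample.image, t, is_mask=False)
        msk = apply_transform(sample.mask, t, is_mask=True)
        out.append(SegmentationSample(np.clip(img, 0.0, 1.0).astype(np.float32), msk))
    return out


def augment_dataset(
    samples: list[SegmentationSample], plan: AugmentationPlan
) -> tuple[list[SegmentationSample], list[int]]:
    """Expand a dataset 16-fold.

    Returns ``(augmented, source_index)`` where ``source_index[i]`` points
    at the originating sample — needed to split train/validation by source
    so augmented copies never straddle the split.
    """
    if not samples:
        raise ValueError("empty input dataset")
    out: list[SegmentationSample] = []
    groups: list[int] = []
    for i, s in enumerate(samples):
        variants = augment_pair(s, plan, i)
        out.extend(variants)
        groups.extend([i] * len(variants))
    return out, groups
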