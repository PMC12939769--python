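"""Synthetic blastocyst phantoms with pixel-perfect five-class masks.

Real blastocyst micrographs are access-restricted, so this module renders
images that reproduce the *structural* and *statistical* challenges of the
task: an elliptical zona pellucida (ZP) shell enclosing a trophectoderm
(TE) ring enclosing the blastocoel (BC) fluid cavity, with one eccentric
inner-cell-mass (ICM) blob resting against the TE; low inter-class
intensity contrast; distinct ZP (fine speckle) vs TE (cellular ripple)
textures; a smooth illumination gradient; additive noise; and the BC+BG
pixel dominance that drives class imbalance.  Every draw is reproducible
from its seed.

Class labels: 0=BG, 1=ZP, 2=TE, 3=BC, 4=ICM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomParams", "SegmentationSample", "generate_phantom", "generate_dataset"]

BG, ZP, TE, BC, ICM = 0, 1, 2, 3, 4


@dataclass
class SegmentationSample:
    """A paired grayscale image (float in [0,1]) and label mask (int in 0..4)."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(f"image {self.image.shape} vs mask {self.mask.shape}")
        if self.mask.min() < 0 or self.mask.max() > 4:
            raise ValueError("mask labels must lie in {0..4}")


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters; pixel quantities are calibrated for 400x400.

    ``contrast`` bounds the separation of per-class base intensities (the
    low-contrast difficulty dial); ``expansion`` scales the cavity,
    emulating different blastocyst expansion stages.
    """

    size: int = 400
    zp_thickness: tuple[float, float] = (14.0, 22.0)
    te_thickness: tuple[float, float] = (10.0, 18.0)
    icm_radius: tuple[float, float] = (30.0, 55.0)
    contrast: float = 0.12
    illumination_gradient: float = 0.08
    noise_sigma: float = 0.02
    expansion: float = 1.0
    seed: int = 0

    @classmethod
    def for_size(cls, size: int, seed: int = 0, **overrides) -> "PhantomParams":
        """Defaults with all pixel quantities rescaled from 400 to ``size``."""
        s = size / 400.0
        base = cls()

        def scaled(lo_hi):
            lo, hi = lo_hi[0] * s, lo_hi[1] * s
            return (max(lo, 2.0), max(hi, 2.5))  # shells never thinner than 2 px

        return cls(
            size=size,
            zp_thickness=scaled(base.zp_thickness),
            te_thickness=scaled(base.te_thickness),
            icm_radius=(base.icm_radius[0] * s, base.icm_radius[1] * s),
            seed=seed,
            **overrides,
        )

    def validate(self) -> "PhantomParams":
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.zp_thickness[0] < 2 or self.te_thickness[0] < 2:
            raise ValueError("shell thicknesses must be >= 2 px")
        max_extent = 0.44 * self.size
        if self.zp_thickness[1] + self.te_thickness[1] + self.icm_radius[1] > max_extent:
            raise ValueError("geometry cannot fit: shells plus ICM exceed the embryo radius")
        if not 0.0 <= self.contrast <= 1.0 or not 0.0 <= self.expansion <= 1.0:
            raise ValueError("contrast and expansion must lie in [0, 1]")
        return self


def _class_levels(base: float, c: float) -> dict[int, float]:
    # adjacent classes separated by at most `c` in base intensity
    return {
        BG: base,
        ZP: base + 0.50 * c,
        TE: base + 0.05 * c,
        BC: base - 0.45 * c,
        ICM: base - 0.10 * c,
    }


def generate_phantom(params: PhantomParams) -> SegmentationSample:
    """Render one phantom; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    s = params.size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    # --- geometry -----------------------------------------------------
    cx = s / 2 + rng.uniform(-0.03, 0.03) * s
    cy = s / 2 + rng.uniform(-0.03, 0.03) * s
    a = s * rng.uniform(0.37, 0.44)
    b = a * rng.uniform(0.82, 1.0)
    phi = rng.uniform(0, np.pi)
    u = ((xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)) / a
    v = (-(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)) / b
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)

    # boundary irregularity (gentle dents, stronger for collapsed embryos)
    dent_amp = 0.02 + 0.04 * (1.0 - params.expansion)
    rho = np.ones_like(theta)
    for k in range(2, 6):
        rho += dent_amp / k * np.cos(k * theta + rng.uniform(0, 2 * np.pi))

    mean_r = 0.5 * (a + b)
    t_zp = rng.uniform(*params.zp_thickness) / mean_r
    t_te = rng.uniform(*params.te_thickness) / mean_r
    cavity_scale = 0.70 + 0.30 * params.expansion
    r_zp_out = rho
    r_zp_in = rho - t_zp
    r_bc = (rho - t_zp - t_te) * cavity_scale

    mask = np.full((s, s), BG, dtype=np.int64)
    mask[r <= r_zp_out] = ZP
    mask[r <= r_zp_in] = TE
    mask[r <= r_bc] = BC

    # --- eccentric ICM touching the TE ring ---------------------------
    icm_r = rng.uniform(*params.icm_radius)
    psi = rng.uniform(0, 2 * np.pi)
    step = np.array([np.cos(psi), np.sin(psi)])
    pos = np.array([cx, cy])
    edge = pos.copy()
    for t in range(1, s):
        p = pos + t * step
        i, j = int(round(p[1])), int(round(p[0]))
        if not (0 <= i < s and 0 <= j < s) or mask[i, j] != BC:
            break
        edge = p
    center = edge - 0.7 * icm_r * step
    icm_disk = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= icm_r**2
    mask[icm_disk & (mask == BC)] = ICM

    # --- rendering ----------------------------------------------------
    base = rng.uniform(0.40, 0.60)
    levels = _class_levels(base, params.contrast)
    img = np.zeros((s, s), dtype=np.float64)
    for cls, level in levels.items():
        img[mask == cls] = level

    # procedural textures: fine speckle on ZP, cellular ripple on TE,
    # coarse blobs on ICM; the cavity stays smooth
    speckle = gaussian_filter(rng.normal(0, 1, (s, s)), 0.8)
    speckle /= max(np.abs(speckle).max(), 1e-9)
    img[mask == ZP] += 0.05 * speckle[mask == ZP]
    n_cells = int(rng.uniform(28, 44))
    ripple = np.cos(n_cells * theta + rng.uniform(0, 2 * np.pi)) * np.cos(
        2 * np.pi * (r - r_zp_in) / max(2.2 * t_te, 1e-6)
    )
    img[mask == TE] += 0.05 * ripple[mask == TE]
    blobs = gaussian_filter(rng.normal(0, 1, (s, s)), 3.0)
    blobs /= max(np.abs(blobs).max(), 1e-9)
    img[mask == ICM] += 0.06 * blobs[mask == ICM]

    # illumination gradient and sensor noise
    ang = rng.uniform(0, 2 * np.pi)
    grad = ((xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)) / s
    img += params.illumination_gradient * grad
    img += rng.normal(0, params.noise_sigma, (s, s))
    return SegmentationSample(np.clip(img, 0.0, 1.0).astype(np.float32), mask)


def generate_dataset(
    n: int,
    size: int = 400,
    seed: int = 0,
    params: PhantomParams | None = None,
) -> list[SegmentationSample]:
    """Draw ``n`` phantoms with independent per-sample seeds.

    Every returned mask contains all five classes; the rare degenerate
    draw (possible at extreme parameter settings) is re-drawn from a
    derived seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    template = params if params is not None else PhantomParams.for_size(size, seed)
    out = []
    for i in range(n):
        sample_seed = (seed * 1_000_003 + 7919 * i) % (2**31)
        for attempt in range(8):
            sample = generate_phantom(replace(template, seed=(sample_seed + 101 * attempt) % 2**31))
            if len(np.unique(sample.mask)) == 5:
                break
        else:
            raise RuntimeError("could not draw a phantom containing all five classes")
        out.append(sample)
    return out


def class_pixel_counts(mask: np.ndarray) -> np.ndarray:
    """Pixel count per class label 0..4."""
    return np.bincount(mask.ravel(), minlength=5)[:5]
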