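"""Multimodal input stem: intensity, LBP texture and oriented Gabor channels.

A grayscale frame is decomposed into four fixed (non-learnable) channels
before it enters the network: the photometric intensity itself, a classic
8-neighbor local-binary-pattern code map capturing micro-texture (the
zona pellucida and trophectoderm differ mainly in texture, not intensity),
and even-symmetric Gabor responses at 0 deg and 90 deg capturing roughly
horizontal/vertical oriented structure.  All channels are normalized to
[0, 1] so the modalities enter fusion at commensurate magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

__all__ = [
    "StemConfig",
    "ModalityStack",
    "local_binary_pattern",
    "gabor_response",
    "build_modality_stack",
]

# neighbor offsets (row, col) clockwise from east for the radius-1, 8-neighbor code
_OFFSETS_8 = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass(frozen=True)
class StemConfig:
    """Parameters of the fixed stem filters.

    Gabor defaults target the mid-frequency ripple scale of the TE/ZP rings
    at the native 400x400 resolution: wavelength 8 px, envelope sigma 4 px,
    aspect ratio 0.5, even (cosine) phase, kernel side 4*sigma+1, DC-free.
    """

    lbp_radius: int = 1
    lbp_neighbors: int = 8
    gabor_wavelength: float = 8.0
    gabor_sigma: float = 4.0
    gabor_aspect: float = 0.5
    orientations: tuple[float, ...] = (0.0, 90.0)


@dataclass
class ModalityStack:
    """Ordered per-image channel decomposition, shape (4, H, W), all in [0,1]."""

    channels: np.ndarray
    names: tuple[str, ...] = ("intensity", "lbp", "gabor_0", "gabor_90")

    def __post_init__(self):
        if self.channels.ndim != 3 or self.channels.shape[0] != len(self.names):
            raise ValueError(f"expected ({len(self.names)}, H, W), got {self.channels.shape}")


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a nonempty 2-D grayscale image, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite pixel values")
    return img


def local_binary_pattern(img: np.ndarray, radius: int = 1, neighbors: int = 8) -> np.ndarray:
    """Per-pixel LBP code normalized by ``2**neighbors - 1``.

    Neighbors are sampled on the axis-aligned square ring at the given
    radius, ordered clockwise starting from east; a bit is set when
    ``neighbor >= center``.  Borders use reflective padding.  A constant
    image therefore maps to an all-ones channel (every comparison true).
    """
    img = _validate_image(img)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if neighbors not in (4, 8, 16):
        raise ValueError("neighbors must be one of 4, 8, 16")
    if radius > min(img.shape) // 2:
        raise ValueError(f"radius {radius} exceeds half the image side {min(img.shape)}")
    if neighbors == 4:
        offs = [(radius * dr, radius * dc) for dr, dc in (_OFFSETS_8[i] for i in (0, 2, 4, 6))]
    elif neighbors == 8:
        offs = [(radius * dr, radius * dc) for dr, dc in _OFFSETS_8]
    else:  # 16 samples on a circle of the given radius, clockwise from east
        ang = np.arange(16) * (2 * np.pi / 16)
        offs = [
            (int(r), int(c))
            for r, c in zip(np.rint(radius * np.sin(ang)), np.rint(radius * np.cos(ang)))
        ]
    pad = radius
    padded = np.pad(img, pad, mode="reflect")
    h, w = img.shape
    code = np.zeros((h, w), dtype=np.float64)
    for bit, (dr, dc) in enumerate(offs):
        nb = padded[pad + dr : pad + dr + h, pad + dc : pad + dc + w]
        code += (nb >= img) * (1 << bit)
    return code / (2.0**neighbors - 1.0)


def gabor_kernel(
    orientation: float, wavelength: float, sigma: float, aspect: float
) -> np.ndarray:
    """Zero-mean, even-symmetric (cosine-phase) Gabor kernel.

    ``orientation`` is the normal of the stripes in degrees: 0 deg responds
    to vertical structure (variation along x), 90 deg to horizontal.
    """
    if wavelength <= 0 or sigma <= 0 or aspect <= 0:
        raise ValueError("wavelength, sigma and aspect must be positive")
    half = int(np.ceil(2.0 * sigma))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    theta = np.deg2rad(orientation)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    k = np.exp(-(xr**2 + (aspect * yr) ** 2) / (2 * sigma**2)) * np.cos(2 * np.pi * xr / wavelength)
    return k - k.mean()


def gabor_response(
    img: np.ndarray,
    orientation: float,
    wavelength: float = 8.0,
    sigma: float = 4.0,
    aspect: float = 0.5,
) -> np.ndarray:
    """Rectified, per-image min-max normalized Gabor filter response.

    The kernel has zero mean, so a constant image maps to an identically
    zero channel (DC rejection); any constant response map normalizes to
    all zeros.
    """
    img = _validate_image(img)
    if orientation not in (0, 90, 0.0, 90.0):
        raise ValueError("orientation must be 0 or 90 degrees")
    k = gabor_kernel(orientation, wavelength, sigma, aspect)
    if k.shape[0] > img.shape[0] or k.shape[1] > img.shape[1]:
        raise ValueError(f"kernel {k.shape} larger than image {img.shape}")
    resp = np.abs(convolve(img, k, mode="reflect"))
    lo, hi = resp.min(), resp.max()
    if hi - lo < 1e-12:
        return np.zeros_like(resp)
    return (resp - lo) / (hi - lo)


def build_modality_stack(img: np.ndarray, config: StemConfig = StemConfig()) -> ModalityStack:
    """Decompose a [0,1] grayscale frame into the four modality channels."""
    img = _validate_image(img)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    chans = [np.clip(img, 0.0, 1.0)]
    chans.append(local_binary_pattern(img, config.lbp_radius, config.lbp_neighbors))
    for ori in config.orientations:
        chans.append(
            gabor_response(img, ori, config.gabor_wavelength, config.gabor_sigma, config.gabor_aspect)
        )
    names = ("intensity", "lbp") + tuple(f"gabor_{int(o)}" for o in config.orientations)
    return ModalityStack(np.stack(chans).astype(np.float32), names)
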