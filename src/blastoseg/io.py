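"""Image/mask I/O, overlay rendering, configs, checkpoints and reports.

Images are single-channel PNG/TIFF/BMP, 8- or 16-bit, normalized to [0,1]
on read by their bit depth; masks are single-channel indexed PNGs with
labels 0..4 (losslessly round-tripped).  Overlays follow the reporting
color convention: correctly labeled TE red, ICM blue, ZP green, BC
yellow, BG gray; misclassified pixels whose true class is a foreground
component are pink (missed component / fn), misclassified pixels whose
true class is background are black (spurious component / fp).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .phantom import SegmentationSample, class_pixel_counts

__all__ = [
    "OVERLAY_COLORS",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_sample",
    "write_sample",
    "render_overlay",
    "write_manifest",
    "write_history_csv",
    "save_checkpoint",
    "load_checkpoint",
    "config_to_yaml",
    "config_from_yaml",
]

#: tp colors per true class (BG, ZP, TE, BC, ICM) plus the two error colors
OVERLAY_COLORS = {
    "BG": (128, 128, 128),
    "ZP": (0, 255, 0),
    "TE": (255, 0, 0),
    "BC": (255, 255, 0),
    "ICM": (0, 0, 255),
    "fp": (0, 0, 0),
    "fn": (255, 105, 180),
}
_CLASS_COLOR_LIST = [OVERLAY_COLORS[k] for k in ("BG", "ZP", "TE", "BC", "ICM")]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image normalized to [0,1] by its bit depth."""
    with Image.open(path) as im:
        if im.mode in ("L", "P"):
            arr, scale = np.asarray(im.convert("L"), dtype=np.float64), 255.0
        elif im.mode.startswith("I;16") or im.mode == "I":
            arr, scale = np.asarray(im, dtype=np.float64), 65535.0
        elif im.mode == "F":
            arr, scale = np.asarray(im, dtype=np.float64), 1.0
        else:
            raise ValueError(
                f"{path}: mode {im.mode!r} is not single-channel grayscale "
                "(convert RGB inputs before loading)"
            )
    return np.clip(arr / scale, 0.0, 1.0).astype(np.float32)


def write_image(path: str | Path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path, n_classes: int = 5) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in ("L", "P"):
            raise ValueError(f"{path}: mask must be a single-channel indexed PNG, got {im.mode!r}")
        arr = np.asarray(im, dtype=np.int64)
    bad = arr[(arr < 0) | (arr >= n_classes)]
    if bad.size:
        raise ValueError(f"{path}: mask contains out-of-range label {int(bad.flat[0])}")
    return arr


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = np.asarray(mask)
    if arr.min() < 0 or arr.max() > 4:
        raise ValueError(f"mask labels out of range: {arr.min()}..{arr.max()}")
    im = Image.fromarray(arr.astype(np.uint8), mode="P")
    palette = []
    for color in _CLASS_COLOR_LIST:
        palette.extend(color)
    im.putpalette(palette + [0, 0, 0] * (256 - len(_CLASS_COLOR_LIST)))
    im.save(path)


def read_sample(image_path: str | Path, mask_path: str | Path) -> SegmentationSample:
    return SegmentationSample(read_image(image_path), read_mask(mask_path))


def write_sample(sample: SegmentationSample, image_path: str | Path, mask_path: str | Path) -> None:
    write_image(image_path, sample.image)
    write_mask(mask_path, sample.mask)


def write_stack_debug(stack, directory: str | Path, prefix: str = "stack") -> list[Path]:
    """Write each modality channel as an 8-bit PNG (debugging aid)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, channel in zip(stack.names, stack.channels):
        p = directory / f"{prefix}_{name}.png"
        write_image(p, channel)
        paths.append(p)
    return paths


def render_overlay(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    """RGB error overlay (uint8).  See module docstring for the convention."""
    pred, true = np.asarray(pred), np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    out = np.zeros(pred.shape + (3,), dtype=np.uint8)
    correct = pred == true
    for cls, color in enumerate(_CLASS_COLOR_LIST):
        out[correct & (true == cls)] = color
    out[~correct & (true == 0)] = OVERLAY_COLORS["fp"]
    out[~correct & (true != 0)] = OVERLAY_COLORS["fn"]
    return out


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    """TSV manifest (filename, seed, per-class pixel counts...)."""
    if not rows:
        raise ValueError("empty manifest")
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def manifest_row(name: str, seed: int, sample: SegmentationSample) -> dict:
    counts = class_pixel_counts(sample.mask)
    row = {"filename": name, "seed": seed}
    for i, cls in enumerate(("BG", "ZP", "TE", "BC", "ICM")):
        row[f"px_{cls}"] = int(counts[i])
    return row


def write_history_csv(path: str | Path, history) -> None:
    lines = ["epoch,train_loss,train_acc,val_loss,val_acc"]
    for i in range(len(history.train_loss)):
        vl = history.val_loss[i] if i < len(history.val_loss) else ""
        va = history.val_acc[i] if i < len(history.val_acc) else ""
        lines.append(f"{i + 1},{history.train_loss[i]},{history.train_acc[i]},{vl},{va}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# checkpoints and configs


def save_checkpoint(net, path: str | Path) -> None:
    """Weights as .npz with the network config as a YAML sidecar."""
    path = Path(path)
    np.savez(path, **net.state_dict())
    path.with_suffix(".yaml").write_text(config_to_yaml(net.config))


def load_checkpoint(path: str | Path):
    from .model import NetworkConfig, build_network

    path = Path(path)
    cfg = config_from_yaml(path.with_suffix(".yaml").read_text(), NetworkConfig)
    net = build_network(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        net.load_state_dict(dict(data))
    return net


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_to_yaml(config) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=False)


def config_from_yaml(text: str, cls):
    data = yaml.safe_load(text)
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)
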