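"""Lightweight multimodal encoder-decoder for five-class segmentation.

The network follows a strict parameter budget (<= 0.65 M trainable
parameters at the default 400x400, five-class configuration):

* **Stem fusion** (FU-1): the four fixed modality channels are
  concatenated and blended by a point-wise convolution.
* **Encoder**: three stride-2 convolutions interleaved with dual-path
  grouped (DPG) blocks take the map through 400 -> 200 -> 100 -> 50; a
  compact bottleneck (one more stride-2 conv + BN + ReLU) reaches the
  deepest 25 x 25 map.  Each DPG block runs two independently initialized
  grouped 3x3 paths in parallel and fuses them with a 1x1 convolution
  (its fusion unit), trading parameters for diverse features.
* **Refinement decoder**: transposed convolutions restore
  25 -> 50 -> 100 -> 200 -> 400, with two semantic skip pathways (grouped
  then point-wise convolutions) injecting encoder features at 50x50 and
  the stem fusion output at full resolution; a final DPG block, a
  point-wise squeeze and a grouped five-channel head feed the softmax
  pixel classifier.

Ablation toggles allow dropping the multimodal stem, replacing DPG blocks
with single grouped paths, and removing the skip pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import Tensor
from .stem import StemConfig, build_modality_stack

__all__ = [
    "NetworkConfig",
    "DualPathGroupedBlock",
    "SegmentationNet",
    "build_network",
    "make_ablation_variant",
    "count_trainable_parameters",
    "PARAMETER_BUDGET",
]

PARAMETER_BUDGET = 650_000


@dataclass(frozen=True)
class NetworkConfig:
    """Instantiable description of the network.

    ``stage_widths`` are the encoder channel counts at full, 1/2, 1/4 and
    1/8 resolution; the decoder mirrors them.  All widths must be
    divisible by ``groups`` and the input size by 16 (four stride-2
    reductions).
    """

    input_size: int = 400
    n_classes: int = 5
    modality_channels: int = 4
    stage_widths: tuple[int, int, int, int] = (32, 48, 64, 96)
    groups: int = 4
    use_mbi_stem: bool = True
    use_dpg: bool = True
    use_ssp: bool = True
    #: normalize by per-sample (instance) statistics at inference instead
    #: of running averages; pairs with single-image training batches
    instance_norm_eval: bool = True
    seed: int = 0

    def validate(self) -> "NetworkConfig":
        if self.input_size % 16:
            raise ValueError(f"input_size {self.input_size} must be divisible by 16")
        if any(w % self.groups for w in self.stage_widths):
            raise ValueError(f"stage widths {self.stage_widths} not divisible by groups={self.groups}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        return self


def _conv_bn_relu(cin, cout, k, stride, groups, rng):
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, stride=stride, groups=groups, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class DualPathGroupedBlock(nn.Module):
    """Two parallel grouped-conv paths fused by a point-wise convolution.

    With ``dual=False`` the block degrades to a single grouped path
    (G-con + BN + ReLU) of the same output width — the ablation variant
    that removes the dual-path fusion while keeping capacity comparable.
    """

    def __init__(self, cin: int, cout: int, groups: int, rng: np.random.Generator, dual: bool = True):
        self.dual = dual
        self.groups = groups
        if dual:
            self.conv_a = nn.Conv2d(cin, cout, 3, groups=groups, rng=rng)
            self.conv_b = nn.Conv2d(cin, cout, 3, groups=groups, rng=rng)
            # one 2C-channel BN == two independent per-path C-channel BNs
            self.bn_pair = nn.BatchNorm2d(2 * cout)
            self.act = nn.ReLU()
            self.fuse = _conv_bn_relu(2 * cout, cout, 1, 1, 1, rng)
        else:
            self.path_a = _conv_bn_relu(cin, cout, 3, 1, groups, rng)

    def pre_fusion(self, x: Tensor, training: bool = False) -> Tensor:
        """Concatenated per-path activations (path A channels first)."""
        pair = nn.autodiff.conv2d_pair(
            x, self.conv_a.weight, self.conv_a.bias, self.conv_b.weight, self.conv_b.bias,
            stride=1, padding=1, groups=self.groups,
        )
        return self.act(self.bn_pair(pair, training), training)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if not self.dual:
            return self.path_a(x, training)
        return self.fuse(self.pre_fusion(x, training), training)


class SemanticSkip(nn.Module):
    """Skip pathway: grouped 3x3 filtering then point-wise re-weighting."""

    def __init__(self, cin: int, cout: int, groups: int, rng: np.random.Generator):
        self.gcon = _conv_bn_relu(cin, cin, 3, 1, groups, rng)
        self.pcon = _conv_bn_relu(cin, cout, 1, 1, 1, rng)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.pcon(self.gcon(x, training), training)


class SegmentationNet(nn.Module):
    """The full encoder-decoder graph (see module docstring)."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w0, w1, w2, w3 = config.stage_widths
        g = config.groups
        cin = config.modality_channels if config.use_mbi_stem else 1
        dual = config.use_dpg

        # --- encoder -----------------------------------------------------
        self.fu1 = _conv_bn_relu(cin, w0, 1, 1, 1, rng)  # stem fusion blend
        self.scon1 = _conv_bn_relu(w0, w1, 3, 2, 1, rng)
        self.dpg_enc1 = DualPathGroupedBlock(w1, w1, g, rng, dual)  # FU-2, at 1/2
        self.scon2 = _conv_bn_relu(w1, w2, 3, 2, 1, rng)
        self.dpg_enc2 = DualPathGroupedBlock(w2, w2, g, rng, dual)  # FU-3, at 1/4
        self.scon3 = _conv_bn_relu(w2, w3, 3, 2, 1, rng)
        self.dpg_enc3 = DualPathGroupedBlock(w3, w3, g, rng, dual)  # FU-4, at 1/8
        self.bottleneck = _conv_bn_relu(w3, w3, 3, 2, 1, rng)  # ComB, at 1/16

        # --- decoder -----------------------------------------------------
        self.tcon1 = nn.Sequential(nn.ConvTranspose2d(w3, w3, rng=rng), nn.BatchNorm2d(w3), nn.ReLU())
        self.dpg_dec1 = DualPathGroupedBlock(w3, w3, g, rng, dual)  # FU-5, at 1/8
        self.pcon_dec = _conv_bn_relu(w3, w2, 1, 1, 1, rng)
        if config.use_ssp:
            self.ssp1 = SemanticSkip(w3, w2 // 2, g, rng)
            self.fu6 = _conv_bn_relu(w2 + w2 // 2, w2, 1, 1, 1, rng)
        else:
            self.fu6 = _conv_bn_relu(w2, w2, 1, 1, 1, rng)
        self.tcon2 = nn.Sequential(nn.ConvTranspose2d(w2, w1, rng=rng), nn.BatchNorm2d(w1), nn.ReLU())
        self.tcon3 = nn.Sequential(nn.ConvTranspose2d(w1, w0, rng=rng), nn.BatchNorm2d(w0), nn.ReLU())
        self.tcon4 = nn.Sequential(nn.ConvTranspose2d(w0, w0, rng=rng), nn.BatchNorm2d(w0), nn.ReLU())
        if config.use_ssp:
            self.ssp2 = SemanticSkip(w0, w0 // 2, g, rng)
            self.fu7 = _conv_bn_relu(w0 + w0 // 2, w0, 1, 1, 1, rng)
        else:
            self.fu7 = _conv_bn_relu(w0, w0, 1, 1, 1, rng)
        self.dpg_dec2 = DualPathGroupedBlock(w0, w0, g, rng, dual)  # FU-8, full res
        head_mid = 4 * config.n_classes
        self.pcon_out = _conv_bn_relu(w0, head_mid, 1, 1, 1, rng)
        # grouped head: one group of 4 channels per class
        self.head = nn.Conv2d(head_mid, config.n_classes, 3, groups=config.n_classes, rng=rng)

        if config.instance_norm_eval:
            self._set_batch_stats_at_eval(self)
        if config == NetworkConfig(seed=config.seed) and self.n_parameters() > PARAMETER_BUDGET:
            raise ValueError(
                f"default configuration exceeds the parameter budget: "
                f"{self.n_parameters()} > {PARAMETER_BUDGET}"
            )

    @staticmethod
    def _set_batch_stats_at_eval(module) -> None:
        if isinstance(module, nn.BatchNorm2d):
            module.batch_stats_at_eval = True
        for _, m in module.submodules():
            SegmentationNet._set_batch_stats_at_eval(m)

    # ------------------------------------------------------------------
    def forward(self, stack: np.ndarray, training: bool = False) -> Tensor:
        """Run the graph on a (N, C, H, W) modality batch; returns probabilities."""
        logits, _ = self._forward_traced(stack, training)
        return logits

    def _forward_traced(self, stack: np.ndarray, training: bool):
        cfg = self.config
        stack = np.asarray(stack, dtype=np.float32)
        if stack.ndim == 3:
            stack = stack[None]
        n, c, h, w = stack.shape
        cin = cfg.modality_channels if cfg.use_mbi_stem else 1
        if c != cin:
            raise ValueError(f"expected {cin} input channels, got {c}")
        if h != w or h % 16:
            raise ValueError(f"spatial size {h}x{w} must be square and divisible by 16")
        trace: list[tuple[str, int]] = []

        def log(name, t):
            trace.append((name, t.data.shape[-1]))
            return t

        x = Tensor(stack)
        stem_out = log("fu1", self.fu1(x, training))
        e1 = log("dpg_enc1", self.dpg_enc1(self.scon1(stem_out, training), training))
        e2 = log("dpg_enc2", self.dpg_enc2(self.scon2(e1, training), training))
        e3 = log("dpg_enc3", self.dpg_enc3(self.scon3(e2, training), training))
        z = log("bottleneck", self.bottleneck(e3, training))

        d = log("tcon1", self.tcon1(z, training))
        d = self.pcon_dec(self.dpg_dec1(d, training), training)
        if cfg.use_ssp:
            d = nn.concat([d, self.ssp1(e3, training)], axis=1)
        d = log("fu6", self.fu6(d, training))
        d = self.tcon3(self.tcon2(d, training), training)
        d = log("tcon4", self.tcon4(d, training))
        if cfg.use_ssp:
            d = nn.concat([d, self.ssp2(stem_out, training)], axis=1)
        d = log("fu7", self.fu7(d, training))
        d = self.dpg_dec2(d, training)
        d = self.pcon_out(d, training)
        probs = nn.softmax_channels(self.head(d, training))
        return probs, trace

    def spatial_trace(self, size: int | None = None) -> list[int]:
        """Encoder side lengths (input, after each stride-2 stage)."""
        size = size or self.config.input_size
        cin = self.config.modality_channels if self.config.use_mbi_stem else 1
        dummy = np.zeros((1, cin, size, size), dtype=np.float32)
        _, trace = self._forward_traced(dummy, training=False)
        sides = [size]
        for name, side in trace:
            if name in ("dpg_enc1", "dpg_enc2", "dpg_enc3", "bottleneck"):
                sides.append(side)
        return sides

    def architecture_summary(self) -> str:
        """Per-block TSV: name, output side at the default input, params."""
        size = self.config.input_size
        cin = self.config.modality_channels if self.config.use_mbi_stem else 1
        _, trace = self._forward_traced(np.zeros((1, cin, size, size), np.float32), False)
        sides = dict(trace)
        rows = ["block\toutput_side\tparameters"]
        for name, module in self.submodules():
            side = sides.get(name, "")
            rows.append(f"{name}\t{side}\t{module.n_parameters()}")
        rows.append(f"total\t{size}\t{self.n_parameters()}")
        return "\n".join(rows) + "\n"

    # ------------------------------------------------------------------
    def prepare_input(self, img: np.ndarray, stem_config: StemConfig = StemConfig()) -> np.ndarray:
        """Image -> network input: modality stack, or bare intensity if ablated."""
        if self.config.use_mbi_stem:
            return build_modality_stack(img, stem_config).channels
        return np.asarray(img, dtype=np.float32)[None]

    def predict(self, img: np.ndarray, stem_config: StemConfig = StemConfig()):
        """Segment one image; returns (label mask, (C, H, W) probability map).

        Labels are the per-pixel argmax; ties break toward the lowest
        class index (numpy argmax convention).
        """
        x = self.prepare_input(img, stem_config)
        probs = self.forward(x[None], training=False).data[0]
        return probs.argmax(axis=0).astype(np.int64), probs


def build_network(config: NetworkConfig = NetworkConfig()) -> SegmentationNet:
    return SegmentationNet(config)


def count_trainable_parameters(net: SegmentationNet) -> int:
    """Total learnable weight and bias elements (BN scale/shift included)."""
    return net.n_parameters()


def make_ablation_variant(
    config: NetworkConfig,
    use_mbi_stem: bool | None = None,
    use_dpg: bool | None = None,
    use_ssp: bool | None = None,
) -> SegmentationNet:
    """Instantiate an ablated network by toggling the three modules."""
    kwargs = {}
    if use_mbi_stem is not None:
        kwargs["use_mbi_stem"] = use_mbi_stem
    if use_dpg is not None:
        kwargs["use_dpg"] = use_dpg
    if use_ssp is not None:
        kwargs["use_ssp"] = use_ssp
    return SegmentationNet(replace(config, **kwargs))


#: the six toggle combinations of the ablation study, in reporting order
ABLATION_GRID: tuple[dict[str, bool], ...] = (
    dict(use_mbi_stem=False, use_dpg=False, use_ssp=False),
    dict(use_mbi_stem=True, use_dpg=True, use_ssp=False),
    dict(use_mbi_stem=False, use_dpg=True, use_ssp=False),
    dict(use_mbi_stem=True, use_dpg=False, use_ssp=True),
    dict(use_mbi_stem=False, use_dpg=True, use_ssp=True),
    dict(use_mbi_stem=True, use_dpg=True, use_ssp=True),
)
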