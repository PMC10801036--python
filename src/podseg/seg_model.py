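"""Width/depth-configurable multi-modal encoder–ASPP–decoder segmentation net.

The architecture mirrors, at configurable scale, a four-stream residual
encoder (one stream per MRI modality) feeding an atrous-spatial-pyramid-
pooling (ASPP) context block and a light decoder:

* per-modality encoder: a stride-2 stem convolution followed by ``n_stages``
  stages of two residual units each (widths double per stage, the first unit
  of every stage past the first downsamples by 2);
* after every stage the per-modality features are fused across modalities by
  channel concatenation and a 1x1 projection — these fused maps are the
  distillation taps;
* ASPP applies parallel dilated 3x3 convolutions (1x1 for rate 1) on the
  deepest fusion and fuses them with a 1x1 projection;
* the decoder concatenates a projected low-level fusion with the upsampled
  ASPP output, applies two depthwise-separable convolution blocks (the
  pre-logit tap), and a 1x1 head produces one logit channel per class.

The desk-scale default (2-D, ``base_width=8``) trains on one CPU; the
paper-scale preset (``base_width=64``) is a configuration, not a tested
surface.  Only ``spatial_dims=2`` is implemented; volumetric inputs are
processed slice-wise by the surrounding tooling.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
import numpy as np

from . import _autograd as ag
from .pod_distill import FeatureMap
from .pseudo_label import ProbabilityMap

__all__ = ["ModelConfig", "SegModel", "build_model", "extend_head",
           "forward_with_taps"]


@dataclass(frozen=True)
class ModelConfig:
    n_modalities: int = 4
    base_width: int = 8
    n_stages: int = 4
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    spatial_dims: int = 2
    head_classes: int = 2
    stem_kernel: int = 3

    def validate(self) -> None:
        problems = []
        if self.n_modalities < 1:
            problems.append("n_modalities must be >= 1")
        if self.base_width < 1:
            problems.append("base_width must be >= 1")
        if self.n_stages < 2:
            problems.append("n_stages must be >= 2")
        if any(r < 1 for r in self.aspp_rates):
            problems.append("aspp_rates must all be >= 1")
        if self.spatial_dims not in (2, 3):
            problems.append("spatial_dims must be 2 or 3")
        if self.head_classes < 2:
            problems.append("head_classes must be >= 2")
        if problems:
            raise ValueError("invalid model config: " + "; ".join(problems))
        if self.spatial_dims == 3:
            raise NotImplementedError(
                "only the 2-D network is implemented; volumetric data is "
                "processed slice-wise"
            )

    def stage_width(self, s: int) -> int:
        return self.base_width * (2 ** s)

    @property
    def aspp_width(self) -> int:
        return 4 * self.base_width

    @property
    def decoder_width(self) -> int:
        return 4 * self.base_width

    @property
    def tap_names(self) -> tuple[str, ...]:
        return tuple(f"stage{s + 1}_fused" for s in range(self.n_stages)) + (
            "decoder_prelogit",
        )


def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class SegModel:
    """Parameter container + forward graph builder."""

    def __init__(self, cfg: ModelConfig, params: dict[str, np.ndarray], seed: int):
        self.cfg = cfg
        self.params = params
        self.seed = seed

    # -- bookkeeping ------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def param_hash(self) -> str:
        """Stable digest of all parameter values (frozen-model contract)."""
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name]).tobytes())
        return h.hexdigest()

    def clone(self) -> "SegModel":
        return SegModel(self.cfg, {k: v.copy() for k, v in self.params.items()},
                        self.seed)

    # -- forward ----------------------------------------------------------

    def _p(self, name: str, train: bool, store: dict[str, ag.Tensor]) -> ag.Tensor:
        if name not in store:
            store[name] = ag.Tensor(self.params[name], requires_grad=train)
        return store[name]

    def forward(
        self, images: np.ndarray, train: bool = False
    ) -> tuple[ag.Tensor, dict[str, ag.Tensor], dict[str, ag.Tensor]]:
        """Run a batch ``N x M x H x W`` through the network.

        Returns ``(logits, taps, param_tensors)``; logits are at input
        resolution.  With ``train=True`` the graph records gradients for all
        parameters.
        """
        cfg = self.cfg
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        n, m, h, w = images.shape
        if m != cfg.n_modalities:
            raise ValueError(f"expected {cfg.n_modalities} modalities, got {m}")
        min_size = 2 ** cfg.n_stages
        if h % min_size or w % min_size:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by {min_size}"
            )
        store: dict[str, ag.Tensor] = {}
        p = lambda name: self._p(name, train, store)

        def gn(x: ag.Tensor, name: str) -> ag.Tensor:
            return ag.group_norm(
                x, p(name + ".g"), p(name + ".be"), _gn_groups(x.shape[1])
            )

        def cn(x: ag.Tensor, name: str, **kw) -> ag.Tensor:
            # conv + group norm (no activation)
            return gn(ag.conv2d(x, p(name + ".w"), p(name + ".b"), **kw), name)

        taps: dict[str, ag.Tensor] = {}
        streams = []
        for mi in range(m):
            x = ag.Tensor(images[:, mi : mi + 1])
            x = ag.relu(cn(x, f"m{mi}.stem", stride=2,
                           padding=cfg.stem_kernel // 2))
            streams.append(x)

        fused_per_stage = []
        for s in range(cfg.n_stages):
            stride = 1 if s == 0 else 2
            new_streams = []
            for mi, x in enumerate(streams):
                for u in range(2):
                    us = stride if u == 0 else 1
                    pre = f"m{mi}.s{s}.u{u}"
                    y = ag.relu(cn(x, pre + ".c1", stride=us, padding=1))
                    y = cn(y, pre + ".c2", padding=1)
                    if us != 1 or x.shape[1] != y.shape[1]:
                        x = ag.conv2d(x, p(pre + ".skip.w"), p(pre + ".skip.b"),
                                      stride=us)
                    x = ag.relu(ag.add(x, y))
                new_streams.append(x)
            streams = new_streams
            fused = ag.concat(streams, axis=1)
            fused = ag.relu(cn(fused, f"fuse{s}"))
            taps[f"stage{s + 1}_fused"] = fused
            fused_per_stage.append(fused)

        # ASPP on the deepest fusion
        deep = fused_per_stage[-1]
        branches = []
        for bi, rate in enumerate(cfg.aspp_rates):
            if rate == 1:
                br = cn(deep, f"aspp{bi}")
            else:
                br = cn(deep, f"aspp{bi}", padding=rate, dilation=rate)
            branches.append(ag.relu(br))
        ctx = ag.relu(cn(ag.concat(branches, axis=1), "aspp_proj"))

        # decoder: project low-level fusion, upsample context, two
        # depthwise-separable blocks, then the classification head
        low = ag.relu(cn(fused_per_stage[0], "dec_low"))
        factor = low.shape[2] // ctx.shape[2]
        dec = ag.concat([low, ag.upsample_nearest(ctx, factor)], axis=1)
        for di in range(2):
            pre = f"dec_sep{di}"
            y = ag.depthwise_conv2d(dec, p(pre + ".dw.w"), p(pre + ".dw.b"),
                                    padding=1)
            dec = ag.relu(cn(y, pre + ".pw"))
        taps["decoder_prelogit"] = dec
        logits = ag.conv2d(dec, p("head.w"), p("head.b"))
        logits = ag.upsample_nearest(logits, 2)  # undo the stem stride
        return logits, taps, store


def _gn_groups(c: int) -> int:
    return max(g for g in (8, 4, 2, 1) if c % g == 0)


def build_model(cfg: ModelConfig, seed: int) -> SegModel:
    """Initialize all parameters (He-normal weights, zero biases) from ``seed``."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}

    def conv_param(name: str, oc: int, ic: int, k: int, norm: bool = True) -> None:
        params[name + ".w"] = _he_init(rng, (oc, ic, k, k))
        params[name + ".b"] = np.zeros(oc, dtype=np.float32)
        if norm:
            params[name + ".g"] = np.ones(oc, dtype=np.float32)
            params[name + ".be"] = np.zeros(oc, dtype=np.float32)

    for mi in range(cfg.n_modalities):
        conv_param(f"m{mi}.stem", cfg.base_width, 1, cfg.stem_kernel)
        w_in = cfg.base_width
        for s in range(cfg.n_stages):
            w_out = cfg.stage_width(s)
            stride = 1 if s == 0 else 2
            for u in range(2):
                us = stride if u == 0 else 1
                pre = f"m{mi}.s{s}.u{u}"
                conv_param(pre + ".c1", w_out, w_in, 3)
                conv_param(pre + ".c2", w_out, w_out, 3)
                if us != 1 or w_in != w_out:
                    conv_param(pre + ".skip", w_out, w_in, 1, norm=False)
                w_in = w_out
    for s in range(cfg.n_stages):
        w_s = cfg.stage_width(s)
        conv_param(f"fuse{s}", w_s, cfg.n_modalities * w_s, 1)

    deep_w = cfg.stage_width(cfg.n_stages - 1)
    for bi, rate in enumerate(cfg.aspp_rates):
        conv_param(f"aspp{bi}", cfg.aspp_width, deep_w, 1 if rate == 1 else 3)
    conv_param("aspp_proj", cfg.aspp_width, cfg.aspp_width * len(cfg.aspp_rates), 1)

    low_proj = cfg.base_width
    conv_param("dec_low", low_proj, cfg.stage_width(0), 1)
    dec_in = low_proj + cfg.aspp_width
    for di in range(2):
        params[f"dec_sep{di}.dw.w"] = _he_init(rng, (dec_in, 3, 3))
        params[f"dec_sep{di}.dw.b"] = np.zeros(dec_in, dtype=np.float32)
        conv_param(f"dec_sep{di}.pw", cfg.decoder_width, dec_in, 1)
        dec_in = cfg.decoder_width
    conv_param("head", cfg.head_classes, cfg.decoder_width, 1, norm=False)
    return SegModel(cfg, params, seed)


def extend_head(model: SegModel, new_classes: list[int], seed: int | None = None,
                init_std: float = 0.01) -> SegModel:
    """Return a copy whose head has ``len(new_classes)`` extra output channels.

    All pre-existing parameters are copied value-identically; new head rows
    are drawn zero-mean with ``init_std`` from a seeded generator, new biases
    are zero.
    """
    n_new = len(new_classes)
    out = model.clone()
    if n_new == 0:
        return out
    rng = np.random.default_rng(model.seed + 1 if seed is None else seed)
    w = out.params["head.w"]
    extra = rng.normal(0.0, init_std, size=(n_new,) + w.shape[1:]).astype(np.float32)
    out.params["head.w"] = np.concatenate([w, extra], axis=0)
    out.params["head.b"] = np.concatenate(
        [out.params["head.b"], np.zeros(n_new, dtype=np.float32)]
    )
    out.cfg = replace(model.cfg, head_classes=model.cfg.head_classes + n_new)
    return out


def forward_with_taps(
    model: SegModel, image: np.ndarray
) -> tuple[ProbabilityMap, dict[str, FeatureMap]]:
    """Inference on one ``M x H x W`` image.

    Returns the per-pixel class distribution (``H x W x K``, channel 0 =
    background) and the distillation taps as ``H x W x C`` feature maps in a
    stable order.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ValueError("expected a single M x H x W image")
    logits, taps, _ = model.forward(image[None], train=False)
    probs = ag.softmax(logits.data, axis=1)[0]  # K x H x W
    prob_map = ProbabilityMap(values=np.moveaxis(probs.astype(float), 0, -1))
    feature_taps = {
        name: FeatureMap(
            values=np.moveaxis(t.data[0].astype(float), 0, -1), layer_index=i
        )
        for i, (name, t) in enumerate(taps.items())
    }
    return prob_map, feature_taps
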