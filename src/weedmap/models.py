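"""Fully convolutional segmentation models: FCN-8s and the modified FCN-4s.

Both architectures share a VGG-16-style backbone whose fully connected
layers are converted to convolutions (fc6 as a 7×7 convolution, fc7/fc8 as
1×1), so the network maps an H×W image to an H×W×K score map end-to-end.

* **fcn8s** — five pooling stages (output stride 32 at fc8) with a skip
  architecture: the fc8 scores are fused with 1×1-scored copies of the
  pool5 and pool4 feature maps, then upsampled to input resolution.
* **fcn4s** — the modified architecture: the fifth pooling operation and
  the skip fusions are removed, so the backbone stops at stride 16, fc6/fc7
  carry 2048 feature maps (half of fcn8s' 4096), and a single ×16
  transposed convolution restores the input resolution.  The narrower head
  plus the missing skip heads make it strictly smaller in parameters.

A ``backbone_scale`` knob multiplies all channel widths so the full
architecture (scale 1) and a CPU-sized replica (e.g. scale 1/8) share the
same code path and contracts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .georaster import CODE_IGNORE, GeoRaster, GeoRef, LabelMap, ScoreMap

#: VGG-16 convolution widths per stage (before scaling).
VGG16_STAGES = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))

#: Stride of each pooled stage output relative to the input.
STAGE_STRIDE = {"pool1": 2, "pool2": 4, "pool3": 8, "pool4": 16, "pool5": 32}


@dataclass(frozen=True)
class FCNConfig:
    """Architecture description for :func:`build_model`."""

    variant: str = "fcn4s"
    num_classes: int = 3
    fc_channels: int | None = None  # default: 2048 for fcn4s, 4096 for fcn8s
    backbone_scale: float = 1.0
    upsample_init: str = "learned_bilinear"  # or "fixed_bilinear"
    fusion_taps: tuple[str, ...] | None = None  # fcn8s default: ("pool5", "pool4")
    pretrained_backbone: str | None = None
    backbone_init: str = "dirac"  # identity-preserving init for from-scratch training
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("fcn8s", "fcn4s"):
            raise ValueError(f"unknown variant: {self.variant!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be ≥ 2")
        if not 0 < self.backbone_scale <= 1:
            raise ValueError("backbone_scale must be in (0, 1]")
        if self.upsample_init not in ("fixed_bilinear", "learned_bilinear"):
            raise ValueError(f"unknown upsample_init: {self.upsample_init!r}")
        if self.backbone_init not in ("he", "dirac"):
            raise ValueError(f"unknown backbone_init: {self.backbone_init!r}")
        fc = self.resolved_fc_channels
        if fc < self.num_classes:
            raise ValueError("fc_channels must be ≥ num_classes")
        if self.scaled(min(w for st in VGG16_STAGES for w in st)) < 1:
            raise ValueError("backbone_scale too small: a stage width would vanish")
        if self.pretrained_backbone is not None and self.backbone_scale < 1:
            raise ValueError("pretrained weights require backbone_scale == 1")
        taps = self.resolved_fusion_taps
        if any(t not in STAGE_STRIDE for t in taps):
            raise ValueError(f"unknown fusion tap in {taps}")

    @property
    def resolved_fc_channels(self) -> int:
        if self.fc_channels is not None:
            return self.fc_channels
        return 2048 if self.variant == "fcn4s" else 4096

    @property
    def resolved_fusion_taps(self) -> tuple[str, ...]:
        if self.variant == "fcn4s":
            return ()
        return ("pool5", "pool4") if self.fusion_taps is None else tuple(self.fusion_taps)

    def scaled(self, width: int) -> int:
        return max(1, round(width * self.backbone_scale))


class FCNModel:
    """A built segmentation network with explicit forward/backward passes."""

    def __init__(self, config: FCNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.num_classes
        fc = config.scaled(config.resolved_fc_channels)
        self.has_pool5 = config.variant == "fcn8s"
        self.fusion_taps = config.resolved_fusion_taps
        self.num_pool_stages = 5 if self.has_pool5 else 4
        #: stride of the coarsest (fc8) score map
        self.head_stride = 32 if self.has_pool5 else 16
        #: input dims must be divisible by this (else reflect-pad + crop)
        self.output_stride = self.head_stride

        self.stages: list[tuple[str, nn.Sequential]] = []
        in_ch = 3
        for i, widths in enumerate(VGG16_STAGES, start=1):
            layers: list[nn.Layer] = []
            for j, w in enumerate(widths, start=1):
                w = config.scaled(w)
                layers += [nn.Conv2d(in_ch, w, 3, name=f"conv{i}_{j}", rng=rng,
                                     init=config.backbone_init), nn.ReLU()]
                in_ch = w
            if i < 5 or self.has_pool5:
                layers.append(nn.MaxPool2d())
            self.stages.append((f"pool{i}", nn.Sequential(*layers)))
        stage_out_ch = {
            name: config.scaled(widths[-1])
            for (name, _), widths in zip(self.stages, VGG16_STAGES)
        }

        self.head = nn.Sequential(
            nn.Conv2d(in_ch, fc, 7, name="fc6", rng=rng), nn.ReLU(),
            nn.Conv2d(fc, fc, 1, name="fc7", rng=rng), nn.ReLU(),
            nn.Conv2d(fc, k, 1, name="fc8", rng=rng),
        )
        self.fc6 = self.head.layers[0]
        self.fc7 = self.head.layers[2]
        self.fc8 = self.head.layers[4]

        frozen = config.upsample_init == "fixed_bilinear"
        self.score_heads: dict[str, nn.Conv2d] = {
            tap: nn.Conv2d(stage_out_ch[tap], k, 1, name=f"score_{tap}", init="zero")
            for tap in self.fusion_taps
        }
        # fusion plan: walk from head_stride down through tap strides, then ×rest
        self.fusion_steps: list[tuple[str, object]] = []
        self.upsamplers: list[nn.ConvTranspose2d] = []
        stride = self.head_stride
        for tap in sorted(self.fusion_taps, key=lambda t: -STAGE_STRIDE[t]):
            ts = STAGE_STRIDE[tap]
            if ts < stride:
                f = stride // ts
                up = nn.ConvTranspose2d(k, k, 2 * f, f, f // 2,
                                        name=f"up{stride}to{ts}", frozen=frozen)
                self.upsamplers.append(up)
                self.fusion_steps.append(("up", up))
                stride = ts
            self.fusion_steps.append(("add", tap))
        final = nn.ConvTranspose2d(k, k, 2 * stride, stride, stride // 2,
                                   name=f"up{stride}tofull", frozen=frozen)
        self.upsamplers.append(final)
        self.fusion_steps.append(("up", final))

        if config.pretrained_backbone is not None:
            self._load_state(dict(np.load(config.pretrained_backbone)), strict=False)

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[nn.Param]:
        out = []
        for _, seq in self.stages:
            out += seq.params()
        out += self.head.params()
        for tap in self.fusion_taps:
            out += self.score_heads[tap].params()
        for up in self.upsamplers:
            out += up.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data for p in self.params()}

    def _load_state(self, state: dict[str, np.ndarray], strict: bool = True) -> None:
        own = {p.name: p for p in self.params()}
        for name, arr in state.items():
            if name not in own:
                if strict:
                    raise KeyError(f"unexpected parameter {name!r}")
                continue
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name!r}: "
                                 f"{own[name].data.shape} vs {arr.shape}")
            own[name].data = arr.astype(np.float32).copy()
            own[name].grad = np.zeros_like(own[name].data)
        if strict:
            missing = set(own) - set(state)
            if missing:
                raise KeyError(f"missing parameters: {sorted(missing)}")

    # -- forward / backward -------------------------------------------------

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """Forward an (N, 3, H, W) float batch to (N, K, H, W) logits.

        H and W must be divisible by the model's output stride.
        """
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        h, w = x.shape[2:]
        s = self.output_stride
        if h % s or w % s:
            raise ValueError(f"spatial dims {h}×{w} not divisible by stride {s}")
        acts: dict[str, np.ndarray] = {}
        out = x
        for name, seq in self.stages:
            out = seq.forward(out)
            acts[name] = out
        scores = self.head.forward(out)
        for kind, ref in self.fusion_steps:
            if kind == "add":
                scores = scores + self.score_heads[ref].forward(acts[ref])
            else:
                scores = ref.forward(scores)
        return scores

    def backward_batch(self, dscores: np.ndarray) -> None:
        """Accumulate parameter gradients for the last :meth:`forward_batch`."""
        g = dscores
        tap_grads: dict[str, np.ndarray] = {}
        for kind, ref in reversed(self.fusion_steps):
            if kind == "add":
                tap_grads[ref] = self.score_heads[ref].backward(g)
            else:
                g = ref.backward(g)
        g = self.head.backward(g)
        for name, seq in reversed(self.stages):
            if name in tap_grads:
                g = g + tap_grads[name]
            g = seq.backward(g)

    # -- inference ----------------------------------------------------------

    @staticmethod
    def preprocess(image: np.ndarray) -> np.ndarray:
        """H×W×3 uint8 → (3, H, W) float32 in roughly [-0.5, 0.5]."""
        return (np.asarray(image, dtype=np.float32) / 255.0 - 0.5).transpose(2, 0, 1)

    def forward(self, image: GeoRaster | np.ndarray) -> ScoreMap:
        """Score a single image; reflect-pads to the stride, crops back."""
        geo = image.geo if isinstance(image, GeoRaster) else GeoRef(1.0)
        arr = image.pixels if isinstance(image, GeoRaster) else np.asarray(image)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"expected an H×W×3 image, got shape {arr.shape}")
        h, w = arr.shape[:2]
        s = self.output_stride
        ph, pw = (-h) % s, (-w) % s
        x = self.preprocess(arr)[None]
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        scores = self.forward_batch(x)[0, :, :h, :w]
        return ScoreMap(scores.transpose(1, 2, 0), geo)


def build_model(config: FCNConfig) -> FCNModel:
    """Construct a segmentation model from its architecture description."""
    return FCNModel(config)


def predict_labels(scores: ScoreMap, ignore_mask: np.ndarray | None = None) -> LabelMap:
    """Per-pixel argmax decode; ties resolve to the lowest class code."""
    codes = np.argmax(scores.scores, axis=2).astype(np.uint8)
    if ignore_mask is not None:
        codes = codes.copy()
        codes[ignore_mask] = CODE_IGNORE
    return LabelMap(codes, scores.geo)


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path: str | Path, model: FCNModel) -> None:
    """Write weights (.npz) plus the architecture JSON alongside."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    cfg = asdict(model.config)
    cfg["fusion_taps"] = list(model.config.fusion_taps) if model.config.fusion_taps else None
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> FCNModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    cfg = json.loads(path.with_suffix(".json").read_text())
    if cfg.get("fusion_taps") is not None:
        cfg["fusion_taps"] = tuple(cfg["fusion_taps"])
    model = FCNModel(FCNConfig(**cfg))
    model._load_state(dict(np.load(path)), strict=True)
    return model
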