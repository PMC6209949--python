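"""Training on labeled patches and whole-field inference.

Training minimises per-pixel softmax cross-entropy (ignore-coded pixels
excluded) with SGD + momentum, selecting the checkpoint with the best
validation mean IU.  Inference supports both field-mapping workflows:

* **workflow 1 (mosaic-then-label)** — tile the assembled field raster,
  score each patch, stitch the predicted labels back;
* **workflow 2 (label-then-mosaic)** — score each collected image in place,
  then mosaic the per-image score maps using their geotransforms.

With a zero-overlap flight set whose images coincide with the tile grid the
two workflows are pixel-identical by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import nn
from .georaster import CODE_IGNORE, GeoRaster, LabelMap
from .metrics import evaluate
from .models import FCNModel, predict_labels
from .tiling import TilePlan, mosaic_predictions, split_raster, stitch_labels


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for from-scratch training on synthetic patches."""

    learning_rate: float = 2e-3
    momentum: float = 0.9
    weight_decay: float = 5e-4
    optimizer: str = "adam"  # or "sgd"
    epochs: int = 10
    batch_size: int = 1
    ignore_code: int = CODE_IGNORE
    seed: int = 0
    augmentations: str = "flips"  # or "none"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("optimisation scalars must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer: {self.optimizer!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be ≥ 1")
        if self.augmentations not in ("none", "flips"):
            raise ValueError(f"unknown augmentations: {self.augmentations!r}")


@dataclass(frozen=True)
class SplitSpec:
    """Random validation/test split with floor rounding (30% of 182 → 54/128)."""

    val_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")


def split_dataset(n_samples: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (validation, test) index split, deterministic per seed."""
    if n_samples < 2:
        raise ValueError(f"need at least 2 samples to split, got {n_samples}")
    n_val = math.floor(spec.val_fraction * n_samples)
    perm = np.random.default_rng(spec.seed).permutation(n_samples)
    return np.sort(perm[:n_val]), np.sort(perm[n_val:])


Scene = tuple  # (GeoRaster | H×W×3 array, LabelMap | H×W codes)


def _as_arrays(scene: Scene) -> tuple[np.ndarray, np.ndarray]:
    img, lab = scene
    img = img.pixels if isinstance(img, GeoRaster) else np.asarray(img)
    lab = lab.codes if isinstance(lab, LabelMap) else np.asarray(lab)
    return img, lab


def train(model: FCNModel, train_scenes: Sequence[Scene],
          val_scenes: Sequence[Scene], config: TrainConfig,
          ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Optimise the model; returns (best state dict, per-epoch metric log).

    The best checkpoint is the epoch with the highest validation mean IU.
    All patches in a batch must share dimensions (they do, by tiling).
    """
    pairs = [_as_arrays(s) for s in train_scenes]
    if not pairs:
        raise ValueError("no training scenes")
    if not any((lab != config.ignore_code).any() for _, lab in pairs):
        raise ValueError("training scenes contain no labeled pixels")
    rng = np.random.default_rng(config.seed)
    if config.optimizer == "adam":
        opt = nn.Adam(model.params(), config.learning_rate,
                      weight_decay=config.weight_decay)
    else:
        opt = nn.SGD(model.params(), config.learning_rate, config.momentum,
                     config.weight_decay)
    log_rows = []
    best = {"mean_iu": -1.0, "state": None}
    n = len(pairs)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        flips = rng.integers(0, 2, size=(n, 2)) if config.augmentations == "flips" \
            else np.zeros((n, 2), dtype=int)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, ys = [], []
            for i in idx:
                img, lab = pairs[i]
                fl, fu = flips[i]
                if fl:
                    img, lab = img[:, ::-1], lab[:, ::-1]
                if fu:
                    img, lab = img[::-1], lab[::-1]
                xs.append(FCNModel.preprocess(np.ascontiguousarray(img)))
                ys.append(np.ascontiguousarray(lab))
            xb, yb = np.stack(xs), np.stack(ys)
            if not (yb != config.ignore_code).any():
                continue  # all-ignore batch carries no signal
            scores = model.forward_batch(xb)
            loss, dscores = nn.softmax_cross_entropy(scores, yb, config.ignore_code)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={config.learning_rate}); "
                    "reduce the learning rate")
            opt.zero_grad()
            model.backward_batch(dscores)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_scenes:
            rep = evaluate_scenes(model, val_scenes)
            row["val_accuracy"], row["val_mean_iu"] = rep.overall_accuracy, rep.mean_iu
        else:
            row["val_accuracy"] = row["val_mean_iu"] = float("nan")
        log_rows.append(row)
        if not val_scenes or row["val_mean_iu"] >= best["mean_iu"]:
            best = {"mean_iu": row["val_mean_iu"],
                    "state": {k: v.copy() for k, v in model.state_dict().items()}}
    model._load_state(best["state"])
    return best["state"], pd.DataFrame(log_rows)


def evaluate_scenes(model: FCNModel, scenes: Iterable[Scene]):
    """Pooled pixel evaluation of the model over image–GT pairs."""
    from .metrics import ConfusionMatrix, accumulate_confusion, row_normalize
    from .metrics import EvalReport, mean_iu, overall_accuracy, per_class_iu

    total = None
    for scene in scenes:
        img, lab = _as_arrays(scene)
        pred = predict_labels(model.forward(img))
        cm = accumulate_confusion(lab, pred.codes)
        total = cm.counts if total is None else total + cm.counts
    cm = ConfusionMatrix(total)
    rn, _ = row_normalize(cm)
    return EvalReport(overall_accuracy(cm), mean_iu(cm), per_class_iu(cm), rn)


def infer_field(model: FCNModel, raster: GeoRaster, plan: TilePlan | None = None,
                ) -> LabelMap:
    """Workflow 1: tile the field raster, score tiles, stitch labels back."""
    h, w = raster.shape
    if plan is None:
        plan = TilePlan.for_shape(h, w)
    tiles = split_raster(raster, plan)
    labeled = []
    for t in tiles:
        pred = predict_labels(model.forward(t.data))
        labeled.append(pred.codes)
    out = stitch_labels(labeled, [t.placement for t in tiles],
                        out_shape=(h, w), geo=raster.geo)
    if raster.nodata is not None:
        nodata = (raster.pixels == raster.nodata).all(axis=2)
        codes = out.codes.copy()
        codes[nodata] = CODE_IGNORE
        out = LabelMap(codes, out.geo)
    return out


def infer_then_mosaic(model: FCNModel, flight_images: Sequence[GeoRaster],
                      ) -> LabelMap:
    """Workflow 2: score each collected image, then mosaic the score maps."""
    if not flight_images:
        raise ValueError("no flight images")
    return mosaic_predictions(model.forward(img) for img in flight_images)
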