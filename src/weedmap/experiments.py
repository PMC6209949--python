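"""Canned reference experiments used by the benchmark script and tests.

The cross-date benchmark reproduces the study design at desk scale: train on
patches from one acquisition date, evaluate on a field imaged on a later
date with a different appearance (illumination/texture), then derive the
prescription-map threshold sweep from the predicted weed cover map.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from .metrics import EvalReport
from .models import FCNConfig, build_model
from .prescription import sweep_thresholds
from .synthetic import FieldSpec, generate_scene, realized_weed_coverage
from .tiling import TilePlan, split_raster
from .training import TrainConfig, evaluate_scenes, infer_field, train


@dataclass
class CrossDateResult:
    report: EvalReport          # pooled date-2 pixel metrics
    train_log: pd.DataFrame     # per-epoch loss and validation metrics
    sweep: pd.DataFrame         # prescription threshold sweep on date-2
    realized_coverage: float    # weed coverage of the date-2 ground truth


def cross_date_benchmark(seed: int = 0, field_px: int = 2000, patch_px: int = 256,
                         weed_coverage: float = 0.30, backbone_scale: float = 0.125,
                         epochs: int = 10, appearance_shift: float = 0.5,
                         n_val_tiles: int = 4) -> CrossDateResult:
    """Train FCN-4s on date-1 patches and evaluate on the full date-2 field.

    Defaults: a 2000×2000 px field at 0.5 cm/pixel (10×10 m) with 30% weed
    coverage, 256×256 training patches, a 1/8-width backbone, and at most
    10 training epochs.
    """
    spec1 = FieldSpec(field_px, field_px, target_weed_coverage=weed_coverage,
                      seed=seed * 101 + 11)
    spec2 = dataclasses.replace(spec1, seed=seed * 101 + 12,
                                appearance_shift=appearance_shift)
    date1, date2 = generate_scene(spec1), generate_scene(spec2)

    plan = TilePlan.for_shape(field_px, field_px, patch_px)
    tiles1 = [(ti.data.pixels, tl.data.codes)
              for ti, tl in zip(split_raster(date1.image, plan),
                                split_raster(date1.labels, plan))]
    tiles2 = [(ti.data.pixels, tl.data.codes)
              for ti, tl in zip(split_raster(date2.image, plan),
                                split_raster(date2.labels, plan))]

    model = build_model(FCNConfig("fcn4s", backbone_scale=backbone_scale,
                                  seed=seed + 3))
    config = TrainConfig(epochs=epochs, seed=seed + 5)
    # a small validation subset monitors training; the full date-2 field is
    # the held-out evaluation target
    stride = max(1, len(tiles2) // n_val_tiles)
    _, log = train(model, tiles1, tiles2[::stride][:n_val_tiles], config)

    report = evaluate_scenes(model, tiles2)
    pred_map = infer_field(model, date2.image, plan)
    sweep = sweep_thresholds(pred_map, date2.labels)
    return CrossDateResult(report, log, sweep, realized_weed_coverage(date2.labels))
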