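"""One-config pipeline: generate → tile → train → infer → evaluate → prescribe.

Each stage reads its inputs from, and writes its artifacts under, the
configured output directory, so stages can be run one at a time or end to
end.  A JSON manifest records completed stages and their artifacts;
re-running a completed stage is a no-op unless forced.  One global seed is
fanned out to the stages with fixed offsets, making a full run reproducible
from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .georaster import read_image, read_labels, write_labels
from .metrics import evaluate
from .models import FCNConfig, build_model, load_checkpoint, save_checkpoint
from .prescription import (
    DEFAULT_THRESHOLDS,
    apply_threshold,
    chessboard_coverage,
    prescription_to_geojson,
    sweep_thresholds,
)
from .synthetic import FieldSpec, generate_dataset, load_manifest
from .tiling import TilePlan, split_raster
from .training import SplitSpec, TrainConfig, evaluate_scenes, infer_field, split_dataset, train

log = logging.getLogger("weedmap")

STAGES = ("generate", "tile", "train", "infer", "evaluate", "prescribe")

# fixed per-stage seed offsets fanned out from the global seed
SEED_OFFSETS = {"date1": 1, "date2": 2, "model": 3, "split": 4, "train": 5}


@dataclass
class PipelineConfig:
    """All pipeline settings; mirrors the YAML config layout."""

    out_dir: str = "weedmap_out"
    seed: int = 0
    field: dict = dc_field(default_factory=dict)        # FieldSpec kwargs (minus seed)
    date2: dict = dc_field(default_factory=dict)        # overrides for the second date
    tiling: dict = dc_field(default_factory=dict)       # {"patch_px": int}
    model: dict = dc_field(default_factory=dict)        # FCNConfig kwargs (minus seed)
    train: dict = dc_field(default_factory=dict)        # TrainConfig kwargs (minus seed)
    split: dict = dc_field(default_factory=dict)        # SplitSpec kwargs (minus seed)
    prescription: dict = dc_field(default_factory=dict) # {"cell_size_m", "thresholds", "map_threshold"}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**data)

    def field_spec(self, date: int) -> FieldSpec:
        kwargs = dict(self.field)
        kwargs.setdefault("width_px", 1024)
        kwargs.setdefault("height_px", 1024)
        if date == 2:
            kwargs.update(self.date2)
            kwargs.setdefault("appearance_shift", 0.3)
        key = "date1" if date == 1 else "date2"
        kwargs["seed"] = self.seed + SEED_OFFSETS[key]
        return FieldSpec(**kwargs)

    @property
    def patch_px(self) -> int:
        return int(self.tiling.get("patch_px", 256))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "pipeline_manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() else {}

    def done(self, stage: str) -> bool:
        entry = self.data.get(stage)
        if not entry:
            return False
        return all((self.path.parent / p).exists() for p in entry["artifacts"])

    def record(self, stage: str, artifacts: list[Path], out_dir: Path) -> None:
        self.data[stage] = {
            "artifacts": [str(p.relative_to(out_dir)) for p in artifacts],
            "hashes": {str(p.relative_to(out_dir)): _sha256(p) for p in artifacts},
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=2))


def _load_tiles(tile_dir: Path, manifest: pd.DataFrame) -> list[tuple]:
    return [
        (read_image(tile_dir / r.tile_path).pixels, read_labels(tile_dir / r.label_path).codes)
        for r in manifest.itertuples()
    ]


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES,
                 force: bool = False) -> dict:
    """Run the requested stages in order; returns the stage→artifact manifest."""
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    for stage in STAGES:
        if stage not in stages:
            continue
        if manifest.done(stage) and not force:
            log.info("stage %s already complete, skipping (use force to re-run)", stage)
            continue
        t0 = time.time()
        log.info("stage %s: starting", stage)
        artifacts = _RUNNERS[stage](config, out)
        manifest.record(stage, artifacts, out)
        log.info("stage %s: done in %.1f s", stage, time.time() - t0)
    return manifest.data


# -- stage runners -----------------------------------------------------------

def _stage_generate(cfg: PipelineConfig, out: Path) -> list[Path]:
    scene_dir = out / "scenes"
    generate_dataset(cfg.field_spec(1), cfg.field_spec(2), scene_dir)
    names = ["manifest.csv", "date1_image.png", "date1_labels.png",
             "date2_image.png", "date2_labels.png"]
    return [scene_dir / n for n in names]


def _stage_tile(cfg: PipelineConfig, out: Path) -> list[Path]:
    from .georaster import write_image

    scene_dir = out / "scenes"
    roles = load_manifest(scene_dir)
    artifacts = []
    for r in roles.itertuples():
        img = read_image(scene_dir / r.image_path)
        lab = read_labels(scene_dir / r.label_path)
        h, w = img.shape
        plan = TilePlan.for_shape(h, w, cfg.patch_px)
        tile_dir = out / "tiles" / f"date{r.date}"
        tile_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for ti, tl in zip(split_raster(img, plan), split_raster(lab, plan)):
            ip, lp = f"tile_{ti.row_off}_{ti.col_off}.png", f"labels_{ti.row_off}_{ti.col_off}.png"
            write_image(tile_dir / ip, ti.data)
            write_labels(tile_dir / lp, tl.data)
            rows.append({"tile_path": ip, "label_path": lp,
                         "row_off": ti.row_off, "col_off": ti.col_off})
        tm = tile_dir / "tiles.csv"
        pd.DataFrame(rows).to_csv(tm, index=False)
        artifacts.append(tm)
    return artifacts


def _stage_train(cfg: PipelineConfig, out: Path) -> list[Path]:
    t1 = _load_tiles(out / "tiles/date1", pd.read_csv(out / "tiles/date1/tiles.csv"))
    d2_manifest = pd.read_csv(out / "tiles/date2/tiles.csv")
    t2 = _load_tiles(out / "tiles/date2", d2_manifest)
    split = SplitSpec(**{**cfg.split, "seed": cfg.seed + SEED_OFFSETS["split"]})
    val_idx, _ = split_dataset(len(t2), split)
    model = build_model(FCNConfig(**{**cfg.model, "seed": cfg.seed + SEED_OFFSETS["model"]}))
    tc = TrainConfig(**{**cfg.train, "seed": cfg.seed + SEED_OFFSETS["train"]})
    _, metric_log = train(model, t1, [t2[i] for i in val_idx], tc)
    ckpt = out / "checkpoint.npz"
    save_checkpoint(ckpt, model)
    metric_log.to_csv(out / "train_log.csv", index=False)
    last = metric_log.iloc[-1]
    log.info("train: final val accuracy %.4f, mean IU %.4f",
             last.val_accuracy, last.val_mean_iu)
    np.save(out / "val_indices.npy", val_idx)
    return [ckpt, ckpt.with_suffix(".json"), out / "train_log.csv", out / "val_indices.npy"]


def _stage_infer(cfg: PipelineConfig, out: Path) -> list[Path]:
    model = load_checkpoint(out / "checkpoint.npz")
    roles = load_manifest(out / "scenes")
    row = roles[roles.role == "valtest"].iloc[0]
    img = read_image(out / "scenes" / row.image_path)
    h, w = img.shape
    pred = infer_field(model, img, TilePlan.for_shape(h, w, cfg.patch_px))
    pred_path = out / "predicted_map.png"
    write_labels(pred_path, pred)
    return [pred_path]


def _stage_evaluate(cfg: PipelineConfig, out: Path) -> list[Path]:
    roles = load_manifest(out / "scenes")
    row = roles[roles.role == "valtest"].iloc[0]
    gt = read_labels(out / "scenes" / row.label_path)
    pred = read_labels(out / "predicted_map.png")
    rep = evaluate(gt, pred)
    rep.to_json(out / "eval.json")
    from .metrics import accumulate_confusion
    accumulate_confusion(gt, pred).to_csv(out / "confusion.csv")
    log.info("evaluate: overall accuracy %.4f, mean IU %.4f",
             rep.overall_accuracy, rep.mean_iu)
    return [out / "eval.json", out / "confusion.csv"]


def _stage_prescribe(cfg: PipelineConfig, out: Path) -> list[Path]:
    roles = load_manifest(out / "scenes")
    row = roles[roles.role == "valtest"].iloc[0]
    gt = read_labels(out / "scenes" / row.label_path)
    pred = read_labels(out / "predicted_map.png")
    pcfg = cfg.prescription
    cell = float(pcfg.get("cell_size_m", 0.5))
    thresholds = tuple(pcfg.get("thresholds", DEFAULT_THRESHOLDS))
    sweep = sweep_thresholds(pred, gt, thresholds, cell)
    sweep.to_csv(out / "sweep.csv", index=False)
    tau = float(pcfg.get("map_threshold", 0.0))
    grid = chessboard_coverage(pred, cell)
    pmap = apply_threshold(grid, tau)
    (out / "prescription.geojson").write_text(
        json.dumps(prescription_to_geojson(pmap, grid)))
    row0 = sweep.iloc[0]
    log.info("prescribe: τ=%.2f accuracy %.4f, herbicide saving %.1f%%",
             row0.threshold, row0.accuracy, 100 * row0.herbicide_saving)
    return [out / "sweep.csv", out / "prescription.geojson"]


_RUNNERS = {
    "generate": _stage_generate,
    "tile": _stage_tile,
    "train": _stage_train,
    "infer": _stage_infer,
    "evaluate": _stage_evaluate,
    "prescribe": _stage_prescribe,
}
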