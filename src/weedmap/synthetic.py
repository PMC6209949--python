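"""Synthetic rice-field scene generator.

Real UAV ortho-imagery of weed-infested paddies is rarely shareable, so the
whole pipeline is exercised on generated scenes that reproduce the features
the method depends on: a rice canopy background, spatially autocorrelated
weed patches (smoothed Gaussian noise thresholded at the quantile matching
the requested coverage), non-vegetation gaps and margins, ~0.5 cm/pixel
ground sampling, and a between-date appearance shift (global gain/offset
plus re-drawn texture noise) that separates the training date from the
evaluation date.  Class appearance is controlled by mean colours with
additive texture noise, so classes are separable but not trivially so.

Everything is a pure function of the :class:`FieldSpec` — identical specs
(including the seed) give bit-identical scenes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .georaster import (
    CODE_IGNORE,
    CODE_OTHERS,
    CODE_RICE,
    CODE_WEEDS,
    GeoRaster,
    GeoRef,
    LabelMap,
    read_image,
    read_labels,
    write_image,
    write_labels,
)

#: Mean RGB of each class before illumination/texture effects.
CLASS_COLORS = {
    CODE_OTHERS: (105.0, 92.0, 70.0),   # wet soil / water gaps
    CODE_RICE: (70.0, 145.0, 75.0),     # rice canopy
    CODE_WEEDS: (170.0, 185.0, 60.0),   # yellow-green sedge/grass patches
}


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic field scene."""

    width_px: int
    height_px: int
    gsd_m: float = 0.005
    target_weed_coverage: float = 0.30
    weed_patch_scale_px: float = 40.0
    nonveg_coverage: float = 0.05
    appearance_shift: float = 0.0
    seed: int = 0
    texture_sigma: float = 9.0

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError(f"width_px must be ≥ 1, got {self.width_px}")
        if self.height_px < 1:
            raise ValueError(f"height_px must be ≥ 1, got {self.height_px}")
        if not self.gsd_m > 0:
            raise ValueError(f"gsd_m must be positive, got {self.gsd_m}")
        if not 0 <= self.target_weed_coverage <= 1:
            raise ValueError(
                f"target_weed_coverage must be in [0, 1], got {self.target_weed_coverage}")
        if not 0 <= self.nonveg_coverage < 1:
            raise ValueError(
                f"nonveg_coverage must be in [0, 1), got {self.nonveg_coverage}")
        if self.target_weed_coverage + self.nonveg_coverage >= 1:
            raise ValueError(
                "target_weed_coverage + nonveg_coverage must be < 1, got "
                f"{self.target_weed_coverage} + {self.nonveg_coverage}")
        if not 0 <= self.appearance_shift <= 1:
            raise ValueError(
                f"appearance_shift must be in [0, 1], got {self.appearance_shift}")
        if not self.weed_patch_scale_px > 0:
            raise ValueError(
                f"weed_patch_scale_px must be positive, got {self.weed_patch_scale_px}")

    @property
    def geo(self) -> GeoRef:
        # field occupies eastings [0, W·gsd], northings [0, H·gsd]
        return GeoRef(self.gsd_m, (0.0, self.height_px * self.gsd_m))


@dataclass
class LabeledScene:
    """An image–ground-truth pair sharing dimensions and geo-metadata."""

    image: GeoRaster
    labels: LabelMap
    spec: FieldSpec

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must share dimensions")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")


def _layout_labels(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    n_total = h * w
    labels = np.full((h, w), CODE_RICE, dtype=np.uint8)

    # "others": field margins plus scattered gaps — a distance-to-edge ramp
    # biases a smoothed noise field toward the borders, thresholded at the
    # exact pixel count matching nonveg_coverage.
    n_others = round(spec.nonveg_coverage * n_total)
    if n_others > 0:
        score = _smooth_noise(rng, (h, w), max(2.0, spec.weed_patch_scale_px / 3))
        ry = np.minimum(np.arange(h), np.arange(h)[::-1])[:, None]
        rx = np.minimum(np.arange(w), np.arange(w)[::-1])[None, :]
        edge_px = np.minimum(ry, rx)
        ramp_width = max(4.0, 0.02 * min(h, w))
        score = score + 2.5 * np.exp(-edge_px / ramp_width)
        flat = np.argpartition(score.ravel(), -n_others)[-n_others:]
        labels.ravel()[flat] = CODE_OTHERS

    # weeds: blob model — smoothed noise, top-k among remaining vegetation
    # pixels so the realized coverage hits the target up to integer rounding.
    n_weeds = round(spec.target_weed_coverage * n_total)
    if n_weeds > 0:
        blob = _smooth_noise(rng, (h, w), spec.weed_patch_scale_px)
        veg = labels.ravel() == CODE_RICE
        veg_idx = np.flatnonzero(veg)
        n_weeds = min(n_weeds, veg_idx.size)  # rounding guard on tiny fields
        order = np.argpartition(blob.ravel()[veg_idx], -n_weeds)[-n_weeds:]
        labels.ravel()[veg_idx[order]] = CODE_WEEDS
    return labels


def _render_image(spec: FieldSpec, labels: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    h, w = labels.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    palette = np.zeros((256, 3))
    for code, rgb in CLASS_COLORS.items():
        palette[code] = rgb
    img[:] = palette[labels]

    # smooth illumination field + per-pixel texture noise
    illum = 1.0 + 0.06 * _smooth_noise(rng, (h, w), max(8.0, min(h, w) / 8))
    img *= illum[:, :, None]
    img += rng.normal(0.0, spec.texture_sigma, (h, w, 3))

    # between-date appearance shift: channel-wise gain and a global offset
    s = spec.appearance_shift
    if s > 0:
        gains = np.array([1.0 + 0.18 * s, 1.0 - 0.10 * s, 1.0 + 0.06 * s])
        img = img * gains[None, None, :] + 12.0 * s
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_scene(spec: FieldSpec) -> LabeledScene:
    """Generate one field scene (image + ground truth + geo-metadata).

    The realized weed coverage — weed pixels over non-ignore pixels —
    matches ``target_weed_coverage`` up to integer rounding, because the
    blob field is thresholded at the exact matching pixel count.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _layout_labels(spec, rng)
    img = _render_image(spec, labels, rng)
    geo = spec.geo
    return LabeledScene(GeoRaster(img, geo), LabelMap(labels, geo), spec)


def realized_weed_coverage(labels: LabelMap) -> float:
    """Weed pixels / non-ignore pixels, counted directly."""
    valid = labels.codes != CODE_IGNORE
    return float((labels.codes[valid] == CODE_WEEDS).sum() / valid.sum())


def generate_flight_set(spec: FieldSpec, n_images: int,
                        overlap_forward: float, overlap_side: float,
                        image_size_px: tuple[int, int] | None = None,
                        ) -> list[LabeledScene]:
    """Cut a master scene into overlapping "flight" images with exact geotransforms.

    ``image_size_px`` is (width, height) of each simulated photo; the default
    is half the field in each dimension.  Forward overlap applies along the
    flight line (east–west, i.e. columns), side overlap between lines (rows).
    Pixels seen by several images are byte-identical because every image is a
    crop of the one master scene.
    """
    for name, v in (("overlap_forward", overlap_forward), ("overlap_side", overlap_side)):
        if not 0 <= v <= 0.95:
            raise ValueError(f"{name} must be in [0, 0.95], got {v}")
    master = generate_scene(spec)
    h, w = master.labels.shape
    iw, ih = image_size_px if image_size_px else (max(1, w // 2), max(1, h // 2))
    if iw > w or ih > h:
        raise ValueError("image size exceeds field size")

    def starts(extent: int, size: int, overlap: float) -> list[int]:
        step = max(1, round(size * (1 - overlap)))
        pos = list(range(0, extent - size + 1, step))
        if pos[-1] != extent - size:
            pos.append(extent - size)
        return pos

    col_starts = starts(w, iw, overlap_forward)
    row_starts = starts(h, ih, overlap_side)
    needed = len(col_starts) * len(row_starts)
    if n_images < needed:
        raise ValueError(
            f"n_images={n_images} cannot cover the field at these overlaps; "
            f"minimum is {needed}")
    scenes = []
    for r in row_starts:
        for c in col_starts:
            scenes.append(LabeledScene(
                master.image.crop(r, c, ih, iw),
                master.labels.crop(r, c, ih, iw),
                spec,
            ))
    return scenes


def generate_dataset(spec_date1: FieldSpec, spec_date2: FieldSpec,
                     out_dir: str | Path) -> pd.DataFrame:
    """Write two dated scenes plus a role manifest to ``out_dir``.

    Date-1 is the training scene; date-2 is the validation/test pool,
    mirroring the practice of evaluating generalisation across acquisition
    dates.  The two specs may differ only in seed and appearance shift.
    """
    a = dataclasses.replace(spec_date1, seed=0, appearance_shift=0.0)
    b = dataclasses.replace(spec_date2, seed=0, appearance_shift=0.0)
    if a != b:
        raise ValueError("date specs may differ only in seed and appearance_shift")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for date, spec, role in ((1, spec_date1, "train"), (2, spec_date2, "valtest")):
        scene = generate_scene(spec)
        img_path = out / f"date{date}_image.png"
        lab_path = out / f"date{date}_labels.png"
        write_image(img_path, scene.image)
        write_labels(lab_path, scene.labels)
        rows.append({"image_path": img_path.name, "label_path": lab_path.name,
                     "role": role, "date": date})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(out_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "manifest.csv")


def load_scene(out_dir: str | Path, row: pd.Series) -> tuple[GeoRaster, LabelMap]:
    out = Path(out_dir)
    return read_image(out / row["image_path"]), read_labels(out / row["label_path"])
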