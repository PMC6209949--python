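"""Tiling of large rasters into model-sized patches, and the inverse.

Whole-field ortho-mosaics are far too large for one network forward pass, so
they are decomposed into square patches (1000×1000 px at full field scale),
classified patch-by-patch and stitched back.  The decomposition is a pure
partition — row-major, 0-based, top-left origin, half-open windows — so that
``stitch_labels(split_raster(x)) == x`` exactly.

Also provides plot masking (pixels outside the studied plot become the
ignore code) and the mosaicking of overlapping per-image score maps used by
the label-then-mosaic workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import shapely

from .georaster import (
    CODE_IGNORE,
    GeoRaster,
    GeoRef,
    LabelMap,
    ScoreMap,
)

Raster = Union[GeoRaster, LabelMap]

PAD_ERROR = "error_if_not_divisible"
PAD_IGNORE = "pad_with_ignore"


def count_tiles(width_px: int, height_px: int, patch_px: int,
                pad_policy: str = PAD_ERROR) -> int:
    """Number of patches produced when tiling a ``width_px``×``height_px`` raster.

    Under exact division this is ``(width/patch) * (height/patch)`` — e.g. a
    14,000×13,000 ortho-mosaic at patch 1000 gives 182 patches.  With
    ``pad_with_ignore`` partial edge tiles are counted too (ceil×ceil).
    """
    if min(width_px, height_px, patch_px) <= 0:
        raise ValueError("all dimensions must be positive")
    if pad_policy == PAD_ERROR:
        rw, rh = width_px % patch_px, height_px % patch_px
        if rw or rh:
            raise ValueError(
                f"dimensions not divisible by patch size {patch_px}: "
                f"remainders (width={rw}, height={rh})"
            )
        return (width_px // patch_px) * (height_px // patch_px)
    if pad_policy == PAD_IGNORE:
        return math.ceil(width_px / patch_px) * math.ceil(height_px / patch_px)
    raise ValueError(f"unknown pad_policy: {pad_policy!r}")


@dataclass(frozen=True)
class TilePlan:
    """Row-major decomposition of a raster into ``patch_px`` square tiles."""

    patch_px: int = 1000
    offsets: tuple[tuple[int, int], ...] = ()
    pad_policy: str = PAD_IGNORE

    @classmethod
    def for_shape(cls, height_px: int, width_px: int, patch_px: int = 1000,
                  pad_policy: str = PAD_IGNORE) -> "TilePlan":
        n = count_tiles(width_px, height_px, patch_px, pad_policy)  # validates
        rows = math.ceil(height_px / patch_px)
        cols = math.ceil(width_px / patch_px)
        offsets = tuple(
            (r * patch_px, c * patch_px) for r in range(rows) for c in range(cols)
        )
        assert len(offsets) == n
        return cls(patch_px, offsets, pad_policy)

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass
class Tile:
    """One patch plus the placement record needed to invert the split."""

    data: Raster
    row_off: int
    col_off: int

    @property
    def placement(self) -> tuple[int, int]:
        return (self.row_off, self.col_off)


def _pad_to(arr: np.ndarray, height: int, width: int, fill) -> np.ndarray:
    ph, pw = height - arr.shape[0], width - arr.shape[1]
    if ph == 0 and pw == 0:
        return arr
    widths = [(0, ph), (0, pw)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, widths, constant_values=fill)


def split_raster(raster: Raster, plan: TilePlan) -> list[Tile]:
    """Split a raster into patch_px×patch_px tiles per ``plan``, row-major.

    Label tiles are padded with the ignore code, image tiles with the raster's
    nodata value (0 if unset), so padding never fabricates class pixels.
    """
    is_labels = isinstance(raster, LabelMap)
    arr = raster.codes if is_labels else raster.pixels
    h, w = arr.shape[:2]
    expected = count_tiles(w, h, plan.patch_px, plan.pad_policy)
    if len(plan.offsets) != expected:
        raise ValueError(
            f"plan has {len(plan.offsets)} offsets but raster {h}×{w} "
            f"needs {expected} at patch {plan.patch_px}"
        )
    if is_labels:
        fill = CODE_IGNORE
    else:
        fill = raster.nodata if raster.nodata is not None else 0
    p = plan.patch_px
    tiles: list[Tile] = []
    for row_off, col_off in plan.offsets:
        win = arr[row_off : row_off + p, col_off : col_off + p]
        win = _pad_to(win, p, p, fill)
        geo = raster.geo.shift(row_off, col_off)
        data: Raster = (
            LabelMap(win, geo) if is_labels else GeoRaster(win.copy(), geo, raster.nodata)
        )
        tiles.append(Tile(data, row_off, col_off))
    return tiles


def stitch_labels(tiles: Sequence[LabelMap | Tile | np.ndarray],
                  placements: Sequence[tuple[int, int]] | None = None,
                  out_shape: tuple[int, int] | None = None,
                  geo: GeoRef | None = None) -> LabelMap:
    """Reassemble label tiles into one map; the inverse of :func:`split_raster`.

    Every output pixel must be written exactly once; tile regions that fall
    outside ``out_shape`` (padding) are cropped away.  Order-invariant.
    """
    if placements is None:
        placements = [t.placement for t in tiles]  # type: ignore[union-attr]
    arrays = []
    for t in tiles:
        if isinstance(t, Tile):
            t = t.data
        arrays.append(t.codes if isinstance(t, LabelMap) else np.asarray(t))
    if out_shape is None:
        out_shape = (
            max(r + a.shape[0] for (r, _), a in zip(placements, arrays)),
            max(c + a.shape[1] for (_, c), a in zip(placements, arrays)),
        )
    out = np.full(out_shape, CODE_IGNORE, dtype=np.uint8)
    written = np.zeros(out_shape, dtype=bool)
    offending = []
    for (row_off, col_off), arr in zip(placements, arrays):
        h = min(arr.shape[0], out_shape[0] - row_off)
        w = min(arr.shape[1], out_shape[1] - col_off)
        sel = (slice(row_off, row_off + h), slice(col_off, col_off + w))
        if written[sel].any():
            offending.append((row_off, col_off))
            continue
        out[sel] = arr[:h, :w]
        written[sel] = True
    if offending:
        raise ValueError(f"overlapping placements at anchors {offending}")
    if not written.all():
        missing = np.argwhere(~written)
        raise ValueError(
            f"{len(missing)} pixels not covered by any placement "
            f"(first missing at {tuple(missing[0])})"
        )
    if geo is None:
        geo = GeoRef(1.0)
    return LabelMap(out, geo)


def mask_plot(labels: LabelMap, plot_polygon) -> LabelMap:
    """Set pixels outside ``plot_polygon`` (world coordinates) to ignore.

    Mirrors the masking of areas outside the studied plot, which are excluded
    from training and evaluation.
    """
    poly = shapely.geometry.shape(plot_polygon) if isinstance(plot_polygon, dict) else plot_polygon
    h, w = labels.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    e0, n0 = labels.geo.origin
    xs = e0 + (cols + 0.5) * labels.gsd_m
    ys = n0 - (rows + 0.5) * labels.gsd_m
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(h, w)
    if not inside.any():
        raise ValueError("plot polygon does not intersect the raster")
    out = labels.codes.copy()
    out[~inside] = CODE_IGNORE
    return LabelMap(out, labels.geo)


def mosaic_predictions(per_image_scores: Iterable[ScoreMap]) -> LabelMap:
    """Mosaic overlapping georeferenced score maps into one label map.

    Each output pixel is the argmax of the *mean* class score over all images
    covering it; ties break to the lowest class code; pixels covered by no
    image become the ignore code.  Permutation-invariant by construction.
    """
    maps = list(per_image_scores)
    if not maps:
        raise ValueError("no score maps given")
    gsd = maps[0].geo.gsd_m
    k = maps[0].num_classes
    for m in maps[1:]:
        if not np.isclose(m.geo.gsd_m, gsd, rtol=1e-9):
            raise ValueError(f"inconsistent gsd: {m.geo.gsd_m} vs {gsd}")
        if m.num_classes != k:
            raise ValueError("inconsistent class counts")
    # union footprint on the shared pixel grid
    anchor = maps[0].geo
    offs = [m.geo.pixel_offset_from(anchor) for m in maps]
    r0 = min(r for r, _ in offs)
    c0 = min(c for _, c in offs)
    r1 = max(r + m.shape[0] for (r, _), m in zip(offs, maps))
    c1 = max(c + m.shape[1] for (_, c), m in zip(offs, maps))
    h, w = r1 - r0, c1 - c0
    acc = np.zeros((h, w, k), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.int32)
    for (r, c), m in zip(offs, maps):
        sel = (slice(r - r0, r - r0 + m.shape[0]), slice(c - c0, c - c0 + m.shape[1]))
        acc[sel] += m.scores
        cnt[sel] += 1
    covered = cnt > 0
    mean = np.zeros_like(acc)
    mean[covered] = acc[covered] / cnt[covered, None]
    codes = np.full((h, w), CODE_IGNORE, dtype=np.uint8)
    codes[covered] = np.argmax(mean, axis=2).astype(np.uint8)[covered]  # argmax → lowest on ties
    geo = GeoRef(gsd, (anchor.origin[0] + c0 * gsd, anchor.origin[1] - r0 * gsd))
    return LabelMap(codes, geo)
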