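"""Chessboard prescription maps: per-cell weed coverage, treatment decisions,
accuracy between prescription maps, and herbicide-saving accounting.

The weed cover map is partitioned into square grid cells of physical side
``cell_size_m`` (0.5 m by default, matching common site-specific sprayer
resolution).  Each cell's weed coverage is the fraction of weed pixels among
its non-ignore pixels; a cell is *treated* when its coverage is strictly
greater than the chosen threshold, so a threshold of 0 treats every cell
containing at least one weed pixel — the conservative setting that
minimises the risk of missing an infestation.  Herbicide saving is the
complement of the treated fraction: ``saving = 1 − P_treatment``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .georaster import CODE_IGNORE, CODE_WEEDS, GeoRef, LabelMap

#: The threshold sweep evaluated by default: 0.00–0.25 in steps of 0.05.
DEFAULT_THRESHOLDS = (0.00, 0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class CoverageGrid:
    """Per-cell weed-coverage fractions on the chessboard grid."""

    values: np.ndarray      # R×C float, coverage in [0,1] where valid
    valid_mask: np.ndarray  # R×C bool, cells with ≥1 non-ignore pixel
    cell_size_m: float
    geo: GeoRef

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape or self.values.ndim != 2:
            raise ValueError("values and valid_mask must be equal 2-D shapes")
        v = self.values[self.valid_mask]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("coverage values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PrescriptionMap:
    """Boolean treatment decisions on the chessboard grid."""

    treatment: np.ndarray   # R×C bool, defined only where valid
    valid_mask: np.ndarray
    threshold: float
    cell_size_m: float
    geo: GeoRef

    @property
    def shape(self) -> tuple[int, int]:
        return self.treatment.shape


def chessboard_coverage(labels: LabelMap, cell_size_m: float = 0.5) -> CoverageGrid:
    """Aggregate a weed cover map into per-cell weed-coverage fractions.

    At 0.5 cm/pixel and 0.5 m cells each cell is 100×100 pixels.  Edge cells
    of a map whose size is not a multiple of the cell size are included with
    coverage over their actual pixels.
    """
    if labels.geo is None or not labels.gsd_m > 0:
        raise ValueError("label map carries no ground sampling distance")
    cell_px_f = cell_size_m / labels.gsd_m
    cell_px = round(cell_px_f)
    if cell_px < 1 or abs(cell_px_f - cell_px) > 1e-6:
        raise ValueError(
            f"cell size {cell_size_m} m is not an integer number of pixels "
            f"at gsd {labels.gsd_m} m ({cell_px_f:.3f} px)"
        )
    h, w = labels.shape
    rows, cols = math.ceil(h / cell_px), math.ceil(w / cell_px)
    codes = labels.codes
    pad_h, pad_w = rows * cell_px - h, cols * cell_px - w
    if pad_h or pad_w:
        codes = np.pad(codes, ((0, pad_h), (0, pad_w)), constant_values=CODE_IGNORE)
    blocks = codes.reshape(rows, cell_px, cols, cell_px)
    weed = (blocks == CODE_WEEDS).sum(axis=(1, 3))
    nonignore = (blocks != CODE_IGNORE).sum(axis=(1, 3))
    valid = nonignore > 0
    values = np.zeros((rows, cols))
    values[valid] = weed[valid] / nonignore[valid]
    return CoverageGrid(values, valid, cell_size_m, labels.geo)


def apply_threshold(grid: CoverageGrid, threshold: float) -> PrescriptionMap:
    """Mark cells with coverage strictly greater than ``threshold`` as treatment."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    treatment = (grid.values > threshold) & grid.valid_mask
    return PrescriptionMap(treatment, grid.valid_mask.copy(), threshold,
                           grid.cell_size_m, grid.geo)


def _check_same_grid(a: PrescriptionMap, b: PrescriptionMap) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(a.cell_size_m, b.cell_size_m):
        raise ValueError("grid cell sizes differ")
    if a.geo.origin != b.geo.origin or not np.isclose(a.geo.gsd_m, b.geo.gsd_m):
        raise ValueError("grid geo-metadata differs")
    if not np.isclose(a.threshold, b.threshold):
        raise ValueError(f"thresholds differ: {a.threshold} vs {b.threshold}")


def prescription_accuracy(pred: PrescriptionMap, ref: PrescriptionMap) -> float:
    """Fraction of valid grid cells whose treatment decision matches the reference."""
    _check_same_grid(pred, ref)
    valid = pred.valid_mask & ref.valid_mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no jointly valid cells")
    return float((pred.treatment[valid] == ref.treatment[valid]).sum() / n)


def treatment_fraction(pmap: PrescriptionMap) -> float:
    """Proportion of valid cells marked for treatment (P_treatment)."""
    n = int(pmap.valid_mask.sum())
    if n == 0:
        raise ValueError("prescription map has no valid cells")
    return float(pmap.treatment[pmap.valid_mask].sum() / n)


def herbicide_saving(pmap: PrescriptionMap) -> float:
    """Herbicide saving = P_non-treatment = 1 − P_treatment."""
    return 1.0 - treatment_fraction(pmap)


def sweep_thresholds(pred_cover: LabelMap, gt_cover: LabelMap,
                     thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                     cell_size_m: float = 0.5) -> pd.DataFrame:
    """Evaluate prescription maps over a threshold sweep.

    For each threshold, the prediction-derived and ground-truth-derived
    prescription maps are compared (accuracy over jointly valid cells), and
    the treated fraction / herbicide saving of the prediction map recorded.
    """
    pg = chessboard_coverage(pred_cover, cell_size_m)
    gg = chessboard_coverage(gt_cover, cell_size_m)
    rows = []
    for tau in thresholds:
        pm, gm = apply_threshold(pg, tau), apply_threshold(gg, tau)
        tf = treatment_fraction(pm)
        rows.append({
            "threshold": tau,
            "accuracy": prescription_accuracy(pm, gm),
            "treatment_fraction": tf,
            "herbicide_saving": 1.0 - tf,
        })
    return pd.DataFrame(rows)


# -- export ------------------------------------------------------------------

def prescription_to_geojson(pmap: PrescriptionMap, coverage: CoverageGrid | None = None) -> dict:
    """Export the grid as GeoJSON polygons with treatment (and coverage) properties."""
    feats = []
    e0, n0 = pmap.geo.origin
    c = pmap.cell_size_m
    for r in range(pmap.shape[0]):
        for col in range(pmap.shape[1]):
            if not pmap.valid_mask[r, col]:
                continue
            x0, y0 = e0 + col * c, n0 - r * c
            ring = [[x0, y0], [x0 + c, y0], [x0 + c, y0 - c], [x0, y0 - c], [x0, y0]]
            props = {"treatment": bool(pmap.treatment[r, col])}
            if coverage is not None:
                props["coverage"] = float(coverage.values[r, col])
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            })
    return {"type": "FeatureCollection", "features": feats}
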