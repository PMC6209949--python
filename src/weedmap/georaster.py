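"""Georeferenced raster containers and plain-file I/O.

A :class:`GeoRaster` couples a pixel array with the two pieces of geo-metadata
the pipeline needs: the ground sampling distance (GSD, metres per pixel) and
the world coordinate of the top-left pixel *corner*.  Rasters are always
axis-aligned and north-up: column index grows with easting, row index grows
against northing.  Pixel indices are 0-based, row-major, half-open.

Imagery is stored as 3-band 8-bit PNG with an ESRI world file sidecar
(``.pgw``); label maps as single-band paletted PNG with the palette
{0: black (others), 1: green (rice), 2: red (weeds), 255: white (ignore)}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

#: Class codes used throughout the package.
CODE_OTHERS = 0
CODE_RICE = 1
CODE_WEEDS = 2
CODE_IGNORE = 255

CLASS_NAMES = ("others", "rice", "weeds")
VALID_CODES = frozenset({CODE_OTHERS, CODE_RICE, CODE_WEEDS, CODE_IGNORE})

#: RGB palette for label rasters.
LABEL_PALETTE = {
    CODE_OTHERS: (0, 0, 0),
    CODE_RICE: (0, 160, 0),
    CODE_WEEDS: (200, 0, 0),
    CODE_IGNORE: (255, 255, 255),
}


@dataclass(frozen=True)
class GeoRef:
    """Geo-metadata shared by images, label maps and score maps."""

    gsd_m: float
    origin: tuple[float, float] = (0.0, 0.0)  # (easting, northing) of top-left corner

    def __post_init__(self) -> None:
        if not self.gsd_m > 0:
            raise ValueError(f"gsd_m must be positive, got {self.gsd_m}")

    def pixel_center(self, row: float, col: float) -> tuple[float, float]:
        """World coordinate of a pixel center."""
        e0, n0 = self.origin
        return (e0 + (col + 0.5) * self.gsd_m, n0 - (row + 0.5) * self.gsd_m)

    def shift(self, row_off: int, col_off: int) -> "GeoRef":
        """Geo-metadata of a sub-window starting at (row_off, col_off)."""
        e0, n0 = self.origin
        return GeoRef(self.gsd_m, (e0 + col_off * self.gsd_m, n0 - row_off * self.gsd_m))

    def pixel_offset_from(self, other: "GeoRef") -> tuple[int, int]:
        """Integer (row, col) offset of this raster's origin within ``other``'s grid.

        Raises if the grids are not aligned (different GSD or fractional offset).
        """
        if not np.isclose(self.gsd_m, other.gsd_m, rtol=1e-9):
            raise ValueError(f"inconsistent gsd: {self.gsd_m} vs {other.gsd_m}")
        de = (self.origin[0] - other.origin[0]) / self.gsd_m
        dn = (other.origin[1] - self.origin[1]) / self.gsd_m
        col, row = round(de), round(dn)
        if abs(de - col) > 1e-6 or abs(dn - row) > 1e-6:
            raise ValueError("rasters are not pixel-aligned")
        return row, col


@dataclass
class GeoRaster:
    """Pixel array + geo-metadata; the carrier of all imagery."""

    pixels: np.ndarray  # H×W×C (C in {1,3}) or H×W
    geo: GeoRef
    nodata: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (1, 3):
            raise ValueError(f"expected H×W×{{1,3}} pixels, got shape {self.pixels.shape}")
        if min(self.pixels.shape[:2]) < 1:
            raise ValueError("raster dimensions must be ≥ 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def gsd_m(self) -> float:
        return self.geo.gsd_m

    def crop(self, row_off: int, col_off: int, height: int, width: int) -> "GeoRaster":
        win = self.pixels[row_off : row_off + height, col_off : col_off + width]
        return GeoRaster(win.copy(), self.geo.shift(row_off, col_off), self.nodata)


@dataclass
class LabelMap:
    """Per-pixel class codes {0 others, 1 rice, 2 weeds, 255 ignore} + geo-metadata."""

    codes: np.ndarray  # H×W uint8
    geo: GeoRef

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError(f"expected H×W codes, got shape {self.codes.shape}")
        bad = set(np.unique(self.codes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid label codes present: {sorted(bad)}")
        self.codes = self.codes.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def gsd_m(self) -> float:
        return self.geo.gsd_m

    def ignore_mask(self) -> np.ndarray:
        return self.codes == CODE_IGNORE

    def crop(self, row_off: int, col_off: int, height: int, width: int) -> "LabelMap":
        win = self.codes[row_off : row_off + height, col_off : col_off + width]
        return LabelMap(win.copy(), self.geo.shift(row_off, col_off))


@dataclass
class ScoreMap:
    """Per-pixel, per-class scores produced by a segmentation model."""

    scores: np.ndarray  # H×W×K float
    geo: GeoRef
    post_softmax: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float32)
        if self.scores.ndim != 3:
            raise ValueError(f"expected H×W×K scores, got shape {self.scores.shape}")
        if self.post_softmax:
            sums = self.scores.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-4):
                raise ValueError("post-softmax scores must sum to 1 per pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape[:2]

    @property
    def num_classes(self) -> int:
        return self.scores.shape[2]


# ---------------------------------------------------------------------------
# I/O: PNG + ESRI world file
# ---------------------------------------------------------------------------

def _world_path(path: Path) -> Path:
    # .png → .pgw convention: first+last letter of suffix + 'w'
    s = path.suffix.lstrip(".")
    ext = (s[0] + s[-1] + "w") if len(s) >= 2 else s + "w"
    return path.with_suffix("." + ext)


def _write_world_file(path: Path, geo: GeoRef) -> None:
    cx, cy = geo.pixel_center(0, 0)
    lines = [geo.gsd_m, 0.0, 0.0, -geo.gsd_m, cx, cy]
    _world_path(path).write_text("".join(f"{v:.10f}\n" for v in lines))


def _read_world_file(path: Path) -> GeoRef:
    vals = [float(v) for v in _world_path(path).read_text().split()]
    gsd, _, _, neg_gsd, cx, cy = vals
    if not np.isclose(gsd, -neg_gsd):
        raise ValueError("only north-up square-pixel world files are supported")
    return GeoRef(gsd, (cx - 0.5 * gsd, cy + 0.5 * gsd))


def write_image(path: str | Path, raster: GeoRaster) -> None:
    """Write a 3-band image as 8-bit PNG with a world-file sidecar."""
    path = Path(path)
    arr = raster.pixels
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    Image.fromarray(arr.astype(np.uint8)).save(path)
    _write_world_file(path, raster.geo)


def read_image(path: str | Path) -> GeoRaster:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("RGB"))
    return GeoRaster(arr, _read_world_file(path))


def write_labels(path: str | Path, labels: LabelMap) -> None:
    """Write a label map as a paletted PNG with a world-file sidecar."""
    path = Path(path)
    img = Image.fromarray(labels.codes, mode="P")
    palette = [0] * (256 * 3)
    for code, rgb in LABEL_PALETTE.items():
        palette[3 * code : 3 * code + 3] = rgb
    img.putpalette(palette)
    img.save(path)
    _write_world_file(path, labels.geo)


def read_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    arr = np.asarray(Image.open(path))
    return LabelMap(arr, _read_world_file(path))
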