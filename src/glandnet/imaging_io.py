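"""Reading and writing of region images, masks, gland polygons and feature tables.

A *region* is a pathologist-annotated sub-area of a digitized slide.  Images
are 8-bit RGB rasters (PNG or TIFF); the annotation mask is a single-channel
raster where nonzero marks pixels inside the annotation.  All coordinates are
row-major and 0-based; polygon vertices are (x=column, y=row) real pairs at
pixel centers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color

DEFAULT_RESOLUTION_UM_PER_PX = 0.5


@dataclass
class RegionImage:
    """An annotated RGB region of a digitized slide.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        8-bit RGB intensities.
    resolution_um_per_px : float
        Physical pixel size; 0.5 um/px corresponds to 20x magnification.
    mask : (H, W) bool array
        True inside the pathologist annotation.
    region_id, case_id : str
        Identifiers carried through to feature tables.
    """

    pixels: np.ndarray
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    mask: np.ndarray = None
    region_id: str = "region0"
    case_id: str = "case0"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        self.pixels = self.pixels.astype(np.uint8, copy=False)
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image "
                f"shape {self.pixels.shape[:2]}"
            )
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class LuminanceImage:
    """The L* (luminance) channel of a region in CIELAB space, range [0, 100]."""

    values: np.ndarray
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def shape(self):
        return self.values.shape


def load_region(image_path, mask_path=None, resolution=DEFAULT_RESOLUTION_UM_PER_PX,
                region_id=None, case_id="case0") -> RegionImage:
    """Load an RGB region image and optional annotation mask from disk.

    An absent mask defaults to the all-true mask (the whole raster is
    analysed).  Nonzero mask pixels are inside the annotation.
    """
    image_path = Path(image_path)
    img = Image.open(image_path).convert("RGB")
    pixels = np.asarray(img, dtype=np.uint8)
    mask = None
    if mask_path is not None:
        m = Image.open(mask_path)
        if m.mode not in ("L", "I", "1", "I;16"):
            m = m.convert("L")
        mask = np.asarray(m) != 0
        if mask.shape != pixels.shape[:2]:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape "
                f"{pixels.shape[:2]}"
            )
    return RegionImage(
        pixels=pixels,
        resolution_um_per_px=resolution,
        mask=mask,
        region_id=region_id or image_path.stem,
        case_id=case_id,
    )


def save_region(img: RegionImage, image_path, mask_path=None) -> None:
    """Write the RGB raster (and optionally the mask) as PNG/TIFF."""
    Image.fromarray(img.pixels, mode="RGB").save(image_path)
    if mask_path is not None:
        Image.fromarray((img.mask.astype(np.uint8) * 255)).save(mask_path)


def to_luminance(img: RegionImage) -> LuminanceImage:
    """Convert an RGB region to its CIELAB luminance (L*) channel.

    Uses the standard sRGB -> XYZ -> L*a*b* transform with the D65 white
    point; black maps to L*=0 and white to L*=100.
    """
    lab = color.rgb2lab(img.pixels)
    return LuminanceImage(values=lab[..., 0],
                          resolution_um_per_px=img.resolution_um_per_px)


# ---------------------------------------------------------------------------
# gland polygon CSV (columns: gland_id, vertex_index, x, y)
# ---------------------------------------------------------------------------

def write_polygons(polygons: dict, path) -> None:
    """Write gland boundary polygons to CSV.

    ``polygons`` maps gland_id -> (n, 2) array of (x, y) vertices.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gland_id", "vertex_index", "x", "y"])
        for gid in sorted(polygons):
            verts = np.asarray(polygons[gid], dtype=float)
            for i, (x, y) in enumerate(verts):
                w.writerow([gid, i, repr(float(x)), repr(float(y))])


def read_polygons(path) -> dict:
    """Read gland boundary polygons written by :func:`write_polygons`."""
    df = pd.read_csv(path)
    out = {}
    for gid, grp in df.groupby("gland_id"):
        grp = grp.sort_values("vertex_index")
        out[int(gid)] = grp[["x", "y"]].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(rows: Sequence[tuple], path) -> None:
    """Write per-region feature vectors to CSV at full float precision.

    ``rows`` is a sequence of (region_id, feature_dict) pairs; every feature
    dict must share one ordered feature-name list.
    """
    rows = list(rows)
    names = None
    for _, feats in rows:
        these = list(feats.keys())
        if names is None:
            names = these
        elif these != names:
            raise ValueError("inconsistent feature-name sets across rows")
    if names is None:
        names = []
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region_id"] + names)
        for rid, feats in rows:
            w.writerow([rid] + [repr(float(feats[n])) for n in names])


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV into a DataFrame indexed by region_id."""
    return pd.read_csv(path, index_col="region_id")
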