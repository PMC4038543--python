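"""Comparative quantitative-histomorphometry feature families.

Six classical families computed from the same gland segmentation used for
the angularity features: per-gland shape morphology (100 values), Voronoi
tessellation (12), Delaunay triangulation (8), minimum spanning tree (4),
gland density (24), and image-intensity co-occurrence texture (26).

The "disorder" aggregate used throughout is the normalized coefficient of
variation 1 - 1/(1 + sigma/mu), which lies in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import spatial
from scipy.sparse.csgraph import minimum_spanning_tree
from shapely.geometry import MultiPoint, Polygon, box as shapely_box
from shapely.ops import voronoi_diagram
from skimage import measure

from ._haralick import STAT_NAMES, haralick_stats
from .imaging_io import LuminanceImage
from .segmentation import GlandSegment

FAMILY_LENGTHS = {
    "morphology": 100,
    "voronoi": 12,
    "delaunay": 8,
    "mst": 4,
    "density": 24,
    "texture": 26,
}

DENSITY_RADII_PX = (10.0, 20.0, 30.0, 40.0, 50.0)
DENSITY_KNN = (3, 5, 7)
TEXTURE_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class QHFeatureVector:
    family: str
    values: Dict[str, float]

    def __post_init__(self):
        expect = FAMILY_LENGTHS[self.family]
        if len(self.values) != expect:
            raise ValueError(
                f"{self.family} family must have {expect} values, "
                f"got {len(self.values)}"
            )


# ---------------------------------------------------------------------------
# shared aggregates
# ---------------------------------------------------------------------------

def disorder(values: np.ndarray) -> float:
    """1 - 1/(1 + sigma/mu) with population sigma; 0 when the mean is 0."""
    values = np.asarray(values, dtype=float)
    mu = values.mean()
    if mu == 0:
        return 0.0
    return float(1.0 - 1.0 / (1.0 + values.std() / mu))


def _minmax_ratio(values: np.ndarray) -> float:
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:
        return 1.0
    if hi == 0:
        return 0.0
    return lo / hi


def _agg4(values) -> Dict[str, float]:
    """mean / std / min-max ratio / disorder of one structural quantity."""
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(v.mean()),
        "std": float(v.std()),
        "minmax_ratio": _minmax_ratio(v),
        "disorder": disorder(v),
    }


# ---------------------------------------------------------------------------
# gland morphology (100)
# ---------------------------------------------------------------------------

MORPH_DESCRIPTORS = (
    ["area_ratio", "distance_ratio", "distance_std", "distance_var",
     "distance_var_raw", "perimeter_ratio", "smoothness"]
    + [f"hu_moment_{k}" for k in range(1, 8)]
    + ["fractal_dimension"]
    + [f"fourier_descriptor_{k}" for k in range(1, 11)]
)


def _radial_series(boundary: np.ndarray) -> np.ndarray:
    center = boundary.mean(axis=0)
    return np.hypot(*(boundary - center).T)


def _hu_moments(pixel_set) -> np.ndarray:
    rows = np.array([p[0] for p in pixel_set])
    cols = np.array([p[1] for p in pixel_set])
    r0, c0 = rows.min(), cols.min()
    img = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=float)
    img[rows - r0, cols - c0] = 1.0
    mu = measure.moments_central(img)
    nu = measure.moments_normalized(mu)
    return measure.moments_hu(nu)


def _fractal_dimension(boundary: np.ndarray) -> float:
    """Box-counting dimension of the boundary curve.

    Counts occupied boxes at dyadic scales of the bounding extent and fits
    the slope of log N against log(1/s).  A smooth contour gives ~1.
    """
    pts = np.asarray(boundary, dtype=float)
    lo = pts.min(axis=0)
    extent = max(float((pts.max(axis=0) - lo).max()), 1e-9)
    logs_n, logs_inv_s = [], []
    for k in range(1, 6):
        s = extent / (2 ** k)
        cells = np.floor((pts - lo) / s).astype(int)
        n = len({(a, b) for a, b in cells})
        logs_n.append(np.log(n))
        logs_inv_s.append(np.log(1.0 / s))
    slope = np.polyfit(logs_inv_s, logs_n, 1)[0]
    return float(slope)


def _fourier_descriptors(radial: np.ndarray, n_desc: int = 10) -> np.ndarray:
    """Magnitudes of the first ``n_desc`` non-DC Fourier coefficients of the
    radial-distance series, normalized by the DC magnitude (scale-free)."""
    c = np.fft.fft(radial)
    dc = np.abs(c[0])
    out = np.zeros(n_desc)
    for k in range(1, n_desc + 1):
        if k < len(c):
            out[k - 1] = np.abs(c[k]) / dc if dc > 0 else 0.0
    return out


def gland_descriptors(g: GlandSegment) -> Dict[str, float]:
    """The 25 per-gland morphology descriptors."""
    poly = Polygon(g.boundary)
    hull = poly.convex_hull
    radial = _radial_series(g.boundary)
    rmax = radial.max()
    rnorm = radial / rmax if rmax > 0 else radial
    smooth = np.abs(rnorm - (np.roll(rnorm, 1) + np.roll(rnorm, -1)) / 2.0)
    hu = _hu_moments(g.pixel_set)
    fd = _fourier_descriptors(rnorm)
    out = {
        "area_ratio": poly.area / hull.area if hull.area > 0 else 1.0,
        "distance_ratio": float(rnorm.mean()),  # mean radial / max radial
        "distance_std": float(rnorm.std()),
        "distance_var": float(rnorm.var()),
        "distance_var_raw": float(radial.var()),
        "perimeter_ratio": (poly.length / hull.length
                            if hull.length > 0 else 1.0),
        "smoothness": float(smooth.mean()),
        "fractal_dimension": _fractal_dimension(g.boundary),
    }
    for k in range(7):
        out[f"hu_moment_{k + 1}"] = float(hu[k])
    for k in range(10):
        out[f"fourier_descriptor_{k + 1}"] = float(fd[k])
    return {name: out[name] for name in MORPH_DESCRIPTORS}


def morphology_features(glands: Sequence[GlandSegment]) -> QHFeatureVector:
    """100 morphology values: mean/std/median/min-max ratio of each of the
    25 per-gland shape descriptors across all glands of the region."""
    if not glands:
        raise ValueError("no glands")
    table = {name: [] for name in MORPH_DESCRIPTORS}
    for g in glands:
        d = gland_descriptors(g)
        for name in MORPH_DESCRIPTORS:
            table[name].append(d[name])
    values = {}
    for name in MORPH_DESCRIPTORS:
        v = np.asarray(table[name], dtype=float)
        values[f"morph_{name}_mean"] = float(v.mean())
        values[f"morph_{name}_std"] = float(v.std())
        values[f"morph_{name}_median"] = float(np.median(v))
        values[f"morph_{name}_minmax_ratio"] = _minmax_ratio(v)
    return QHFeatureVector(family="morphology", values=values)


# ---------------------------------------------------------------------------
# Voronoi (12), Delaunay (8), MST (4)
# ---------------------------------------------------------------------------

def _as_xy(centroids) -> np.ndarray:
    xy = np.asarray(centroids, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("centroids must be an (n, 2) array of (x, y)")
    return xy


def voronoi_polygons(centroids) -> List[Polygon]:
    """Voronoi cells of the centroid set, clipped to its bounding box so
    every cell is a finite polygon; together they partition the box."""
    xy = _as_xy(centroids)
    if len(xy) < 4:
        raise ValueError("need at least 4 centroids")
    window = shapely_box(*xy.min(axis=0), *xy.max(axis=0))
    if window.area <= 0:
        raise ValueError("degenerate (collinear) centroid layout")
    cells = voronoi_diagram(MultiPoint([tuple(p) for p in xy]))
    out = []
    for cell in cells.geoms:
        clipped = cell.intersection(window)
        if not clipped.is_empty and clipped.area > 0:
            out.append(clipped)
    return out


def voronoi_features(centroids) -> QHFeatureVector:
    """12 values: mean/std/min-max ratio/disorder of polygon area, perimeter
    and chord length (longest vertex-to-vertex distance) over all cells."""
    polys = voronoi_polygons(centroids)
    areas, perims, chords = [], [], []
    for p in polys:
        areas.append(p.area)
        perims.append(p.exterior.length)
        verts = np.asarray(p.exterior.coords[:-1])
        chords.append(float(spatial.distance.pdist(verts).max()))
    values = {}
    for qty, vals in (("area", areas), ("perimeter", perims), ("chord", chords)):
        for agg, v in _agg4(vals).items():
            values[f"voronoi_{qty}_{agg}"] = v
    return QHFeatureVector(family="voronoi", values=values)


def delaunay_features(centroids) -> QHFeatureVector:
    """8 values: the four aggregates of per-triangle side lengths (three per
    triangle, shared sides counted once per triangle) and triangle areas."""
    xy = _as_xy(centroids)
    if len(xy) < 3:
        raise ValueError("need at least 3 centroids")
    try:
        tri = spatial.Delaunay(xy)
    except spatial.QhullError as e:
        raise ValueError("degenerate (collinear) centroid layout") from e
    sides, areas = [], []
    for simplex in tri.simplices:
        p = xy[simplex]
        for i in range(3):
            sides.append(float(np.hypot(*(p[i] - p[(i + 1) % 3]))))
        u, v = p[1] - p[0], p[2] - p[0]
        areas.append(abs(u[0] * v[1] - u[1] * v[0]) / 2.0)
    values = {}
    for qty, vals in (("side", sides), ("area", areas)):
        for agg, v in _agg4(vals).items():
            values[f"delaunay_{qty}_{agg}"] = v
    return QHFeatureVector(family="delaunay", values=values)


def mst_edge_lengths(centroids) -> np.ndarray:
    """Edge lengths of the Euclidean minimum spanning tree."""
    xy = _as_xy(centroids)
    if len(xy) < 2:
        raise ValueError("need at least 2 centroids")
    dist = spatial.distance.squareform(spatial.distance.pdist(xy))
    mst = minimum_spanning_tree(dist)
    return np.asarray(mst[mst.nonzero()]).ravel()


def mst_features(centroids) -> QHFeatureVector:
    """4 values: the four aggregates of MST edge lengths."""
    lengths = mst_edge_lengths(centroids)
    values = {f"mst_edge_{agg}": v for agg, v in _agg4(lengths).items()}
    return QHFeatureVector(family="mst", values=values)


# ---------------------------------------------------------------------------
# gland density (24)
# ---------------------------------------------------------------------------

def density_features(centroids) -> QHFeatureVector:
    """24 values: per gland, the neighbour counts within 10..50 px radii
    (<= radius, self excluded) and the distances to its 3rd/5th/7th nearest
    neighbours, each aggregated by mean, std and disorder."""
    xy = _as_xy(centroids)
    n = len(xy)
    if n < max(DENSITY_KNN) + 1:
        raise ValueError(f"need at least {max(DENSITY_KNN) + 1} centroids")
    dist = spatial.distance.squareform(spatial.distance.pdist(xy))
    np.fill_diagonal(dist, np.inf)
    per_gland = {}
    for radius in DENSITY_RADII_PX:
        per_gland[f"count_r{radius:g}"] = (dist <= radius).sum(axis=1)
    sorted_d = np.sort(dist, axis=1)
    for k in DENSITY_KNN:
        per_gland[f"nn{k}_dist"] = sorted_d[:, k - 1]
    values = {}
    for qty, vals in per_gland.items():
        v = np.asarray(vals, dtype=float)
        values[f"density_{qty}_mean"] = float(v.mean())
        values[f"density_{qty}_std"] = float(v.std())
        values[f"density_{qty}_disorder"] = disorder(v)
    return QHFeatureVector(family="density", values=values)


# ---------------------------------------------------------------------------
# intensity co-occurrence texture (26)
# ---------------------------------------------------------------------------

def quantize_luminance(lum: LuminanceImage) -> np.ndarray:
    """Quantize L* in [0, 100] to 8-bit levels 0..255."""
    return np.clip(np.round(lum.values / 100.0 * 255.0), 0, 255).astype(np.uint8)


def glcm(levels: np.ndarray, mask: np.ndarray, offset: Tuple[int, int]) -> np.ndarray:
    """Symmetric 256 x 256 gray-level co-occurrence counts at one offset,
    restricted to pixel pairs that both lie inside the mask."""
    H, W = levels.shape
    dr, dc = offset
    src = (slice(max(0, -dr), H - max(0, dr)), slice(max(0, -dc), W - max(0, dc)))
    dst = (slice(max(0, dr), H - max(0, -dr)), slice(max(0, dc), W - max(0, -dc)))
    ok = mask[src] & mask[dst]
    a = levels[src][ok].astype(np.int64)
    b = levels[dst][ok].astype(np.int64)
    counts = np.bincount(a * 256 + b, minlength=256 * 256).reshape(256, 256)
    return counts + counts.T


def intensity_texture_features(lum: LuminanceImage, mask: np.ndarray
                               ) -> QHFeatureVector:
    """26 values: the 13 second-order statistics of the distance-1 GLCM in
    each of the four unique directions, averaged (mean and std) over the
    directions."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    levels = quantize_luminance(lum)
    per_offset = []
    for off in TEXTURE_OFFSETS:
        counts = glcm(levels, mask, off)
        if counts.sum() == 0:
            continue
        per_offset.append(haralick_stats(counts))
    if not per_offset:
        raise ValueError("no in-mask pixel pairs at distance 1")
    values = {}
    for stat in STAT_NAMES:
        col = np.array([d[stat] for d in per_offset], dtype=float)
        values[f"texture_{stat}_mean"] = float(col.mean())
        values[f"texture_{stat}_std"] = float(col.std())
    return QHFeatureVector(family="texture", values=values)
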