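"""Gland detection and segmentation by multiscale seeding and region growing.

Glands in the CIELAB luminance channel appear as contiguous bright blobs on
darker stroma.  Seeds are the regional maxima of the Gaussian-smoothed
luminance image at several scales.  From each seed a region is grown inside a
k x k bounding box by repeatedly moving the brightest current-boundary (CB)
pixel into the current region (CR); at every iteration the *boundary
strength* -- mean intensity of the internal boundary (CR pixels adjacent to
CB) minus mean intensity of CB -- is recorded, and the region returned is the
CR snapshot of maximal boundary strength.  Overlapping candidate regions are
resolved by repeatedly discarding the weakest overlapping region.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .imaging_io import LuminanceImage, RegionImage, to_luminance

try:  # numba accelerates the sequential growth loop; logic is mirrored below
    from ._growth import grow_flat as _grow_fast
except ImportError:  # pragma: no cover
    _grow_fast = None


@dataclass
class SegmentationParams:
    """Tunable knobs of the gland segmentation pipeline.

    ``gaussian_scales_px`` are the smoothing sigmas (pixels) used for seed
    detection; at 0.5 um/px the defaults 10/20/40 cover small to large acini.
    The growth bounding box is ``box_factor * scale`` so it exceeds any
    plausible gland diameter at that scale.  Regions smaller than
    ``min_gland_area_px`` are discarded as noise specks.
    """

    gaussian_scales_px: Sequence[float] = (10.0, 20.0, 40.0)
    box_factor: float = 8.0
    min_gland_area_px: int = 30

    def __post_init__(self):
        scales = [float(s) for s in self.gaussian_scales_px]
        if not scales or any(s <= 0 for s in scales):
            raise ValueError("gaussian scales must be positive")
        if scales != sorted(scales):
            raise ValueError("gaussian scales must be sorted ascending")
        self.gaussian_scales_px = scales
        if self.box_factor * min(scales) < 3:
            raise ValueError("bounding box would be smaller than 3 px")

    def box_size(self, scale_px: float) -> int:
        return max(3, int(round(self.box_factor * scale_px)))


@dataclass
class GlandSegment:
    """One segmented gland."""

    gland_id: int
    boundary: np.ndarray          # (n, 2) closed polygon of (x, y) vertices
    pixel_set: Set[Tuple[int, int]]
    centroid: Tuple[float, float]  # (x, y)
    boundary_strength: float
    seed: Tuple[int, int]          # (row, col)
    scale_px: float


def detect_seeds(lum: LuminanceImage, mask: np.ndarray,
                 params: SegmentationParams) -> List[Tuple[Tuple[int, int], float]]:
    """Find region-growing seeds as regional maxima of smoothed luminance.

    For each Gaussian scale the luminance image is smoothed and its regional
    maxima inside the mask are returned tagged with the scale.  A maximal
    plateau contributes a single seed at its (rounded) centroid; plateaus
    with no strictly lower neighbour (e.g. a constant image) are not maxima.
    Seeds are ordered by scale, then raster order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no true pixel")
    vals = lum.values
    seeds = []
    for scale in params.gaussian_scales_px:
        sm = ndimage.gaussian_filter(vals, sigma=scale, mode="nearest")
        for seed in _regional_maxima(sm):
            if mask[seed]:
                seeds.append((seed, scale))
    return seeds


_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _shift_views(img, dr, dc):
    """Aligned (src, dst) slice pairs so that dst is the +(dr,dc) neighbour."""
    H, W = img.shape
    src = (slice(max(0, -dr), H - max(0, dr)), slice(max(0, -dc), W - max(0, dc)))
    dst = (slice(max(0, dr), H - max(0, -dr)), slice(max(0, dc), W - max(0, -dc)))
    return src, dst


def _regional_maxima(img: np.ndarray) -> List[Tuple[int, int]]:
    """Centroids of 8-connected equal-value plateaus that dominate all their
    neighbours and have at least one strictly lower neighbour.

    A pixel is a candidate when no 8-neighbour exceeds it; adjacent candidate
    pixels necessarily share one value, so candidate components are plateaus.
    A component touching an equal-valued non-candidate pixel belongs to a
    larger plateau with a higher neighbour and is rejected, as is a plateau
    with no strictly lower neighbour (e.g. a constant image).
    """
    H, W = img.shape
    ge_all = np.ones((H, W), dtype=bool)
    for dr, dc in _OFFSETS8:
        src, dst = _shift_views(img, dr, dc)
        ge_all[src] &= ~(img[dst] > img[src])
    labels, n = ndimage.label(ge_all, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    bad = np.zeros(n + 1, dtype=bool)
    lower = np.zeros(n + 1, dtype=bool)
    for dr, dc in _OFFSETS8:
        src, dst = _shift_views(img, dr, dc)
        lab = labels[src]
        a, b = img[src], img[dst]
        sel = (lab > 0) & (b == a) & ~ge_all[dst]
        bad[lab[sel]] = True
        sel = (lab > 0) & (b < a)
        lower[lab[sel]] = True
    keep = np.nonzero(~bad[1:] & lower[1:])[0] + 1
    out = []
    for rbar, cbar in ndimage.center_of_mass(ge_all, labels, keep):
        out.append((int(round(rbar)), int(round(cbar))))
    out.sort()
    return out


def grow_region(lum: LuminanceImage, seed: Tuple[int, int], box_size_px: int,
                mask: Optional[np.ndarray] = None,
                ) -> Tuple[Set[Tuple[int, int]], float]:
    """Grow a gland candidate from one seed; return (pixel_set, strength).

    The box is centered on the seed and clipped to the image.  Growth stops
    when the brightest CB pixel lies outside the bounding box; pixels outside
    the mask are never entered.  Ties in CB intensity are broken by raster
    order, ties in boundary strength by the earliest iteration.
    """
    vals = np.asarray(lum.values, dtype=np.float64)
    H, W = vals.shape
    sr, sc = int(seed[0]), int(seed[1])
    if not (0 <= sr < H and 0 <= sc < W):
        raise ValueError("seed outside image")
    if mask is not None and not mask[sr, sc]:
        raise ValueError("seed outside mask")
    half = box_size_px // 2
    r0, c0 = max(0, sr - half), max(0, sc - half)
    r1 = min(H - 1, r0 + box_size_px - 1)
    c1 = min(W - 1, c0 + box_size_px - 1)
    m8 = (np.ones((H, W), dtype=np.uint8) if mask is None
          else np.asarray(mask, dtype=np.uint8))
    if _grow_fast is not None:
        rows, cols, strength = _grow_fast(vals, m8, sr, sc, r0, r1, c0, c1)
        rows, cols = np.asarray(rows), np.asarray(cols)
    else:  # pragma: no cover
        rows, cols, strength = _grow_py(vals, m8, sr, sc, r0, r1, c0, c1)
    pixel_set = set(zip(rows.tolist(), cols.tolist()))
    return pixel_set, float(strength)


def _grow_py(vals, mask, sr, sc, r0, r1, c0, c1):
    """Pure-Python reference implementation of the growth loop (used as an
    oracle for the compiled path and as a fallback)."""
    H, W = vals.shape
    state = {}  # (r,c) -> 1 CB, 2 CR
    cbn = {}    # CR pixel -> number of CB neighbours
    heap = []
    cb_sum = cb_cnt = 0.0
    ib_sum = ib_cnt = 0.0
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    def neighbours(r, c):
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W:
                yield rr, cc

    state[(sr, sc)] = 2
    cbn[(sr, sc)] = 0
    for rr, cc in neighbours(sr, sc):
        if mask[rr, cc] and (rr, cc) not in state:
            state[(rr, cc)] = 1
            heapq.heappush(heap, (-vals[rr, cc], rr * W + cc))
            cb_sum += vals[rr, cc]
            cb_cnt += 1
            cbn[(sr, sc)] += 1
    if cbn[(sr, sc)] > 0:
        ib_sum += vals[sr, sc]
        ib_cnt += 1

    order = []
    strengths = []
    while heap:
        negv, idx = heapq.heappop(heap)
        r, c = divmod(idx, W)
        if r < r0 or r > r1 or c < c0 or c > c1:
            break  # attempts to add a pixel outside the bounding box
        v = -negv
        state[(r, c)] = 2
        cb_sum -= v
        cb_cnt -= 1
        for rr, cc in neighbours(r, c):
            if state.get((rr, cc)) == 2:
                cbn[(rr, cc)] -= 1
                if cbn[(rr, cc)] == 0:
                    ib_sum -= vals[rr, cc]
                    ib_cnt -= 1
        # IB membership of the incorporated pixel: count its current CB
        # neighbours first, then let the CB-extension loop add the rest
        n = sum(1 for rr, cc in neighbours(r, c) if state.get((rr, cc)) == 1)
        cbn[(r, c)] = n
        if n > 0:
            ib_sum += v
            ib_cnt += 1
        new_cb = []
        for rr, cc in neighbours(r, c):
            if (rr, cc) not in state and mask[rr, cc]:
                state[(rr, cc)] = 1
                heapq.heappush(heap, (-vals[rr, cc], rr * W + cc))
                cb_sum += vals[rr, cc]
                cb_cnt += 1
                new_cb.append((rr, cc))
        for rr, cc in new_cb:
            for r2, c2 in neighbours(rr, cc):
                if state.get((r2, c2)) == 2:
                    if cbn[(r2, c2)] == 0:
                        ib_sum += vals[r2, c2]
                        ib_cnt += 1
                    cbn[(r2, c2)] += 1
        ib_mean = ib_sum / ib_cnt if ib_cnt > 0 else 0.0
        cb_mean = cb_sum / cb_cnt if cb_cnt > 0 else 0.0
        strengths.append(ib_mean - cb_mean)
        order.append((r, c))

    if not strengths:
        return np.array([sr]), np.array([sc]), 0.0
    best = int(np.argmax(strengths))  # argmax takes the earliest maximum
    kept = [(sr, sc)] + order[: best + 1]
    rows = np.array([p[0] for p in kept])
    cols = np.array([p[1] for p in kept])
    return rows, cols, float(strengths[best])


def resolve_overlaps(candidates: Sequence[Tuple[Set[Tuple[int, int]], float]],
                     ) -> List[int]:
    """Resolve overlapping candidate regions; return surviving indices.

    While any two surviving regions share a pixel, the overlapping region of
    lowest boundary strength is removed (ties: the later candidate in the
    input order is removed first).
    """
    n = len(candidates)
    alive = set(range(n))
    overlaps = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if candidates[i][0] & candidates[j][0]:
                overlaps[i].add(j)
                overlaps[j].add(i)
    while True:
        conflicted = [i for i in alive if overlaps[i] & alive]
        if not conflicted:
            break
        victim = min(conflicted, key=lambda i: (candidates[i][1], -i))
        alive.remove(victim)
    return sorted(alive)


def boundary_polygon(pixel_set: Set[Tuple[int, int]]) -> np.ndarray:
    """Outer contour of a pixel set as a closed (x, y) polygon.

    The contour follows the half-pixel iso-line around the region; the first
    vertex is not repeated at the end.
    """
    rows = [p[0] for p in pixel_set]
    cols = [p[1] for p in pixel_set]
    r0, c0 = min(rows), min(cols)
    h = max(rows) - r0 + 1
    w = max(cols) - c0 + 1
    m = np.zeros((h + 2, w + 2), dtype=float)
    for r, c in pixel_set:
        m[r - r0 + 1, c - c0 + 1] = 1.0
    contours = measure.find_contours(m, 0.5)
    outer = max(contours, key=len)
    if np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]
    xy = np.empty_like(outer)
    xy[:, 0] = outer[:, 1] + c0 - 1  # x = column
    xy[:, 1] = outer[:, 0] + r0 - 1  # y = row
    return xy


def segment_glands(img: RegionImage,
                   params: Optional[SegmentationParams] = None,
                   ) -> List[GlandSegment]:
    """Full gland segmentation pipeline for one annotated region.

    detect_seeds -> grow_region per seed -> resolve_overlaps -> drop regions
    below the minimum area -> extract boundary polygon and centroid.  Gland
    ids are assigned in raster order of the surviving seeds.
    """
    params = params or SegmentationParams()
    lum = to_luminance(img)
    seeds = detect_seeds(lum, img.mask, params)
    candidates = []
    meta = []
    for seed, scale in seeds:
        px, strength = grow_region(lum, seed, params.box_size(scale), mask=img.mask)
        candidates.append((px, strength))
        meta.append((seed, scale))
    survivors = resolve_overlaps(candidates)
    kept = [(candidates[i][0], candidates[i][1], meta[i][0], meta[i][1])
            for i in survivors
            if len(candidates[i][0]) >= params.min_gland_area_px]
    kept.sort(key=lambda t: t[2])  # raster order of seeds
    out = []
    for gid, (px, strength, seed, scale) in enumerate(kept):
        arr = np.array(sorted(px))
        centroid = (float(arr[:, 1].mean()), float(arr[:, 0].mean()))
        out.append(GlandSegment(
            gland_id=gid,
            boundary=boundary_polygon(px),
            pixel_set=px,
            centroid=centroid,
            boundary_strength=strength,
            seed=seed,
            scale_px=scale,
        ))
    return out
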