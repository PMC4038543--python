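"""Gland orientation estimation.

Each gland's dominant orientation is the first principal component of its
boundary points: the major axis along which the boundary varies most.  The
axis is undirected, so angles live on the half-circle [0, 180).  Angles are
measured counterclockwise from +x in the (x, y) plane of the boundary
coordinates; with image coordinates (x = column, y = row) the on-screen
appearance is mirrored, which is immaterial for axial-disorder statistics
as long as every module shares the convention (they do).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np

from .segmentation import GlandSegment


@dataclass
class GlandOrientation:
    gland_id: int
    theta_deg: float            # in [0, 180)
    eccentricity: float         # sqrt(1 - lambda2/lambda1), in [0, 1]
    principal_axis: Tuple[float, float]  # unit (vx, vy) in image coords


def principal_axis(boundary: np.ndarray) -> Tuple[np.ndarray, float]:
    """Major axis of a point set and the eigenvalue ratio lambda2/lambda1.

    The axis is the eigenvector of the 2x2 covariance of the centered points
    belonging to the larger eigenvalue; its sign is arbitrary.  The ratio is
    in [0, 1] (1 for rotationally symmetric sets).
    """
    pts = np.asarray(boundary, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("need at least 3 (x, y) points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    if np.trace(cov) <= 0:
        raise ValueError("zero total variance")
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    axis = evecs[:, 1]
    ratio = float(evals[0] / evals[1]) if evals[1] > 0 else 1.0
    ratio = min(max(ratio, 0.0), 1.0)
    return axis / np.linalg.norm(axis), ratio


def gland_angle(axis) -> float:
    """Counterclockwise angle of an undirected axis from +x, in [0, 180).

    ``axis`` is a (vx, vy) vector; v and -v map to the same angle, e.g.
    (0, 1) and (0, -1) both give 90.
    """
    vx, vy = float(axis[0]), float(axis[1])
    if vx == 0.0 and vy == 0.0:
        raise ValueError("zero vector has no direction")
    ang = np.degrees(np.arctan2(vy, vx))
    ang %= 180.0
    if ang >= 180.0:  # guard the 179.999... -> 180.0 rounding edge
        ang -= 180.0
    return float(ang)


def resample_closed_polygon(boundary: np.ndarray, n: int = 256) -> np.ndarray:
    """Resample a closed polygon to n points uniformly spaced by arc length.

    Contour extraction emits vertices wherever the curve crosses a pixel
    grid line, so raw vertex density depends on local direction; uniform
    resampling removes the resulting orientation bias (up to a few degrees
    for moderately elongated glands) before PCA.
    """
    p = np.vstack([boundary, boundary[:1]])
    seg = np.hypot(*np.diff(p, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate boundary with zero length")
    t = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.column_stack([np.interp(t, s, p[:, 0]), np.interp(t, s, p[:, 1])])


def orientations(glands: Iterable[GlandSegment]) -> List[GlandOrientation]:
    """Orientation of every gland from its boundary polygon.

    Boundaries are resampled uniformly by arc length before PCA.
    Near-circular glands (eigenvalue ratio > 0.95, eccentricity < ~0.22) are
    not excluded; their angle is whatever the eigensolver returns and their
    low eccentricity flags the instability.
    """
    out = []
    for g in glands:
        axis, ratio = principal_axis(resample_closed_polygon(g.boundary))
        out.append(GlandOrientation(
            gland_id=g.gland_id,
            theta_deg=gland_angle(axis),
            eccentricity=float(np.sqrt(1.0 - ratio)),
            principal_axis=(float(axis[0]), float(axis[1])),
        ))
    return out
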