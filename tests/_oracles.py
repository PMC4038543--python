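"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the defining formulas with plain loops and
none of the package's computational paths (no shared helpers, no vectorized
shortcuts), so agreement with the package is meaningful.
"""

import math
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# second-order co-occurrence statistics
# ---------------------------------------------------------------------------

def oracle_haralick(counts):
    """The 13 second-order statistics by direct summation."""
    counts = np.asarray(counts, dtype=float)
    B = counts.shape[0]
    total = counts.sum()
    p = counts / total

    p_diff = {}
    p_sum = {}
    for a in range(B):
        for b in range(B):
            p_diff[abs(a - b)] = p_diff.get(abs(a - b), 0.0) + p[a, b]
            p_sum[a + b] = p_sum.get(a + b, 0.0) + p[a, b]

    def ent(dist):
        return -sum(v * math.log2(v) for v in dist if v > 0)

    c_avg = sum(k * v for k, v in p_diff.items())
    c_var = sum((k - c_avg) ** 2 * v for k, v in p_diff.items())
    i_avg = sum(k * v for k, v in p_sum.items())
    i_var = sum((k - i_avg) ** 2 * v for k, v in p_sum.items())

    px = [sum(p[a, b] for b in range(B)) for a in range(B)]
    py = [sum(p[a, b] for a in range(B)) for b in range(B)]
    mx = sum(a * px[a] for a in range(B))
    my = sum(b * py[b] for b in range(B))
    vx = sum((a - mx) ** 2 * px[a] for a in range(B))
    vy = sum((b - my) ** 2 * py[b] for b in range(B))
    if vx > 0 and vy > 0:
        cov = sum((a - mx) * (b - my) * p[a, b]
                  for a in range(B) for b in range(B))
        corr = cov / math.sqrt(vx * vy)
    else:
        corr = 0.0

    hxy = ent(p.ravel())
    hx = ent(px)
    hy = ent(py)
    hxy1 = -sum(p[a, b] * math.log2(px[a] * py[b])
                for a in range(B) for b in range(B)
                if p[a, b] > 0 and px[a] * py[b] > 0)
    hxy2 = ent([px[a] * py[b] for a in range(B) for b in range(B)])
    denom = max(hx, hy)
    info1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    info2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return {
        "contrast_energy": sum(v ** 2 for v in p_diff.values()),
        "contrast_inverse_moment": sum(v / (1.0 + k ** 2)
                                       for k, v in p_diff.items()),
        "contrast_average": c_avg,
        "contrast_variance": c_var,
        "contrast_entropy": ent(p_diff.values()),
        "intensity_average": i_avg,
        "intensity_variance": i_var,
        "intensity_entropy": ent(p_sum.values()),
        "entropy": hxy,
        "energy": sum(p[a, b] ** 2 for a in range(B) for b in range(B)),
        "correlation": corr,
        "info_measure_1": info1,
        "info_measure_2": info2,
    }


def oracle_cooccurrence(angles, omega):
    """Symmetric pair-count matrix over a list of angles, by enumeration."""
    B = math.ceil(180.0 / omega)
    m = np.zeros((B, B), dtype=int)
    for i, j in combinations(range(len(angles)), 2):
        a = min(int(angles[i] // omega), B - 1)
        b = min(int(angles[j] // omega), B - 1)
        m[a, b] += 1
        m[b, a] += 1
    return m


# ---------------------------------------------------------------------------
# graph constructions
# ---------------------------------------------------------------------------

def oracle_components(nodes, edges):
    """Connected components by Warshall-style transitive closure."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    reach = [[i == j for j in range(n)] for i in range(n)]
    for a, b in edges:
        reach[idx[a]][idx[b]] = True
        reach[idx[b]][idx[a]] = True
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    comps = set()
    for i in range(n):
        comps.add(frozenset(nodes[j] for j in range(n) if reach[i][j]))
    return comps


def oracle_prim_mst_weight(points):
    """Total Euclidean MST weight by Prim's algorithm, hand-coded."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    in_tree = [False] * n
    dist = [math.inf] * n
    dist[0] = 0.0
    total = 0.0
    for _ in range(n):
        u = min((i for i in range(n) if not in_tree[i]), key=lambda i: dist[i])
        in_tree[u] = True
        total += dist[u]
        for v in range(n):
            if not in_tree[v]:
                d = math.hypot(*(points[u] - points[v]))
                if d < dist[v]:
                    dist[v] = d
    return total


def oracle_delaunay_triangles(points):
    """Delaunay triangles by brute-force empty-circumcircle test.

    Assumes points in general position (no 4 cocircular, no 3 collinear).
    Returns a set of index triples.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    tris = set()
    for i, j, k in combinations(range(n), 3):
        ax, ay = pts[i]
        bx, by = pts[j]
        cx, cy = pts[k]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
              + (cx ** 2 + cy ** 2) * (ay - by)) / d
        uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
              + (cx ** 2 + cy ** 2) * (bx - ax)) / d
        r2 = (ax - ux) ** 2 + (ay - uy) ** 2
        empty = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if (pts[m, 0] - ux) ** 2 + (pts[m, 1] - uy) ** 2 < r2 - 1e-9:
                empty = False
                break
        if empty:
            tris.add(tuple(sorted((i, j, k))))
    return tris


def oracle_voronoi_cells(points, window):
    """Voronoi cells clipped to a rectangular window, by intersecting
    half-planes with shapely geometry only (no Voronoi construction).

    ``window`` is (xmin, ymin, xmax, ymax).  Returns one polygon per point.
    """
    from shapely.geometry import box

    pts = np.asarray(points, dtype=float)
    cells = []
    for i in range(len(pts)):
        cell = box(*window)
        for j in range(len(pts)):
            if i == j:
                continue
            cell = _halfplane_clip(cell, pts[i], pts[j])
            if cell.is_empty:
                break
        cells.append(cell)
    return cells


def _halfplane_clip(poly, p, q):
    """Clip a convex polygon to the half-plane of points closer to p than q
    (Sutherland-Hodgman against the bisector)."""
    from shapely.geometry import Polygon

    if poly.is_empty:
        return poly
    mid = (p + q) / 2.0
    normal = q - p  # points toward q; keep side where (v - mid) . normal <= 0
    verts = list(poly.exterior.coords[:-1])
    out = []
    m = len(verts)
    for k in range(m):
        a = np.asarray(verts[k])
        b = np.asarray(verts[(k + 1) % m])
        da = float(np.dot(a - mid, normal))
        db = float(np.dot(b - mid, normal))
        if da <= 0:
            out.append(tuple(a))
            if db > 0:
                t = da / (da - db)
                out.append(tuple(a + t * (b - a)))
        elif db <= 0:
            t = da / (da - db)
            out.append(tuple(a + t * (b - a)))
    if len(out) < 3:
        return Polygon()
    return Polygon(out)


def oracle_density(points, radii, ks):
    """All-pairs counts within radii and k-th nearest distances."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    counts = {r: [] for r in radii}
    knn = {k: [] for k in ks}
    for i in range(n):
        d = sorted(math.hypot(*(pts[i] - pts[j])) for j in range(n) if j != i)
        for r in radii:
            counts[r].append(sum(1 for x in d if x <= r))
        for k in ks:
            knn[k].append(d[k - 1])
    return counts, knn


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def oracle_auc_pairs(scores, labels):
    """AUC as the fraction of positive/negative pairs ranked correctly,
    ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_km(times, events):
    """Product-limit survival estimate at each distinct event time."""
    order = sorted(set(t for t, e in zip(times, events) if e))
    s = 1.0
    curve = []
    for t in order:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ei and ti == t)
        s *= 1.0 - d / at_risk
        curve.append((t, s))
    return curve


def oracle_logrank(times_a, events_a, times_b, events_b):
    """Two-group logrank chi-square by observed/expected tabulation."""
    all_times = sorted(set([t for t, e in zip(times_a, events_a) if e]
                           + [t for t, e in zip(times_b, events_b) if e]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n1 = sum(1 for ti in times_a if ti >= t)
        n2 = sum(1 for ti in times_b if ti >= t)
        d1 = sum(1 for ti, ei in zip(times_a, events_a) if ei and ti == t)
        d2 = sum(1 for ti, ei in zip(times_b, events_b) if ei and ti == t)
        n = n1 + n2
        d = d1 + d2
        if n == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e ** 2 / var
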