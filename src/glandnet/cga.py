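"""Co-occurring gland angularity (CGA) features.

Gland angles are discretized into omega-degree bins on [0, 180); for every
gland network (connected component of the sparsified gland graph) a B x B
angular co-occurrence matrix counts, symmetrically, the binned angle pairs
of all unordered gland pairs in the network.  Thirteen second-order
statistics summarize each matrix, and their mean, standard deviation and
range across the networks of a region form the 39-element CGA descriptor.
A network whose glands all point the same way concentrates counts near the
diagonal (low entropy); disordered networks spread counts off-diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np

from ._haralick import STAT_NAMES, haralick_stats
from .gland_graph import GlandGraph, Neighborhood, neighborhoods

DEFAULT_OMEGA_DEG = 10.0


def n_bins(omega_deg: float) -> int:
    """Number of angular bins B = ceil(180 / omega); omega = 10 gives B = 18."""
    if not 0 < omega_deg <= 180:
        raise ValueError("omega must be in (0, 180]")
    return int(np.ceil(180.0 / omega_deg))


@dataclass
class AngularCooccurrenceMatrix:
    counts: np.ndarray            # B x B non-negative integers, symmetric
    omega_deg: float
    B: int
    neighborhood_id: int


def discretize_angle(theta_deg: float, omega_deg: float = DEFAULT_OMEGA_DEG) -> int:
    """Bin index floor(theta / omega) of an angle in [0, 180)."""
    if not 0.0 <= theta_deg < 180.0:
        raise ValueError(f"angle {theta_deg} outside [0, 180)")
    b = int(theta_deg // omega_deg)
    return min(b, n_bins(omega_deg) - 1)


def cooccurrence_matrix(orientations: Mapping[int, float], hood: Neighborhood,
                        omega_deg: float = DEFAULT_OMEGA_DEG,
                        neighborhood_id: int = 0) -> AngularCooccurrenceMatrix:
    """Angular co-occurrence matrix of one gland network.

    Every unordered pair (i, j) of distinct member glands increments both
    counts[bin(theta_i)][bin(theta_j)] and its transpose, so the matrix is
    symmetric with total count twice the number of pairs.  Singleton
    networks yield the all-zero matrix.
    """
    B = n_bins(omega_deg)
    counts = np.zeros((B, B), dtype=np.int64)
    members = sorted(hood.member_ids)
    for gid in members:
        if gid not in orientations:
            raise KeyError(f"no orientation for gland {gid}")
    bins = [discretize_angle(orientations[g], omega_deg) for g in members]
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            counts[bins[i], bins[j]] += 1
            counts[bins[j], bins[i]] += 1
    return AngularCooccurrenceMatrix(counts=counts, omega_deg=omega_deg, B=B,
                                     neighborhood_id=neighborhood_id)


def second_order_stats(m: AngularCooccurrenceMatrix) -> Dict[str, float]:
    """The 13 second-order angular statistics of one co-occurrence matrix."""
    return haralick_stats(m.counts)


def cga_feature_names() -> List[str]:
    names = []
    for stat in STAT_NAMES:
        names += [f"cga_{stat}_mean", f"cga_{stat}_std", f"cga_{stat}_range"]
    return names


@dataclass
class CGAFeatureVector:
    values: Dict[str, float]      # the 39 named features
    n_neighborhoods_used: int


def cga_vector(orientations: Mapping[int, float], graph: GlandGraph,
               omega_deg: float = DEFAULT_OMEGA_DEG) -> CGAFeatureVector:
    """The 39 CGA features of one region.

    For every gland network with at least one angle pair the 13 statistics
    are computed; each statistic is aggregated across networks by mean,
    sample (n-1) standard deviation (0 for a single network) and range.
    With no usable network the vector is all zeros with
    ``n_neighborhoods_used = 0`` and a warning.
    """
    per_hood = []
    for k, hood in enumerate(neighborhoods(graph)):
        m = cooccurrence_matrix(orientations, hood, omega_deg, neighborhood_id=k)
        if m.counts.sum() > 0:
            per_hood.append(second_order_stats(m))
    values = {}
    if not per_hood:
        warnings.warn("no gland network with >= 2 members; degenerate CGA vector")
        for name in cga_feature_names():
            values[name] = 0.0
        return CGAFeatureVector(values=values, n_neighborhoods_used=0)
    for stat in STAT_NAMES:
        col = np.array([h[stat] for h in per_hood], dtype=float)
        values[f"cga_{stat}_mean"] = float(col.mean())
        values[f"cga_{stat}_std"] = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        values[f"cga_{stat}_range"] = float(col.max() - col.min())
    return CGAFeatureVector(values=values, n_neighborhoods_used=len(per_hood))
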