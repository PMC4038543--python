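"""End-to-end convenience pipelines tying the stages together."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import qh_comparators as qh
from .cga import DEFAULT_OMEGA_DEG, CGAFeatureVector, cga_vector
from .gland_geometry import orientations
from .gland_graph import GlandGraph, GraphParams, build_subgraph
from .imaging_io import RegionImage, to_luminance
from .segmentation import GlandSegment, SegmentationParams, segment_glands
from .synthetic import CohortCase, PhantomTruth


def layout_graph(truth: PhantomTruth,
                 graph_params: Optional[GraphParams] = None) -> GlandGraph:
    """Gland graph over the ground-truth centers of a phantom layout."""
    centroids = [(i, float(x), float(y))
                 for i, (x, y) in enumerate(truth.centers_xy)]
    return build_subgraph(centroids, graph_params)


def cga_features_from_layout(truth: PhantomTruth,
                             graph_params: Optional[GraphParams] = None,
                             omega_deg: float = DEFAULT_OMEGA_DEG,
                             ) -> CGAFeatureVector:
    """CGA features of a phantom layout using its true gland orientations."""
    graph = layout_graph(truth, graph_params)
    angle_map = {i: float(t) for i, t in enumerate(truth.angles_deg)}
    return cga_vector(angle_map, graph, omega_deg)


def cohort_feature_table(cases: Sequence[CohortCase],
                         graph_params: Optional[GraphParams] = None,
                         omega_deg: float = DEFAULT_OMEGA_DEG,
                         ) -> Tuple[pd.DataFrame, np.ndarray]:
    """CGA feature table of a synthetic cohort.

    Returns (DataFrame indexed by case_id, binary labels with BCR = 1).
    """
    rows = []
    labels = []
    for case in cases:
        vec = cga_features_from_layout(case.truth, graph_params, omega_deg)
        rows.append(pd.Series(vec.values, name=case.case_id))
        labels.append(1 if case.label == "BCR" else 0)
    return pd.DataFrame(rows), np.asarray(labels, dtype=int)


def cga_features_from_image(img: RegionImage,
                            seg_params: Optional[SegmentationParams] = None,
                            graph_params: Optional[GraphParams] = None,
                            omega_deg: float = DEFAULT_OMEGA_DEG,
                            ) -> Tuple[CGAFeatureVector, List[GlandSegment]]:
    """Segment a region and compute its CGA features."""
    glands = segment_glands(img, seg_params)
    orient = orientations(glands)
    angle_map = {o.gland_id: o.theta_deg for o in orient}
    centroids = [(g.gland_id, g.centroid[0], g.centroid[1]) for g in glands]
    if not centroids:
        raise ValueError("no glands segmented in region")
    graph = build_subgraph(centroids, graph_params)
    return cga_vector(angle_map, graph, omega_deg), glands


def comparator_features(img: RegionImage, glands: Sequence[GlandSegment],
                        families: Sequence[str] = ("morphology", "voronoi",
                                                   "delaunay", "mst",
                                                   "density", "texture"),
                        ) -> Dict[str, float]:
    """Concatenated comparator feature values for the requested families."""
    centroids = np.array([g.centroid for g in glands], dtype=float)
    out: Dict[str, float] = {}
    for family in families:
        if family == "morphology":
            vec = qh.morphology_features(list(glands))
        elif family == "voronoi":
            vec = qh.voronoi_features(centroids)
        elif family == "delaunay":
            vec = qh.delaunay_features(centroids)
        elif family == "mst":
            vec = qh.mst_features(centroids)
        elif family == "density":
            vec = qh.density_features(centroids)
        elif family == "texture":
            vec = qh.intensity_texture_features(to_luminance(img), img.mask)
        else:
            raise ValueError(f"unknown family {family!r}")
        out.update(vec.values)
    return out
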