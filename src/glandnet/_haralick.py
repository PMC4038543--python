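"""Second-order (Haralick-family) statistics of a symmetric co-occurrence
matrix, shared by the angular (gland-orientation) and image-intensity
co-occurrence features.

Conventions: with p the count matrix normalized to sum 1, p_x its row
marginal, p_{x+y}(k) = sum over a+b=k, and p_{|x-y|}(k) = sum over |a-b|=k,
the contrast family is computed on p_{|x-y|}, the intensity family on
p_{x+y}, and entropy/energy/correlation on p itself.  All logarithms are
base 2 with 0*log(0) = 0; correlation is 0 when a marginal variance
vanishes, and the two information measures use the HXY1/HXY2 forms.
"""

from __future__ import annotations

import numpy as np

STAT_NAMES = (
    "contrast_energy",
    "contrast_inverse_moment",
    "contrast_average",
    "contrast_variance",
    "contrast_entropy",
    "intensity_average",
    "intensity_variance",
    "intensity_entropy",
    "entropy",
    "energy",
    "correlation",
    "info_measure_1",
    "info_measure_2",
)


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_stats(counts: np.ndarray) -> dict:
    """The 13 second-order statistics of a B x B co-occurrence count matrix.

    The matrix total must be positive; the counts are normalized to a joint
    distribution internally.  Returns an ordered name -> value dict (order of
    ``STAT_NAMES``).
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("co-occurrence matrix has zero total count")
    p = counts / total
    B = p.shape[0]
    a = np.arange(B, dtype=float)

    idx = np.add.outer(np.arange(B), np.arange(B))           # a + b
    p_sum = np.bincount(idx.ravel(), weights=p.ravel(), minlength=2 * B - 1)
    idx = np.abs(np.subtract.outer(np.arange(B), np.arange(B)))  # |a - b|
    p_diff = np.bincount(idx.ravel(), weights=p.ravel(), minlength=B)

    k_diff = np.arange(B, dtype=float)
    k_sum = np.arange(2 * B - 1, dtype=float)

    contrast_average = float((k_diff * p_diff).sum())
    contrast_variance = float(((k_diff - contrast_average) ** 2 * p_diff).sum())
    intensity_average = float((k_sum * p_sum).sum())
    intensity_variance = float(((k_sum - intensity_average) ** 2 * p_sum).sum())

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((a * px).sum())
    mu_y = float((a * py).sum())
    var_x = float(((a - mu_x) ** 2 * px).sum())
    var_y = float(((a - mu_y) ** 2 * py).sum())
    if var_x > 0 and var_y > 0:
        cov = float((np.outer(a - mu_x, a - mu_y) * p).sum())
        correlation = cov / np.sqrt(var_x * var_y)
    else:
        correlation = 0.0

    hxy = _entropy_bits(p)
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = _entropy_bits(pxpy)
    denom = max(hx, hy)
    info1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    info2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "contrast_energy": float((p_diff ** 2).sum()),
        "contrast_inverse_moment": float((p_diff / (1.0 + k_diff ** 2)).sum()),
        "contrast_average": contrast_average,
        "contrast_variance": contrast_variance,
        "contrast_entropy": _entropy_bits(p_diff),
        "intensity_average": intensity_average,
        "intensity_variance": intensity_variance,
        "intensity_entropy": _entropy_bits(p_sum),
        "entropy": hxy,
        "energy": float((p ** 2).sum()),
        "correlation": float(correlation),
        "info_measure_1": float(info1),
        "info_measure_2": info2,
    }
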