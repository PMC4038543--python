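"""Ground-truthed gland phantoms and synthetic cohorts.

Phantoms emulate a pathologist-annotated region: bright elliptical
gland-like blobs on darker stroma, with controllable count, size, spacing
and -- the property of interest -- orientation disorder.  Orientations are
axial (defined modulo 180 degrees) and are drawn from a wrapped von Mises
distribution on the half-circle: concentration ``kappa`` -> infinity gives
perfectly aligned glands, ``kappa`` = 0 a uniform (fully disordered)
orientation field.  Cohorts pair ordered ("non-recurrence"-like) and
disordered ("recurrence"-like) cases with class-specific exponential
survival times, so the full feature -> classifier -> survival pipeline can
be exercised without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from shapely.geometry import MultiPoint
from skimage import draw as skdraw

from .imaging_io import RegionImage


@dataclass
class PhantomSpec:
    """Parameters of one phantom region.

    Defaults are sized for a 512 x 512 region at 0.5 um/px: 25 glands with
    ~30/12 px semi-axes, gland luminance L* ~ 85 on an L* ~ 45 background
    with sigma = 3 pixel noise, at least 70 px between gland centers.
    """

    image_size_px: Tuple[int, int] = (512, 512)
    n_glands: int = 25
    gland_axes_px: Tuple[float, float, float] = (30.0, 12.0, 0.2)  # major, minor, rel. jitter
    base_orientation_deg: float = 45.0
    orientation_kappa: float = 8.0
    min_spacing_px: float = 70.0
    gland_intensity: Tuple[float, float] = (85.0, 3.0)   # L* mean, noise sigma
    background_intensity: Tuple[float, float] = (45.0, 3.0)
    annotation_margin_px: float = 15.0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: per-gland geometry plus region metadata."""

    centers_xy: np.ndarray        # (n, 2) gland centers (x, y)
    axes_px: np.ndarray           # (n, 2) semi-axes (major, minor)
    angles_deg: np.ndarray        # (n,) true orientations in [0, 180)
    orientation_kappa: float
    label: Optional[str] = None
    time_months: Optional[float] = None
    event: Optional[bool] = None


def sample_axial_angles(rng: np.random.Generator, n: int, base_deg: float,
                        kappa: float) -> np.ndarray:
    """Draw axial orientations on [0, 180) from a wrapped von Mises.

    The doubled angles 2*theta follow a von Mises with the given
    concentration, the standard construction for axial data; kappa = 0 is
    the uniform distribution on the half-circle.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    phi = rng.vonmises(0.0, kappa, size=n)    # on [-pi, pi)
    theta = (base_deg + np.degrees(phi) / 2.0) % 180.0
    return theta


def circular_dispersion(angles_deg: np.ndarray) -> float:
    """Axial circular variance 1 - |mean resultant| of the doubled angles,
    in [0, 1]: 0 for perfectly aligned, -> 1 for uniform orientations."""
    z = np.exp(2j * np.radians(np.asarray(angles_deg, dtype=float)))
    return float(1.0 - np.abs(z.mean()))


def circular_std_deg(angles_deg: np.ndarray) -> float:
    """Axial circular standard deviation in degrees."""
    z = np.exp(2j * np.radians(np.asarray(angles_deg, dtype=float)))
    rbar = max(np.abs(z.mean()), 1e-300)
    return float(np.degrees(np.sqrt(-2.0 * np.log(rbar))) / 2.0)


def _place_centers(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    H, W = spec.image_size_px
    major, minor, jit = spec.gland_axes_px
    margin = major * (1.0 + jit) + 5.0
    if 2 * margin >= min(H, W):
        raise ValueError("glands do not fit inside the image")
    centers = []
    budget = spec.n_glands * 2000
    while len(centers) < spec.n_glands:
        if budget <= 0:
            raise ValueError("could not place glands with the given spacing")
        budget -= 1
        x = rng.uniform(margin, W - margin)
        y = rng.uniform(margin, H - margin)
        if all(np.hypot(x - cx, y - cy) >= spec.min_spacing_px
               for cx, cy in centers):
            centers.append((x, y))
    return np.array(centers)


def generate_layout(spec: PhantomSpec) -> PhantomTruth:
    """Gland centers, semi-axes and true orientations, without rendering.

    This is the fast path used for graph/angularity studies where the
    segmentation stage is not under test.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(rng, spec)
    major, minor, jit = spec.gland_axes_px
    axes = np.column_stack([
        major * (1.0 + rng.uniform(-jit, jit, spec.n_glands)),
        minor * (1.0 + rng.uniform(-jit, jit, spec.n_glands)),
    ])
    angles = sample_axial_angles(rng, spec.n_glands, spec.base_orientation_deg,
                                 spec.orientation_kappa)
    return PhantomTruth(centers_xy=centers, axes_px=axes, angles_deg=angles,
                        orientation_kappa=spec.orientation_kappa)


def ellipse_mask_points(center_xy, axes, theta_deg, shape) -> Tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels inside a rotated ellipse.

    ``theta_deg`` is the major-axis angle in the (x = column, y = row)
    plane, the same convention the orientation estimator recovers.
    """
    cx, cy = center_xy
    a, b = axes
    H, W = shape
    r0 = max(0, int(np.floor(cy - a - 1)))
    r1 = min(H - 1, int(np.ceil(cy + a + 1)))
    c0 = max(0, int(np.floor(cx - a - 1)))
    c1 = min(W - 1, int(np.ceil(cx + a + 1)))
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    dx = cc - cx
    dy = rr - cy
    t = np.radians(theta_deg)
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _lstar_to_gray8(lstar: np.ndarray) -> np.ndarray:
    """Invert the sRGB -> L* mapping for neutral grays (D65), to 8-bit."""
    L = np.clip(np.asarray(lstar, dtype=float), 0.0, 100.0)
    fy = (L + 16.0) / 116.0
    y = np.where(L > 8.0, fy ** 3, L / 903.2962962962963)
    srgb = np.where(y > 0.0031308,
                    1.055 * np.power(y, 1 / 2.4) - 0.055,
                    12.92 * y)
    return np.clip(np.round(srgb * 255.0), 0, 255).astype(np.uint8)


def _annotation_mask(truth: PhantomTruth, spec: PhantomSpec) -> np.ndarray:
    """Pathologist-annotation-like mask: the glandular tissue, i.e. every
    gland dilated by the annotation margin.  Like a real annotation it
    excludes gland-free stroma."""
    H, W = spec.image_size_px
    mask = np.zeros((H, W), dtype=bool)
    m = spec.annotation_margin_px
    for center, axes, theta in zip(truth.centers_xy, truth.axes_px,
                                   truth.angles_deg):
        rr, cc = ellipse_mask_points(center, (axes[0] + m, axes[1] + m),
                                     theta, (H, W))
        mask[rr, cc] = True
    return mask


def generate_phantom(spec: PhantomSpec) -> Tuple[RegionImage, PhantomTruth]:
    """Render a phantom region image with its ground truth.

    Bright noisy ellipses on a darker noisy background, composed in L*
    space and converted to an 8-bit neutral-gray RGB raster (quantization
    perturbs the luminance by at most ~0.25 L*).  The annotation mask is the
    dilated convex hull of the glands.  Fully determined by ``spec.seed``.
    """
    truth = generate_layout(spec)
    # the layout consumed its own generator stream; derive a fresh one for
    # the pixel noise so layout and rendering stay independently seeded
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    H, W = spec.image_size_px
    bg_mean, bg_sigma = spec.background_intensity
    g_mean, g_sigma = spec.gland_intensity
    lstar = rng.normal(bg_mean, bg_sigma, size=(H, W))
    for center, axes, theta in zip(truth.centers_xy, truth.axes_px,
                                   truth.angles_deg):
        rr, cc = ellipse_mask_points(center, axes, theta, (H, W))
        lstar[rr, cc] = rng.normal(g_mean, g_sigma, size=rr.shape)
    gray = _lstar_to_gray8(lstar)
    pixels = np.repeat(gray[..., None], 3, axis=2)
    mask = _annotation_mask(truth, spec)
    img = RegionImage(pixels=pixels, mask=mask,
                      region_id=f"phantom_seed{spec.seed}")
    return img, truth


def truth_pixel_sets(truth: PhantomTruth, shape) -> List[set]:
    """Ground-truth pixel sets of each gland (for Dice comparisons)."""
    out = []
    for center, axes, theta in zip(truth.centers_xy, truth.axes_px,
                                   truth.angles_deg):
        rr, cc = ellipse_mask_points(center, axes, theta, shape)
        out.append(set(zip(rr.tolist(), cc.tolist())))
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class SurvivalParams:
    """Exponential recurrence hazards (per month) and independent uniform
    censoring on [0, censor_max_months]."""

    hazard_positive: float = 0.03    # recurrence-like class, median ~ 23 mo
    hazard_negative: float = 0.004   # non-recurrence-like class
    censor_max_months: float = 120.0

    def __post_init__(self):
        if self.hazard_positive <= 0 or self.hazard_negative <= 0:
            raise ValueError("hazards must be positive")


@dataclass
class CohortCase:
    case_id: str
    label: str                    # "BCR" (disordered) or "NR" (ordered)
    kappa: float
    truth: PhantomTruth


def generate_cohort(n_cases: int = 40, ordered_kappa: float = 32.0,
                    disordered_kappa: float = 0.0,
                    survival_params: Optional[SurvivalParams] = None,
                    seed: int = 0,
                    template: Optional[PhantomSpec] = None) -> List[CohortCase]:
    """Generate a labeled cohort of gland layouts with survival times.

    Half the cases are ordered (NR-like, ``ordered_kappa``), half disordered
    (BCR-like, ``disordered_kappa``); each case has its own base orientation
    and layout.  Survival is exponential with class-specific hazards and
    independent uniform censoring.
    """
    if n_cases % 2 != 0:
        raise ValueError("n_cases must be even for an equal class split")
    sp = survival_params or SurvivalParams()
    template = template or PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        label = "BCR" if i < n_cases // 2 else "NR"
        kappa = disordered_kappa if label == "BCR" else ordered_kappa
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(template,
                       base_orientation_deg=float(rng.uniform(0.0, 180.0)),
                       orientation_kappa=kappa,
                       seed=case_seed)
        truth = generate_layout(spec)
        hazard = sp.hazard_positive if label == "BCR" else sp.hazard_negative
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.uniform(0.0, sp.censor_max_months)
        truth.label = label
        truth.time_months = float(min(t_event, t_censor))
        truth.event = bool(t_event <= t_censor)
        truth.orientation_kappa = kappa
        cases.append(CohortCase(case_id=f"case{i:03d}", label=label,
                                kappa=kappa, truth=truth))
    return cases
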