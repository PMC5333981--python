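"""Synthetic vessel patterns, ROI layouts and rendered IHC images.

Every downstream stage of the pipeline is testable without real slides:

* :func:`generate_csr_points` draws a homogeneous 2D Poisson pattern (complete
  spatial randomness, the null model of the belt statistic) inside an
  arbitrary polygon by rejection sampling.
* :func:`generate_belt_pattern` plants a "vascular belt": a strip of stated
  width abutting a reference region in which the vessel intensity is boosted
  by a known enrichment factor, returning the analytic planted excess as
  ground truth.
* :func:`render_ihc_image` turns a point pattern into a DAB-on-hematoxylin
  RGB image of elliptical vessel profiles via the same optical-density stain
  model the segmentation inverts, so segmentation accuracy can be scored
  against the planted centroid table.

The default layout stacks three bands — intestinal lumen (1 mm), tumor (5 mm)
and adjacent tissue (2 mm) — across a 10 mm wide domain at 0.5 um/pixel,
comparable in scale to the belt zones the statistic is meant to find (~1.3 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, GeometryError
from .roi import ADJACENT, LUMEN, TUMOR, PointPattern, RoiSet, canonical_label
from .seeds import as_rng
from .stains import DEFAULT_HDAB, StainModel, reconstruct_rgb

__all__ = [
    "SyntheticLayout",
    "BeltSpec",
    "generate_csr_points",
    "generate_belt_pattern",
    "render_ihc_image",
]

_MAX_REJECTION_TRIES = 10**6  # per requested point, to surface pathological geometry


@dataclass(frozen=True)
class SyntheticLayout:
    """Three stacked rectangular ROIs: lumen on top, tumor, adjacent below.

    All extents in mm; ``mpp`` (um/pixel) is only used when rendering.  The
    y axis points downward (image convention), x rightward, origin at the
    top-left corner.
    """

    domain_width: float = 10.0
    lumen_band_height: float = 1.0
    tumor_band_height: float = 5.0
    adjacent_band_height: float = 2.0
    mpp: float = 0.5

    def __post_init__(self) -> None:
        for name in ("domain_width", "lumen_band_height", "tumor_band_height",
                     "adjacent_band_height", "mpp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def domain_height(self) -> float:
        return self.lumen_band_height + self.tumor_band_height + self.adjacent_band_height

    @property
    def tumor_top(self) -> float:
        return self.lumen_band_height

    @property
    def tumor_bottom(self) -> float:
        return self.lumen_band_height + self.tumor_band_height

    def tumor_polygon(self) -> Polygon:
        return box(0.0, self.tumor_top, self.domain_width, self.tumor_bottom)

    def to_roi_set(self) -> RoiSet:
        return RoiSet(
            {
                LUMEN: box(0.0, 0.0, self.domain_width, self.lumen_band_height),
                TUMOR: self.tumor_polygon(),
                ADJACENT: box(0.0, self.tumor_bottom, self.domain_width, self.domain_height),
            }
        )


@dataclass(frozen=True)
class BeltSpec:
    """A planted enrichment belt inside the tumor band.

    ``baseline_intensity`` (vessels/mm^2) applies outside the belt; inside the
    belt of width ``belt_width`` abutting ``reference_side`` the intensity is
    ``baseline_intensity * enrichment_factor``.  ``enrichment_factor == 1``
    reduces exactly to CSR.
    """

    baseline_intensity: float = 80.0
    belt_width: float = 1.2
    enrichment_factor: float = 4.0
    reference_side: str = LUMEN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_intensity < 0:
            raise ConfigurationError("baseline_intensity must be >= 0")
        if self.enrichment_factor < 0:
            raise ConfigurationError("enrichment_factor must be >= 0")
        if self.belt_width <= 0:
            raise ConfigurationError("belt_width must be positive")
        object.__setattr__(self, "reference_side", canonical_label(self.reference_side))
        if self.reference_side == TUMOR:
            raise ConfigurationError("reference_side must be lumen or adjacent")


def generate_csr_points(
    region: Polygon, intensity: float, seed=None, *, n_points: int | None = None
) -> PointPattern:
    """Homogeneous Poisson (CSR) pattern inside a polygon.

    The number of points is Poisson(intensity * area) unless ``n_points``
    pins it (used by the Monte-Carlo null, which conditions on the observed
    count).  Points are uniform over the region via rejection sampling from
    the bounding box.
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    area = float(region.area)
    if area <= 0:
        raise GeometryError("region polygon has zero area")
    rng = as_rng(seed)
    if n_points is None:
        n_points = int(rng.poisson(intensity * area))
    pts = sample_uniform_in_polygon(region, n_points, rng)
    return PointPattern(pts, TUMOR, area)


def sample_uniform_in_polygon(region: Polygon, n: int, rng) -> np.ndarray:
    """Uniform points in a polygon by batched rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    import shapely

    xmin, ymin, xmax, ymax = region.bounds
    bbox_area = (xmax - xmin) * (ymax - ymin)
    accept_rate = max(float(region.area) / bbox_area, 1e-12)
    out = np.empty((n, 2))
    got = 0
    tries = 0
    while got < n:
        need = n - got
        batch = max(64, int(need / accept_rate * 1.2))
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, batch), rng.uniform(ymin, ymax, batch)]
        )
        inside = shapely.contains_xy(region, cand[:, 0], cand[:, 1])
        take = cand[inside][:need]
        out[got : got + len(take)] = take
        got += len(take)
        tries += batch
        if tries > _MAX_REJECTION_TRIES * n:
            raise GeometryError("rejection sampling failed; pathological region geometry")
    return out


def generate_belt_pattern(
    layout: SyntheticLayout, spec: BeltSpec
) -> tuple[PointPattern, float]:
    """Belt-enriched pattern in the tumor band plus its analytic planted excess.

    The tumor band is split into a belt strip of width ``w`` abutting the
    reference side and the remainder; each part receives an independent CSR
    pattern at its own intensity (lambda*k in the belt, lambda outside).
    Returns ``(pattern, expected_excess)`` with
    ``expected_excess = lambda * (k - 1) * belt_area``.
    """
    w = spec.belt_width
    if w > layout.tumor_band_height:
        raise ConfigurationError("belt_width exceeds the tumor band height")
    if spec.reference_side == LUMEN:
        belt = box(0.0, layout.tumor_top, layout.domain_width, layout.tumor_top + w)
    else:
        belt = box(0.0, layout.tumor_bottom - w, layout.domain_width, layout.tumor_bottom)
    tumor = layout.tumor_polygon()
    rest = tumor.difference(belt)

    rng = as_rng(spec.seed)
    lam, k = spec.baseline_intensity, spec.enrichment_factor
    belt_pts = sample_uniform_in_polygon(belt, int(rng.poisson(lam * k * belt.area)), rng)
    rest_pts = (
        sample_uniform_in_polygon(rest, int(rng.poisson(lam * rest.area)), rng)
        if rest.area > 0
        else np.empty((0, 2))
    )
    pts = np.vstack([belt_pts, rest_pts])
    expected_excess = lam * (k - 1.0) * float(belt.area)
    return PointPattern(pts, TUMOR, float(tumor.area)), expected_excess


def render_ihc_image(
    pattern: PointPattern,
    layout: SyntheticLayout,
    *,
    major_axis_um: tuple[float, float] = (12.7, 1.7),
    aspect_range: tuple[float, float] = (0.45, 0.9),
    vessel_od: float = 0.9,
    background_od: float = 0.25,
    noise_sd: float = 4.0,
    stain_model: StainModel = DEFAULT_HDAB,
    seed=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a pattern as a DAB-on-hematoxylin RGB image plus ground truth.

    Each point becomes an ellipse with major axis ~ N(mean, sd) um (defaults
    12.7 +/- 1.7 um, the scale of real vessel profiles), random aspect ratio
    and orientation, drawn as DAB optical density ``vessel_od`` over a uniform
    hematoxylin background ``background_od``; the OD stack is pushed through
    the forward stain-mixing model, Gaussian pixel noise of ``noise_sd``
    (8-bit intensity units) is added and the result clipped to [0, 255].

    Returns ``(image, truth)`` where ``truth`` has one row per planted vessel
    (x_mm, y_mm, area_um2, major_axis_um).
    """
    rng = as_rng(seed)
    mpp = layout.mpp
    if major_axis_um[0] < mpp:
        raise ConfigurationError("vessel size below one pixel at this mpp")
    width_px = int(round(layout.domain_width * 1000.0 / mpp))
    height_px = int(round(layout.domain_height * 1000.0 / mpp))
    h_od = np.full((height_px, width_px), background_od)
    d_od = np.zeros((height_px, width_px))

    rows = []
    for x_mm, y_mm in pattern.points:
        major = max(rng.normal(*major_axis_um), 2.0 * mpp)
        aspect = rng.uniform(*aspect_range)
        theta = rng.uniform(0.0, np.pi)
        r_px = y_mm * 1000.0 / mpp
        c_px = x_mm * 1000.0 / mpp
        rr, cc = draw_ellipse(
            r_px,
            c_px,
            (major / 2.0) / mpp,
            (major * aspect / 2.0) / mpp,
            shape=(height_px, width_px),
            rotation=theta,
        )
        d_od[rr, cc] = vessel_od
        rows.append(
            {
                "x_mm": x_mm,
                "y_mm": y_mm,
                "area_um2": len(rr) * mpp * mpp,
                "major_axis_um": major,
            }
        )
    truth = pd.DataFrame(rows, columns=["x_mm", "y_mm", "area_um2", "major_axis_um"])

    concentrations = np.stack([h_od, d_od, np.zeros_like(h_od)], axis=-1)
    img = reconstruct_rgb(concentrations, stain_model, dtype=float)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), truth
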