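"""Vessel detection: DAB thresholding, morphology and object morphometry.

The pipeline is deliberately plain — color deconvolution, Otsu thresholding of
the DAB channel, a single dilation-erosion (closing) pass and connected-
component analysis — because vessel profiles are high-contrast blobs on a
counterstained background.  Each detected object carries its centroid (um),
area (um^2), best-fit-ellipse major axis (um) and solidity (area / convex
area); dilated, irregular vessels have solidity well below 1.

Coordinate convention: origin at the top-left pixel center, x rightward,
y downward; physical units via the microns-per-pixel calibration ``mpp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation, disk, erosion

from .errors import DegenerateInputError
from .stains import DEFAULT_HDAB, StainModel, color_deconvolve

__all__ = [
    "VesselObject",
    "VesselSet",
    "unsupervised_threshold",
    "morph_close",
    "detect_vessels",
    "segment_image",
]


@dataclass(frozen=True)
class VesselObject:
    """One detected vessel profile, in physical units."""

    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    major_axis_um: float
    solidity: float


@dataclass
class VesselSet:
    """Detected vessels of one image plus its calibration."""

    objects: list[VesselObject]
    mpp: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.objects)

    @property
    def centroids_um(self) -> np.ndarray:
        if not self.objects:
            return np.empty((0, 2))
        return np.array([o.centroid_um for o in self.objects])

    @property
    def centroids_mm(self) -> np.ndarray:
        return self.centroids_um / 1000.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.source,
                "x_um": [o.centroid_um[0] for o in self.objects],
                "y_um": [o.centroid_um[1] for o in self.objects],
                "area_um2": [o.area_um2 for o in self.objects],
                "major_axis_um": [o.major_axis_um for o in self.objects],
                "solidity": [o.solidity for o in self.objects],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mpp: float, source: str = "") -> "VesselSet":
        objs = [
            VesselObject(
                (float(r.x_um), float(r.y_um)),
                float(getattr(r, "area_um2", np.nan)),
                float(getattr(r, "major_axis_um", np.nan)),
                float(getattr(r, "solidity", np.nan)),
            )
            for r in df.itertuples()
        ]
        return cls(objs, mpp, source)


def unsupervised_threshold(channel: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu threshold over a 256-level quantization of the channel range.

    Returns ``(threshold, mask)`` with ``mask = channel > threshold`` —
    the threshold maximizing between-class variance.
    """
    channel = np.asarray(channel, dtype=float)
    if np.ptp(channel) == 0:
        raise DegenerateInputError("constant channel has no threshold")
    thr = float(threshold_otsu(channel, nbins=256))
    return thr, channel > thr


def morph_close(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a disk element."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    selem = disk(radius)
    return erosion(dilation(mask, selem), selem)


def detect_vessels(
    mask: np.ndarray,
    mpp: float,
    min_area_um2: float = 16.0,
    max_area_um2: float = 1e5,
    source: str = "",
) -> VesselSet:
    """Label 8-connected components and measure them in physical units.

    Components with area outside ``[min_area_um2, max_area_um2]`` are
    discarded.  An empty mask yields an empty set, not an error.
    """
    if min_area_um2 >= max_area_um2:
        raise ValueError("min_area_um2 must be < max_area_um2")
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    labels = cc_label(np.asarray(mask, dtype=bool), connectivity=2)
    px_area = mpp * mpp
    objects = []
    for prop in regionprops(labels):
        area = prop.area * px_area
        if area < min_area_um2 or area > max_area_um2:
            continue
        row, col = prop.centroid
        objects.append(
            VesselObject(
                centroid_um=(col * mpp, row * mpp),
                area_um2=float(area),
                major_axis_um=float(prop.axis_major_length * mpp),
                solidity=float(prop.solidity),
            )
        )
    return VesselSet(objects, mpp, source)


def segment_image(
    image: np.ndarray,
    mpp: float,
    *,
    stain_model: StainModel = DEFAULT_HDAB,
    close_radius: int = 1,
    min_area_um2: float = 16.0,
    max_area_um2: float = 1e5,
    min_od: float = 0.15,
    source: str = "",
    return_mask: bool = False,
):
    """Full vessel segmentation of an RGB IHC image.

    Deconvolves to the DAB channel, thresholds it (Otsu, floored at
    ``min_od`` so vessel-free images with pure background noise yield an
    empty mask), closes with a disk of ``close_radius`` and measures objects.
    """
    dab = color_deconvolve(image, stain_model)[..., 1]
    try:
        thr, _ = unsupervised_threshold(dab)
    except DegenerateInputError:
        thr = np.inf
    thr = max(thr, min_od)
    mask = morph_close(dab > thr, close_radius)
    vessels = detect_vessels(mask, mpp, min_area_um2, max_area_um2, source)
    if return_mask:
        return vessels, mask
    return vessels
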