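"""Color deconvolution of H-DAB immunohistochemistry images.

Brightfield IHC obeys a Beer-Lambert mixing model: each stain attenuates
transmitted light along a characteristic unit optical-density (OD) direction
in (R, G, B).  A pixel with intensities I relative to the unstained background
I0 has OD = -log10((I + eps) / I0), which is (approximately) a nonnegative
linear combination of the stain vectors; inverting the 3x3 stain matrix
recovers per-stain concentrations.  Default vectors are the published
hematoxylin / DAB pair (Ruifrok-Johnston convention) with the residual third
vector completed orthogonally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["StainModel", "DEFAULT_HDAB", "color_deconvolve", "reconstruct_rgb"]

_EPS = 1.0  # intensity offset avoiding log(0) on fully saturated pixels


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainModel:
    """Three unit OD vectors over (R, G, B) plus per-channel background I0."""

    hematoxylin: tuple = (0.650, 0.704, 0.286)
    dab: tuple = (0.268, 0.570, 0.776)
    residual: tuple | None = None
    background: tuple = (255.0, 255.0, 255.0)

    @property
    def matrix(self) -> np.ndarray:
        """Rows: hematoxylin, DAB, residual; each a unit vector."""
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        if self.residual is not None:
            r = _unit(self.residual)
        else:
            cross = np.cross(h, d)
            if np.linalg.norm(cross) < 1e-8:
                raise ConfigurationError("stain vectors are collinear")
            r = _unit(cross)
        m = np.stack([h, d, r])
        if not np.all(np.isfinite(m)) or np.linalg.cond(m) > 1e8:
            raise ConfigurationError("stain matrix is singular or ill-conditioned")
        return m

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


DEFAULT_HDAB = StainModel()


def color_deconvolve(image: np.ndarray, model: StainModel = DEFAULT_HDAB) -> np.ndarray:
    """Unmix an RGB image into per-stain OD concentration channels.

    Returns an (H, W, 3) float array ordered (hematoxylin, DAB, residual);
    negative unmixed concentrations are clamped to 0.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    i0 = np.asarray(model.background, dtype=float)
    od = -np.log10((image + _EPS) / (i0 + _EPS))
    conc = od @ model.inverse
    return np.maximum(conc, 0.0)


def reconstruct_rgb(
    concentrations: np.ndarray, model: StainModel = DEFAULT_HDAB, dtype=np.uint8
) -> np.ndarray:
    """Forward model: per-stain concentrations -> RGB intensities.

    Exact inverse of :func:`color_deconvolve` for nonnegative concentrations
    (up to quantization when cast to uint8).
    """
    conc = np.asarray(concentrations, dtype=float)
    od = conc @ model.matrix
    i0 = np.asarray(model.background, dtype=float)
    img = (i0 + _EPS) * np.power(10.0, -od) - _EPS
    if dtype is float:
        return img
    return np.clip(np.round(img), 0, 255).astype(dtype)
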