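"""Color deconvolution for H-DAB brightfield immunohistochemistry.

Brightfield IHC images record transmitted light. Converting each channel to
optical density (OD = log10 of incident over transmitted intensity) makes the
absorbances of co-localized stains add linearly, so a pixel's OD 3-vector is a
non-negative combination of the unit absorbance vectors of hematoxylin (blue,
nuclei), DAB (brown, antigen) and a residual direction. Inverting that 3x3
system per pixel ("color deconvolution") yields per-stain concentration maps;
the same matrix run forward composes synthetic images, which makes the whole
transform round-trip testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_HEMATOXYLIN_OD",
    "DEFAULT_DAB_OD",
    "DEFAULT_WHITE_POINT",
    "OD_EPS",
    "StainSeparationError",
    "StainVectors",
    "ODImage",
    "StainChannels",
    "rgb_to_od",
    "deconvolve",
    "compose",
]

#: Standard published H-DAB absorbance directions (renormalized on construction).
DEFAULT_HEMATOXYLIN_OD = (0.651, 0.701, 0.290)
DEFAULT_DAB_OD = (0.269, 0.568, 0.778)

#: White-point intensity of an 8-bit brightfield image.
DEFAULT_WHITE_POINT = 255.0

#: Floor applied to pixel intensities before the log, keeping OD finite.
OD_EPS = 1.0


class StainSeparationError(ValueError):
    """Malformed input or an unusable (singular) stain configuration."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise StainSeparationError("stain vector has zero norm")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Unit OD absorbance vectors for hematoxylin, DAB and the residual.

    The residual completes an invertible basis; by default it is the
    normalized cross product of the two stain vectors.
    """

    hematoxylin: tuple[float, float, float]
    dab: tuple[float, float, float]
    residual: tuple[float, float, float]

    @classmethod
    def hdab(
        cls,
        hematoxylin=DEFAULT_HEMATOXYLIN_OD,
        dab=DEFAULT_DAB_OD,
    ) -> "StainVectors":
        h = _unit(np.asarray(hematoxylin, dtype=float))
        d = _unit(np.asarray(dab, dtype=float))
        if np.any(h < 0) or np.any(d < 0):
            raise StainSeparationError("stain absorbances must be non-negative")
        r = np.cross(h, d)
        nr = float(np.linalg.norm(r))
        if nr < 1e-9:
            raise StainSeparationError("hematoxylin and DAB vectors are collinear")
        r = r / nr
        return cls(tuple(h.tolist()), tuple(d.tolist()), tuple(r.tolist()))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with stain vectors as rows (hematoxylin, DAB, residual)."""
        return np.array([self.hematoxylin, self.dab, self.residual], dtype=float)

    @property
    def inverse(self) -> np.ndarray:
        m = self.matrix
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e8:
            raise StainSeparationError("stain matrix is singular or ill-conditioned")
        return np.linalg.inv(m)


@dataclass
class ODImage:
    """Per-pixel optical density 3-vectors (base-10, dimensionless)."""

    od: np.ndarray  # (H, W, 3) float

    @property
    def height(self) -> int:
        return self.od.shape[0]

    @property
    def width(self) -> int:
        return self.od.shape[1]


@dataclass
class StainChannels:
    """Per-pixel scalar OD concentration of each stain after deconvolution.

    Values may be slightly negative from noise/quantization; ``clamped``
    records whether :meth:`clamp` has been applied.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray
    clamped: bool = False

    def clamp(self) -> "StainChannels":
        """Return a copy with negative concentrations set to 0."""
        return StainChannels(
            np.maximum(self.hematoxylin, 0.0),
            np.maximum(self.dab, 0.0),
            np.maximum(self.residual, 0.0),
            clamped=True,
        )


def rgb_to_od(image: np.ndarray, i0: float = DEFAULT_WHITE_POINT) -> ODImage:
    """Convert an 8-bit RGB raster to base-10 optical densities.

    OD = log10(i0 / max(pixel, eps)) per channel, eps = 1, so white pixels
    (255,255,255) map to OD (0,0,0) and OD is monotone decreasing in pixel
    value.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise StainSeparationError(
            f"expected an (H, W, 3) RGB raster, got shape {arr.shape}"
        )
    if i0 <= 0:
        raise StainSeparationError("white point i0 must be positive")
    vals = np.maximum(arr.astype(float), OD_EPS)
    od = np.log10(i0 / vals)
    return ODImage(od)


def deconvolve(od: ODImage, vectors: StainVectors) -> StainChannels:
    """Unmix an OD image into per-stain concentrations.

    Per pixel, concentrations solve ``od = c_h*H + c_d*D + c_r*R``; the
    operation is linear in the OD input and negative solutions are preserved
    (clamp explicitly at measurement time via :meth:`StainChannels.clamp`).
    """
    inv = vectors.inverse
    conc = np.asarray(od.od, dtype=float) @ inv
    return StainChannels(conc[..., 0], conc[..., 1], conc[..., 2])


def compose(
    hema: np.ndarray,
    dab: np.ndarray,
    vectors: StainVectors | None = None,
    i0: float = DEFAULT_WHITE_POINT,
) -> np.ndarray:
    """Forward model: render an 8-bit RGB raster from stain concentration fields.

    pixel_c = round(i0 * 10**-(hema*H_c + dab*D_c)) clamped to [0, 255];
    zero concentration everywhere yields a white image.
    """
    if vectors is None:
        vectors = StainVectors.hdab()
    hema = np.asarray(hema, dtype=float)
    dab = np.asarray(dab, dtype=float)
    if np.any(hema < 0) or np.any(dab < 0):
        raise StainSeparationError("stain concentrations must be non-negative")
    h = np.asarray(vectors.hematoxylin)
    d = np.asarray(vectors.dab)
    od = hema[..., None] * h + dab[..., None] * d
    trans = i0 * np.power(10.0, -od)
    return np.clip(np.rint(trans), 0, 255).astype(np.uint8)
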