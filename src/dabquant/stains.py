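"""DAB / hematoxylin stain separation in optical-density space.

Brightfield immunohistochemistry obeys the Beer-Lambert law: the transmitted
intensity in channel ``c`` is ``I_c = I0_c * 10**(-OD_c)`` where the optical
density ``OD_c`` is a linear mixture of the per-stain absorption directions.
Detecting the brown DAB chromogen therefore amounts to (1) converting RGB to
optical density against a background reference, (2) inverting the 3x3 stain
matrix per pixel (color deconvolution) to obtain per-stain concentrations,
(3) thresholding the DAB concentration, and (4) mapping it to an inverted
8-bit expression map in which 255 means strongest DEFA6/DAB signal.

The stain matrix defaults to the widely used hematoxylin/DAB absorption
vectors of Ruifrok-style color deconvolution; the residual (third) vector is
the per-channel complement, as in the classic ImageJ implementation, which
keeps all entries non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateStainBasisError, InvalidReferenceError

__all__ = [
    "RGBImage",
    "ODImage",
    "StainMatrix",
    "StainConcentrations",
    "DABIntensityMap",
    "ThresholdWindow",
    "default_hdab_stain_matrix",
    "rgb_to_od",
    "deconvolve",
    "detect_dab",
    "to_inverted_8bit",
    "apply_threshold_window",
]

#: grey-level guard against log(0) on saturated black pixels
EPSILON_GREY = 1.0

# Hematoxylin and DAB absorption directions (R, G, B), unit-normalized below.
_HEMATOXYLIN_RGB = (0.650, 0.704, 0.286)
_DAB_RGB = (0.268, 0.570, 0.776)


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit, 3-channel brightfield image with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
    pixel_size_um : float
        Physical edge length of one pixel in micrometres; must be > 0.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError(f"pixel size must be finite and > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ODImage:
    """Per-pixel, per-channel optical density with its background reference."""

    od: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=np.float64)
        bg = np.asarray(self.background, dtype=np.float64)
        if od.ndim != 3 or od.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) OD array, got shape {od.shape}")
        if od.min() < 0:
            raise ValueError("optical density must be non-negative")
        object.__setattr__(self, "od", od)
        object.__setattr__(self, "background", bg)


@dataclass(frozen=True)
class StainMatrix:
    """A 3x3 basis of stain absorption directions (rows: hematoxylin, DAB, residual).

    Each row is a unit vector of per-channel (R, G, B) optical densities.  The
    matrix must be comfortably invertible; deconvolution applies its inverse
    to every pixel's OD vector.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "dab", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("stain vectors must have non-negative components")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"stain vectors must have unit norm, got norms {norms}")
        if np.linalg.cond(m) >= 1e6:
            raise DegenerateStainBasisError(
                f"stain matrix is ill-conditioned (cond={np.linalg.cond(m):.3g})"
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_vectors(cls, hematoxylin, dab, residual=None) -> "StainMatrix":
        """Build a matrix from raw (unnormalized) stain vectors.

        If *residual* is omitted it is completed per channel as
        ``sqrt(max(0, 1 - h_c**2 - d_c**2))``, the convention of the classic
        ImageJ color-deconvolution plugin, which is always non-negative.
        """
        h = np.asarray(hematoxylin, dtype=np.float64)
        d = np.asarray(dab, dtype=np.float64)
        h = h / np.linalg.norm(h)
        d = d / np.linalg.norm(d)
        if residual is None:
            r = np.sqrt(np.clip(1.0 - h**2 - d**2, 0.0, None))
        else:
            r = np.asarray(residual, dtype=np.float64)
        r = r / np.linalg.norm(r)
        return cls(np.vstack([h, d, r]))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


@dataclass(frozen=True)
class StainConcentrations:
    """Per-pixel stain concentrations (OD units along each stain direction)."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray


@dataclass(frozen=True)
class DABIntensityMap:
    """Inverted 8-bit DAB/DEFA6 expression map: 255 = strongest expression.

    ``values`` is 0 everywhere outside ``mask``; ``mask`` marks DAB-positive
    pixels that survived detection (and, downstream, the threshold window).
    """

    values: np.ndarray
    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        m = np.asarray(self.mask, dtype=bool)
        if v.shape != m.shape:
            raise ValueError("values and mask must share a shape")
        if v.dtype != np.uint8:
            if v.min() < 0 or v.max() > 255:
                raise ValueError("map values must lie in [0, 255]")
            v = v.astype(np.uint8)
        if np.any(v[~m] != 0):
            raise ValueError("map must be 0 outside its mask")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be > 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class ThresholdWindow:
    """Inclusive pass-band on the inverted 8-bit map.

    Pixels whose value falls strictly below ``low`` or strictly above
    ``high`` are treated as unspecific signal and removed.  One window is
    shared by every image of an analysis run.
    """

    low: int = 5
    high: int = 250

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high <= 255):
            raise ValueError(f"require 0 <= low < high <= 255, got ({self.low}, {self.high})")


def default_hdab_stain_matrix() -> StainMatrix:
    """The conventional hematoxylin / DAB / residual absorption basis.

    Deterministic; rows are unit-normalized.  The residual vector is the
    per-channel complement of the two dyes (see :meth:`StainMatrix.from_vectors`).
    """
    return StainMatrix.from_vectors(_HEMATOXYLIN_RGB, _DAB_RGB)


def rgb_to_od(image, background=(255.0, 255.0, 255.0)) -> ODImage:
    """Convert an 8-bit RGB image to per-channel optical density.

    ``OD_c = -log10(max(I_c, eps) / I0_c)`` with ``eps = 1`` grey level, so a
    saturated black pixel carries the maximal finite OD ``log10(I0_c)``.
    Values are clamped at zero (a pixel brighter than the reference has OD 0).

    Parameters
    ----------
    image : RGBImage or ndarray
    background : per-channel incident-light reference, each in (0, 255].
    """
    bg = np.asarray(background, dtype=np.float64).reshape(3)
    if np.any(bg <= 0) or np.any(bg > 255):
        raise InvalidReferenceError(f"background reference must lie in (0, 255], got {bg}")
    px = image.pixels if isinstance(image, RGBImage) else np.asarray(image)
    i = np.maximum(px.astype(np.float64), EPSILON_GREY)
    od = -np.log10(i / bg)
    np.clip(od, 0.0, None, out=od)
    return ODImage(od=od, background=bg)


def deconvolve(od, stains: StainMatrix) -> StainConcentrations:
    """Separate an OD image into per-stain concentration maps.

    Applies the inverse stain matrix to every pixel's OD vector and clips
    negative concentrations (noise pushing a pixel outside the stain cone)
    to zero after solving.
    """
    arr = od.od if isinstance(od, ODImage) else np.asarray(od, dtype=np.float64)
    flat = arr.reshape(-1, 3) @ stains.inverse
    conc = np.clip(flat, 0.0, None).reshape(arr.shape)
    return StainConcentrations(
        hematoxylin=conc[..., 0], dab=conc[..., 1], residual=conc[..., 2]
    )


def detect_dab(dab_concentration: np.ndarray, od_threshold: float = 0.15) -> np.ndarray:
    """Binary DAB-positive mask: concentration strictly above *od_threshold*."""
    if od_threshold < 0:
        raise ValueError(f"od_threshold must be >= 0, got {od_threshold}")
    return np.asarray(dab_concentration) > od_threshold


def to_inverted_8bit(
    dab_concentration: np.ndarray,
    mask: np.ndarray,
    scale_od: float = 1.0,
    pixel_size_um: float = 1.0,
) -> DABIntensityMap:
    """Map DAB concentration to the inverted 8-bit expression scale.

    Inside the mask, ``value = round(255 * min(c / scale_od, 1))`` with
    round-half-to-even; outside, 0.  This composes the workflow's
    convert-to-8-bit and invert steps in one go, so that the highest pixel
    value corresponds to the highest DEFA6 expression.
    """
    if not scale_od > 0:
        raise ValueError(f"scale_od must be > 0, got {scale_od}")
    c = np.asarray(dab_concentration, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    scaled = np.clip(c / scale_od, 0.0, 1.0)
    values = np.rint(255.0 * scaled).astype(np.uint8)
    values[~m] = 0
    return DABIntensityMap(values=values, mask=m, pixel_size_um=pixel_size_um)


def apply_threshold_window(imap: DABIntensityMap, window: ThresholdWindow) -> DABIntensityMap:
    """Filter unspecific too-high and/or too-low pixel values.

    Pixels with value < low or > high are zeroed and removed from the mask;
    all others pass unchanged.  Idempotent for a fixed window.
    """
    v = imap.values
    kill = (v < window.low) | (v > window.high)
    new_mask = imap.mask & ~kill
    new_values = np.where(new_mask, v, 0).astype(np.uint8)
    return DABIntensityMap(values=new_values, mask=new_mask, pixel_size_um=imap.pixel_size_um)
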