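"""Mucosal ROI morphometry and the per-micrometre expression statistic.

Mucosal height varies strongly between subjects, so a raw sum of DAB signal
over the region of interest is not comparable across sections.  The measure
implemented here divides the summed, inverted 8-bit DAB intensity by an
effective mucosa *length*:

    length_um        = roi_area_um2 / mean_mucosal_height_um
    expression_per_um = total_dab_intensity / length_um

where the mean height is the arithmetic mean of (conventionally ten)
representative height measurements of the section.  A second, staining-
intensity-robust statistic is the percentage of ROI pixels that are
DAB-positive.

Coordinate convention: polygon vertices are (x right, y down) with the
origin at the centre of the top-left pixel, so pixel (row i, col j) has its
centre at (x=j, y=i).  A pixel belongs to the ROI iff its centre lies inside
the polygon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .errors import (
    InvalidNormalizerError,
    InvalidROIError,
    MissingMeasurementError,
)
from .stains import (
    DABIntensityMap,
    RGBImage,
    apply_threshold_window,
    deconvolve,
    detect_dab,
    rgb_to_od,
    to_inverted_8bit,
)

__all__ = [
    "ROIPolygon",
    "MucosaHeights",
    "ExpressionResult",
    "rasterize_roi",
    "mean_mucosal_height",
    "mucosa_length",
    "expression_per_um",
    "percent_dab_area",
    "quantify_sample",
]

#: number of height sites the measurement convention expects
CONVENTIONAL_N_HEIGHT_SITES = 10


@dataclass(frozen=True)
class ROIPolygon:
    """A closed, simple polygon delimiting the mucosa, in pixel coordinates."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidROIError(
                f"polygon needs >= 3 (x, y) vertices, got array of shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)

    def to_shapely(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise InvalidROIError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise InvalidROIError("polygon encloses zero area")
        return poly


@dataclass(frozen=True)
class MucosaHeights:
    """Representative mucosal height measurements (um) and their mean."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=np.float64))
        if v.size == 0:
            raise MissingMeasurementError("no mucosal height measurements supplied")
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("every mucosal height must be finite and > 0")
        object.__setattr__(self, "values", v)

    @property
    def mean_um(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class ExpressionResult:
    """All per-sample quantities of the expression analysis, for auditability.

    ``length_um * mean_height_um == roi_area_um2`` holds by construction.
    ``total_intensity`` is the sum of inverted 8-bit values over ROI ∩ mask
    after the threshold window (sub-threshold pixels contribute 0).
    """

    roi_area_px: int
    roi_area_um2: float
    mean_height_um: float
    length_um: float
    total_intensity: float
    expr_per_um: float
    pct_area: float
    n_dab_px: int
    pixel_size_um: float

    def as_dict(self) -> dict:
        return {
            "roi_area_px": self.roi_area_px,
            "roi_area_um2": self.roi_area_um2,
            "mean_height_um": self.mean_height_um,
            "length_um": self.length_um,
            "total_intensity": self.total_intensity,
            "expr_per_um": self.expr_per_um,
            "pct_area": self.pct_area,
            "n_dab_px": self.n_dab_px,
            "pixel_size_um": self.pixel_size_um,
        }


def rasterize_roi(polygon: ROIPolygon, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a ROI polygon onto the pixel grid.

    A pixel is inside iff its centre (integer coordinates) lies strictly
    inside the polygon.  A polygon reaching beyond the image is clipped to
    the image extent with a warning; a polygon fully outside yields an empty
    mask (also with a warning).
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    poly = polygon.to_shapely()
    image_rect = box(-0.5, -0.5, w - 0.5, h - 0.5)
    if not image_rect.contains(poly):
        warnings.warn(
            "ROI polygon extends beyond the image bounds; clipping to the image",
            stacklevel=2,
        )
        poly = poly.intersection(image_rect)
        if poly.is_empty or poly.area == 0:
            return np.zeros((h, w), dtype=bool)
    xs, ys = np.meshgrid(np.arange(w, dtype=np.float64), np.arange(h, dtype=np.float64))
    mask = shapely.contains_xy(poly, xs.ravel(), ys.ravel())
    return mask.reshape(h, w)


def mean_mucosal_height(heights: MucosaHeights) -> float:
    """Arithmetic mean of the height measurements, in micrometres.

    Warns when the number of sites differs from the conventional ten.
    """
    if heights.values.size != CONVENTIONAL_N_HEIGHT_SITES:
        warnings.warn(
            f"expected {CONVENTIONAL_N_HEIGHT_SITES} height sites by convention, "
            f"got {heights.values.size}",
            stacklevel=2,
        )
    return heights.mean_um


def mucosa_length(roi_area_px: float, pixel_size_um: float, mean_height_um: float) -> float:
    """Effective mucosa length: ROI area (um^2) divided by mean height (um)."""
    if roi_area_px <= 0 or pixel_size_um <= 0:
        raise InvalidROIError("ROI area and pixel size must be > 0")
    if mean_height_um <= 0:
        raise InvalidNormalizerError(f"mean mucosal height must be > 0, got {mean_height_um}")
    return float(roi_area_px) * pixel_size_um**2 / mean_height_um


def expression_per_um(total_intensity: float, length_um: float) -> float:
    """Total inverted DAB intensity per micrometre of mucosa length (a.u./um)."""
    if total_intensity < 0:
        raise ValueError("total intensity must be >= 0")
    if length_um <= 0:
        raise InvalidNormalizerError(f"mucosa length must be > 0, got {length_um}")
    return float(total_intensity) / float(length_um)


def percent_dab_area(dab_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """Percentage of ROI pixels that are DAB-positive."""
    dab = np.asarray(dab_mask, dtype=bool)
    roi = np.asarray(roi_mask, dtype=bool)
    if dab.shape != roi.shape:
        raise InvalidROIError(f"mask shapes differ: {dab.shape} vs {roi.shape}")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise InvalidROIError("ROI mask is empty")
    return 100.0 * int((dab & roi).sum()) / n_roi


def quantify_sample(image: RGBImage, roi: ROIPolygon, heights: MucosaHeights, config) -> ExpressionResult:
    """Run the full per-sample workflow: stain separation, then morphometry.

    The chain is: RGB -> OD -> color deconvolution -> DAB detection ->
    inverted 8-bit map -> shared threshold window -> summation over
    ROI ∩ mask -> per-um and percent-area statistics.

    Parameters
    ----------
    config : RunConfig
        Carries the stain matrix, detection threshold, OD-to-8-bit scale,
        the run-wide threshold window and the background reference.
    """
    od = rgb_to_od(image, background=config.background)
    conc = deconvolve(od, config.resolved_stain_matrix())
    raw_mask = detect_dab(conc.dab, od_threshold=config.dab_od_threshold)
    imap = to_inverted_8bit(
        conc.dab, raw_mask, scale_od=config.scale_od, pixel_size_um=image.pixel_size_um
    )
    imap = apply_threshold_window(imap, config.threshold_window())

    roi_mask = rasterize_roi(roi, image.shape)
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise InvalidROIError("rasterized ROI contains no pixels")

    mean_h = mean_mucosal_height(heights)
    area_um2 = n_roi * image.pixel_size_um**2
    length = mucosa_length(n_roi, image.pixel_size_um, mean_h)
    positive = imap.mask & roi_mask
    total = float(imap.values[positive].sum(dtype=np.int64))
    return ExpressionResult(
        roi_area_px=n_roi,
        roi_area_um2=area_um2,
        mean_height_um=mean_h,
        length_um=length,
        total_intensity=total,
        expr_per_um=expression_per_um(total, length),
        pct_area=percent_dab_area(imap.mask, roi_mask),
        n_dab_px=int(positive.sum()),
        pixel_size_um=image.pixel_size_um,
    )
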