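"""Spheroid silhouette segmentation and the invasion "complexity" metric.

Complexity is the reciprocal of the isoperimetric quotient,

    complexity = perimeter**2 / (4 * pi * area),

equal to 1 for a circle and strictly larger for any other shape. Spheroids
that send out more and longer invasive strands accumulate perimeter at
roughly constant area, so more invasive spheroids score higher. The value
is dimensionless and invariant to uniform rescaling of the silhouette.

The perimeter and area are measured on a sub-pixel contour extracted by
marching squares at iso-level 0.5, not by counting pixel edges: pixel-edge
perimeters systematically overestimate smooth boundaries (by up to 4/pi for
a disk) and would bias complexity upward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from . import _geom
from .errors import SegmentationError, ValidationError
from .io import PlanarImage

log = logging.getLogger(__name__)


@dataclass
class SpheroidShape:
    """A segmented spheroid silhouette and its shape measurements.

    ``contour`` is the closed outline as an (n, 2) array of (x, y) µm
    coordinates; for synthetic silhouettes it is the exact generating
    polygon, for segmented masks the marching-squares iso-contour.
    """

    mask: np.ndarray
    contour: np.ndarray
    perimeter_um: float
    area_um2: float
    pixel_size_um: float = 1.0

    @property
    def complexity(self) -> float:
        return complexity(self.perimeter_um, self.area_um2)


def complexity(perimeter_um: float, area_um2: float) -> float:
    """Reciprocal isoperimetric quotient: perimeter² / (4π · area)."""
    if not (perimeter_um > 0 and area_um2 > 0):
        raise ValidationError(
            f"perimeter and area must be positive; got P={perimeter_um}, A={area_um2}"
        )
    return perimeter_um**2 / (4.0 * math.pi * area_um2)


def segment_spheroid(
    image: PlanarImage,
    min_area_um2: float = 0.0,
    smooth_sigma_px: float = 1.0,
) -> np.ndarray:
    """Segment the dominant bright object of a calcein-stained spheroid image.

    Pipeline: Gaussian smoothing, Otsu threshold, keep the largest connected
    component, fill holes, and discard it if smaller than ``min_area_um2``.
    Returns a boolean mask.
    """
    pixels = image.pixels.astype(float)
    smoothed = ndimage.gaussian_filter(pixels, smooth_sigma_px)
    if np.ptp(smoothed) == 0:
        raise SegmentationError("image is constant; nothing to segment")
    thresh = filters.threshold_otsu(smoothed)
    fg = smoothed > thresh
    if not fg.any():
        raise SegmentationError("no foreground after Otsu thresholding")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(labels == keep)
    area = mask.sum() * image.pixel_size_um**2
    if area < min_area_um2:
        raise SegmentationError(
            f"largest object ({area:.1f} µm²) is below min_area_um2={min_area_um2}"
        )
    return mask


def measure_shape(
    mask: np.ndarray, pixel_size_um: float = 1.0
) -> tuple[float, float, np.ndarray]:
    """Perimeter (µm), area (µm²) and the sub-pixel contour of a binary mask.

    The binary mask is lightly Gaussian-smoothed (sigma 1 px) and the
    contour extracted by marching squares at iso-level 0.5, giving a
    sub-pixel outline free of staircase artefacts (a hard-binary iso-contour
    overestimates a disk's perimeter by ~5%, the smoothed one by < 1%);
    perimeter is the contour polyline length and area its shoelace area,
    both in physical units. Objects too thin to survive smoothing (e.g. a
    single-pixel mask) fall back to the unsmoothed iso-contour; a lone pixel
    yields the marching-squares diamond through its four neighbour midpoints
    (area = half a pixel), the documented degenerate convention. A mask
    touching the image border is measured after padding, with a warning that
    the visible perimeter underestimates the object's.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    border = (
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    if border:
        log.warning("mask touches the image border; perimeter is an underestimate")
    pad = 4
    padded = np.pad(mask.astype(float), pad)
    smoothed = ndimage.gaussian_filter(padded, 1.0)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:  # object thinner than the smoothing kernel
        pad = 1
        padded = np.pad(mask.astype(float), pad)
        contours = measure.find_contours(padded, 0.5)
    # the object of interest is the longest contour (outer boundary)
    contour_rc = max(contours, key=lambda c: _geom.polyline_length(c))
    # (row, col) on padded grid -> (x, y) µm; pixel centres at half-integers
    xy = np.column_stack([contour_rc[:, 1] - pad + 0.5, contour_rc[:, 0] - pad + 0.5])
    xy *= pixel_size_um
    perimeter = _geom.polyline_length(xy)
    area = _geom.shoelace_area(xy)
    return perimeter, area, xy


def analyze_spheroid(
    image: PlanarImage, min_area_um2: float = 0.0
) -> SpheroidShape:
    """Segment one spheroid image and measure perimeter, area and complexity."""
    mask = segment_spheroid(image, min_area_um2=min_area_um2)
    perimeter, area, contour = measure_shape(mask, image.pixel_size_um)
    return SpheroidShape(
        mask=mask,
        contour=contour,
        perimeter_um=perimeter,
        area_um2=area,
        pixel_size_um=image.pixel_size_um,
    )


def shape_from_mask(mask: np.ndarray, pixel_size_um: float = 1.0) -> SpheroidShape:
    """Measure an already-segmented binary mask."""
    perimeter, area, contour = measure_shape(mask, pixel_size_um)
    return SpheroidShape(
        mask=np.asarray(mask, dtype=bool),
        contour=contour,
        perimeter_um=perimeter,
        area_um2=area,
        pixel_size_um=pixel_size_um,
    )
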