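"""Perimeter intensity profiles and the Peripheral Distribution Index.

Perimeter profiling quantifies extracellular-matrix staining (laminin,
fibronectin) along the front-cytoplasm contour of a leader cell, as signed
arc length from the protrusion tip (tip = 0, the two sides negative and
positive by traversal direction). Profiles from many cells are interpolated
onto a common grid and summarized as a mean with a t-based 95% confidence
band.

The Peripheral Distribution Index (PDI) scores how peripherally an RNA
signal sits in a single cell: it is the intensity-weighted mean squared
distance of the signal from the nucleus centroid, divided by the same
second moment of a uniform distribution over the cytoplasm (cell mask
minus nucleus mask). A perfectly diffuse signal scores 1; peripheral
enrichment scores above 1, perinuclear concentration below 1. The index is
invariant to uniform intensity scaling and to rigid motions of the whole
geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import LineString, Point

from . import _geom
from .errors import ValidationError
from .io import PlanarImage
from .spots import SpotSet

log = logging.getLogger(__name__)


@dataclass
class PerimeterProfile:
    """Band intensity along one cell's front contour vs signed arc length."""

    arclength_um: np.ndarray
    intensity: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.arclength_um = np.asarray(self.arclength_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.arclength_um) <= 0):
            raise ValidationError("arclength must be strictly increasing")
        if not (self.arclength_um[0] <= 0.0 <= self.arclength_um[-1]):
            raise ValidationError("the tip (arc length 0) must lie within the range")


@dataclass
class ProfileAggregate:
    grid_um: np.ndarray
    mean_intensity: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_cells: np.ndarray


@dataclass
class PDIResult:
    pdi: float
    n_signal_pixels: int
    cell_id: str = ""


def front_perimeter_contour(annotation, tol_um: float = 0.5) -> np.ndarray:
    """Open contour of the front cytoplasm, running side-tip-side.

    Takes the boundary of the annotation's front region and removes the
    stretch that follows the nuclear edge (within ``tol_um``), leaving the
    open perimeter that passes the protrusion tip — the path laminin and
    fibronectin intensity is profiled along. Requires ``front_region``.
    """
    from .io import EdgeAnnotation  # local import to avoid a cycle

    if not isinstance(annotation, EdgeAnnotation) or annotation.front_region is None:
        raise ValidationError("annotation with a front_region polygon is required")
    ring = _geom.as_points(annotation.front_region)
    # drop a duplicated closing vertex
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    nuclear = LineString(annotation.nuclear_edge)
    on_nuclear = np.array([nuclear.distance(Point(p)) <= tol_um for p in ring])
    if not on_nuclear.any():
        raise ValidationError("front_region boundary never meets the nuclear edge")
    if on_nuclear.all():
        raise ValidationError("front_region boundary is entirely on the nuclear edge")
    # rotate the ring so the non-nuclear run starts at index 0, then keep
    # that run plus the junction vertex on the nuclear edge at either end
    # (the corners where the lateral sides meet the nucleus)
    start = int(np.argmax(~on_nuclear & np.roll(on_nuclear, 1)))
    rolled = np.roll(ring, -(start - 1), axis=0)
    keep = ~np.roll(on_nuclear, -(start - 1))
    run_end = int(np.argmin(keep[1:])) + 1 if not keep[1:].all() else len(rolled)
    return rolled[: min(run_end + 1, len(rolled))]


def perimeter_intensity_profile(
    image: PlanarImage,
    front_contour: np.ndarray,
    tip: np.ndarray,
    band_um: float = 1.0,
    step_um: float = 0.5,
    cell_id: str = "",
) -> PerimeterProfile:
    """Mean band intensity along a contour, signed arc length from the tip.

    The contour is resampled at ``step_um``; at each sample the intensity is
    the mean over image pixels whose centres lie within a disk of radius
    ``band_um`` around the contour point. The tip must lie on the contour
    or within 1 µm of it (it is snapped to its nearest contour position).
    """
    contour = _geom.as_points(front_contour)
    tip = np.asarray(tip, dtype=float).reshape(2)
    line = LineString(contour)
    if line.distance(Point(tip)) > 1.0:
        raise ValidationError("tip is farther than 1 µm from the contour")
    s_tip = float(line.project(Point(tip)))
    samples, s = _geom.resample_polyline(contour, step_um)

    px = image.pixel_size_um
    h, w = image.pixels.shape
    half = int(math.ceil(band_um / px)) + 1
    intensity = np.empty(len(samples))
    for i, (x, y) in enumerate(samples):
        c0 = int(round(x / px - 0.5))
        r0 = int(round(y / px - 0.5))
        rows = np.arange(max(r0 - half, 0), min(r0 + half + 1, h))
        cols = np.arange(max(c0 - half, 0), min(c0 + half + 1, w))
        if not len(rows) or not len(cols):
            intensity[i] = np.nan
            continue
        cx = (cols + 0.5) * px
        cy = (rows + 0.5) * px
        dist2 = (cx[None, :] - x) ** 2 + (cy[:, None] - y) ** 2
        inside = dist2 <= band_um**2
        vals = image.pixels[np.ix_(rows, cols)][inside]
        intensity[i] = vals.mean() if len(vals) else np.nan
    keep = ~np.isnan(intensity)
    return PerimeterProfile(
        arclength_um=(s - s_tip)[keep], intensity=intensity[keep], cell_id=cell_id
    )


def aggregate_profiles(
    profiles: list[PerimeterProfile],
    normalize: bool = True,
    step_um: float = 0.5,
    confidence: float = 0.95,
) -> ProfileAggregate:
    """Mean profile across cells with a t-based confidence band.

    Each profile is optionally normalized by its own mean intensity (making
    the aggregate invariant to per-cell exposure), linearly interpolated
    onto a common signed-arc-length grid, and averaged; the band is the
    per-grid-point t interval across contributing cells. Grid points with
    fewer than 3 contributing cells are dropped; profiles whose arc-length
    ranges share no such grid point are an error.
    """
    if len(profiles) < 3:
        raise ValidationError("need at least 3 profiles to aggregate")
    lo = min(p.arclength_um[0] for p in profiles)
    hi = max(p.arclength_um[-1] for p in profiles)
    grid = np.arange(math.floor(lo / step_um), math.ceil(hi / step_um) + 1) * step_um
    stack = np.full((len(profiles), len(grid)), np.nan)
    for i, p in enumerate(profiles):
        vals = p.intensity / p.intensity.mean() if normalize else p.intensity
        inside = (grid >= p.arclength_um[0]) & (grid <= p.arclength_um[-1])
        stack[i, inside] = np.interp(grid[inside], p.arclength_um, vals)
    n = np.sum(~np.isnan(stack), axis=0)
    keep = n >= 3
    if not keep.any():
        raise ValidationError("profiles do not overlap on any common arc-length range")
    grid, stack, n = grid[keep], stack[:, keep], n[keep]
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    halfwidth = tcrit * sd / np.sqrt(n)
    return ProfileAggregate(
        grid_um=grid,
        mean_intensity=mean,
        ci_low=mean - halfwidth,
        ci_high=mean + halfwidth,
        n_cells=n,
    )


def compute_pdi(
    signal: PlanarImage | SpotSet | np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size_um: float | None = None,
    cell_id: str = "",
) -> PDIResult:
    """Peripheral Distribution Index of a signal within one cell.

    PDI = (intensity-weighted mean squared distance of the signal from the
    nucleus centroid) / (the same moment for a uniform distribution over
    the cytoplasm). ``signal`` may be an intensity image (weights = pixel
    intensities inside the cytoplasm), a detected spot set, or a raw (n, 2)
    array of µm positions (unit weights at positions inside the cytoplasm).
    A value of 1 indicates a diffuse distribution; > 1 peripheral
    enrichment; < 1 perinuclear concentration.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if cell_mask.shape != nucleus_mask.shape:
        raise ValidationError("cell and nucleus masks differ in shape")
    if (nucleus_mask & ~cell_mask).any():
        raise ValidationError("nucleus mask extends outside the cell mask")
    if isinstance(signal, PlanarImage):
        px = signal.pixel_size_um
    else:
        if pixel_size_um is None:
            raise ValidationError("pixel_size_um required for point-based signal")
        px = pixel_size_um

    cytoplasm = cell_mask & ~nucleus_mask
    if not cytoplasm.any():
        raise ValidationError("cytoplasm (cell minus nucleus) is empty")

    xs, ys = _geom.pixel_centers_um(cell_mask.shape, px)
    nuc_centroid = np.array([xs[nucleus_mask].mean(), ys[nucleus_mask].mean()])
    r2 = (xs - nuc_centroid[0]) ** 2 + (ys - nuc_centroid[1]) ** 2
    uniform_moment = r2[cytoplasm].mean()

    if isinstance(signal, PlanarImage):
        if signal.pixels.shape != cell_mask.shape:
            raise ValidationError("signal image and masks differ in shape")
        weights = signal.pixels[cytoplasm]
        if weights.sum() <= 0:
            raise ValidationError("signal has no positive intensity in the cytoplasm")
        signal_moment = float(np.average(r2[cytoplasm], weights=weights))
        n_signal = int(np.count_nonzero(weights > 0))
    else:
        pts = signal.positions() if isinstance(signal, SpotSet) else np.asarray(signal, float)
        pts = pts.reshape(-1, 2)
        cols = np.clip((pts[:, 0] / px - 0.5).round().astype(int), 0, cell_mask.shape[1] - 1)
        rows = np.clip((pts[:, 1] / px - 0.5).round().astype(int), 0, cell_mask.shape[0] - 1)
        inside = cytoplasm[rows, cols]
        pts = pts[inside]
        if len(pts) == 0:
            raise ValidationError("no signal points inside the cytoplasm")
        d2 = np.sum((pts - nuc_centroid) ** 2, axis=1)
        signal_moment = float(d2.mean())
        n_signal = len(pts)
    return PDIResult(pdi=signal_moment / uniform_moment, n_signal_pixels=n_signal, cell_id=cell_id)
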