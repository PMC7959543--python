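"""Small polyline/polygon helpers used by several modules.

All coordinates are (x, y) in micrometres unless a name says otherwise.
Raster indexing is 0-based (row, col); the centre of pixel (r, c) sits at
physical position ((c + 0.5) * px, (r + 0.5) * px).
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Point


def as_points(coords) -> np.ndarray:
    """Coerce a coordinate list to a float (n, 2) array."""
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) coordinate array, got shape {pts.shape}")
    return pts


def polyline_is_simple(pts: np.ndarray) -> bool:
    """True when the open polyline does not self-intersect."""
    if len(pts) < 2:
        return False
    return LineString(pts).is_simple


def polyline_length(pts: np.ndarray) -> float:
    seg = np.diff(pts, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def cumulative_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


def resample_polyline(pts: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample an open polyline at a fixed arc-length step.

    Returns (samples, arclengths); the final vertex is always included.
    """
    s = cumulative_arclength(pts)
    total = s[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    n = max(int(np.floor(total / step)), 1)
    grid = np.linspace(0.0, total, n + 1)
    x = np.interp(grid, s, pts[:, 0])
    y = np.interp(grid, s, pts[:, 1])
    return np.column_stack([x, y]), grid


def point_to_polyline_distance(point, polyline_pts: np.ndarray) -> float:
    """Minimum Euclidean distance from a point to an open polyline."""
    return float(Point(point).distance(LineString(polyline_pts)))


def project_arclength(point, polyline_pts: np.ndarray) -> float:
    """Arc length along the polyline of the point's nearest contour position."""
    return float(LineString(polyline_pts).project(Point(point)))


def shoelace_area(pts: np.ndarray) -> float:
    """Absolute polygon area by the shoelace formula (closed implicitly)."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def pixel_centers_um(shape: tuple[int, int], pixel_size_um: float):
    """Physical (x, y) coordinates of every pixel centre, as two 2-D arrays."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (cols + 0.5) * pixel_size_um, (rows + 0.5) * pixel_size_um
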