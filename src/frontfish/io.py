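"""Image and annotation I/O, z-projection, and the shared domain containers.

Conventions
-----------
* All public coordinates are (x, y) in micrometres (µm), origin at the
  top-left pixel corner; pixel centres sit at half-integer multiples of the
  pixel size. Raster indexing is 0-based ``(row, col)``.
* Z-projection is always maximum-intensity: confocal stacks through the
  whole cell/spheroid volume are collapsed to one plane per channel before
  any quantification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import LineString, Point, Polygon

from . import _geom
from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MultiChannelStack:
    """A z-stack of co-registered fluorescence channels.

    ``voxels`` is indexed ``(z, channel, y, x)``; ``channel_names`` labels the
    channel axis; ``pixel_size_um`` is the physical edge length of one pixel.
    """

    voxels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValidationError(
                f"stack must be (z, channel, y, x); got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"{self.voxels.shape[1]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class PlanarImage:
    """A single 2-D intensity image with physical pixel size."""

    pixels: np.ndarray
    channel_name: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError(f"planar image must be 2-D; got {self.pixels.ndim}-D")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in µm."""
        h, w = self.pixels.shape
        return w * self.pixel_size_um, h * self.pixel_size_um


@dataclass
class EdgeAnnotation:
    """Manually drawn cell-front geometry, in µm.

    ``invasive_edge`` and ``nuclear_edge`` are open polylines: the membrane
    boundary facing the matrix (the d = 0 reference) and the nuclear boundary
    (d = 1). ``front_region`` optionally delimits the front cytoplasm as a
    closed polygon; ``tip`` optionally marks the protrusion tip used as the
    arc-length origin of perimeter profiles.
    """

    invasive_edge: np.ndarray
    nuclear_edge: np.ndarray
    front_region: np.ndarray | None = None
    tip: np.ndarray | None = None
    boundary_tol_um: float = field(default=1.0, repr=False)

    def __post_init__(self) -> None:
        self.invasive_edge = _geom.as_points(self.invasive_edge)
        self.nuclear_edge = _geom.as_points(self.nuclear_edge)
        for name in ("invasive_edge", "nuclear_edge"):
            pts = getattr(self, name)
            if len(pts) < 2:
                raise ValidationError(f"{name} needs at least 2 points")
            if not _geom.polyline_is_simple(pts):
                raise ValidationError(f"{name} is self-intersecting")
        if self.front_region is not None:
            self.front_region = _geom.as_points(self.front_region)
            poly = Polygon(self.front_region)
            if not poly.is_valid or poly.area <= 0:
                raise ValidationError("front_region is not a valid simple polygon")
            ring = poly.exterior
            for name in ("invasive_edge", "nuclear_edge"):
                dmax = max(ring.distance(Point(p)) for p in getattr(self, name))
                if dmax > self.boundary_tol_um:
                    raise ValidationError(
                        f"{name} lies {dmax:.3g} µm off the front_region boundary "
                        f"(tolerance {self.boundary_tol_um} µm)"
                    )
        if self.tip is not None:
            self.tip = np.asarray(self.tip, dtype=float).reshape(2)

    def swapped(self) -> "EdgeAnnotation":
        """The same annotation with invasive and nuclear edges exchanged."""
        return EdgeAnnotation(
            invasive_edge=self.nuclear_edge.copy(),
            nuclear_edge=self.invasive_edge.copy(),
            front_region=None if self.front_region is None else self.front_region.copy(),
            tip=None if self.tip is None else self.tip.copy(),
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def load_stack(
    path, channel_map: dict[str, int], pixel_size_um: float = 1.0
) -> MultiChannelStack:
    """Read a TIFF into a labelled ``MultiChannelStack``.

    ``channel_map`` maps a channel label to its index on the channel axis.
    Page-axis interpretation: a 2-D image becomes a single-slice,
    single-channel stack; a 3-D array is treated as ``(channel, y, x)`` when
    the map names more than one channel and ``(z, y, x)`` otherwise; a 4-D
    array is taken as ``(z, channel, y, x)``.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF image at {path}") from exc

    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        if len(channel_map) > 1:
            arr = arr[None, :]  # (channel, y, x) -> single z
        else:
            arr = arr[:, None]  # (z, y, x) -> single channel
    elif arr.ndim != 4:
        raise ValidationError(f"unsupported TIFF dimensionality {arr.ndim}")

    n_channels = arr.shape[1]
    for label, idx in channel_map.items():
        if not 0 <= idx < n_channels:
            raise ConfigurationError(
                f"channel {label!r} maps to index {idx} but the file has "
                f"{n_channels} channel(s)"
            )
    order = sorted(channel_map.items(), key=lambda kv: kv[1])
    names = [label for label, _ in order]
    voxels = arr[:, [idx for _, idx in order]]
    return MultiChannelStack(voxels=voxels, channel_names=names, pixel_size_um=pixel_size_um)


def max_project(stack: MultiChannelStack) -> dict[str, PlanarImage]:
    """Maximum-intensity projection over z, one planar image per channel."""
    if stack.n_slices < 1:
        raise ValidationError("stack has no z-slices")
    out: dict[str, PlanarImage] = {}
    for c, name in enumerate(stack.channel_names):
        out[name] = PlanarImage(
            pixels=stack.voxels[:, c].max(axis=0),
            channel_name=name,
            pixel_size_um=stack.pixel_size_um,
        )
    return out


_REQUIRED_EDGES = ("invasive_edge", "nuclear_edge")


def read_edge_annotation(path) -> EdgeAnnotation:
    """Read an edge-annotation JSON file (see format notes below).

    The file holds named coordinate lists with an explicit ``units`` field::

        {"units": "px" | "um", "pixel_size_um": 0.2,
         "invasive_edge": [[x, y], ...], "nuclear_edge": [[x, y], ...],
         "front_region": [[x, y], ...],  # optional closed polygon
         "tip": [x, y]}                  # optional

    Pixel-unit coordinates are converted to µm on read; the returned
    annotation is always in µm.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except OSError as exc:
        raise OSError(f"cannot read annotation file at {path}") from exc
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path} is not valid JSON: {exc}") from exc

    units = payload.get("units", "um")
    if units not in ("px", "um"):
        raise ValidationError(f"units must be 'px' or 'um', got {units!r}")
    scale = 1.0
    if units == "px":
        if "pixel_size_um" not in payload:
            raise ValidationError("pixel-unit annotations require pixel_size_um")
        scale = float(payload["pixel_size_um"])
        if not scale > 0:
            raise ValidationError("pixel_size_um must be positive")

    for key in _REQUIRED_EDGES:
        if key not in payload:
            raise ValidationError(f"annotation is missing required field {key!r}")

    def _pts(key):
        if key not in payload or payload[key] is None:
            return None
        return _geom.as_points(payload[key]) * scale

    tip = payload.get("tip")
    return EdgeAnnotation(
        invasive_edge=_pts("invasive_edge"),
        nuclear_edge=_pts("nuclear_edge"),
        front_region=_pts("front_region"),
        tip=None if tip is None else np.asarray(tip, dtype=float) * scale,
    )


def write_edge_annotation(annotation: EdgeAnnotation, path) -> None:
    """Write an annotation as µm-unit JSON (the read_edge_annotation dialect)."""
    payload: dict = {
        "units": "um",
        "invasive_edge": annotation.invasive_edge.tolist(),
        "nuclear_edge": annotation.nuclear_edge.tolist(),
    }
    if annotation.front_region is not None:
        payload["front_region"] = annotation.front_region.tolist()
    if annotation.tip is not None:
        payload["tip"] = annotation.tip.tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def write_planar_image(image: PlanarImage, path) -> None:
    """Write a planar image as a single-page float32 TIFF."""
    tifffile.imwrite(Path(path), image.pixels.astype(np.float32))
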