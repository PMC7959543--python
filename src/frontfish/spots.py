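"""Single-molecule FISH spot detection with sub-pixel localization.

The detector is a single-scale Laplacian-of-Gaussian (LoG) filter — the
standard choice for diffraction-limited smFISH spots — followed by local-
maximum extraction, thresholding, non-maximum suppression at a minimum
separation, and quadratic sub-pixel refinement. The threshold may be given
absolutely or, by default, in units of the robust (MAD-based) standard
deviation of the filter response, which makes detection invariant to
multiplying the image by any positive constant and to adding any offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import PlanarImage

log = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor for Gaussian data


@dataclass
class SpotDetectionParams:
    """Detector settings.

    ``scale_um`` should approximate the spot radius (the LoG sigma).
    ``threshold_k`` is in robust background sds of the LoG response unless
    ``threshold_abs`` is given. ``min_separation_um`` defaults to twice the
    scale.
    """

    scale_um: float = 0.25
    threshold_k: float = 5.0
    threshold_abs: float | None = None
    min_separation_um: float | None = None

    def min_sep(self) -> float:
        return (
            2.0 * self.scale_um
            if self.min_separation_um is None
            else self.min_separation_um
        )


@dataclass
class Spot:
    """One detected RNA molecule: sub-pixel position in µm and its response."""

    position: np.ndarray
    peak_intensity: float
    species: str = ""
    quality: float = 0.0


@dataclass
class SpotSet:
    spots: list[Spot]
    source_channel: str = ""
    detection_params: SpotDetectionParams = field(default_factory=SpotDetectionParams)

    def __len__(self) -> int:
        return len(self.spots)

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) µm positions."""
        if not self.spots:
            return np.empty((0, 2))
        return np.array([s.position for s in self.spots])


def _quadratic_offset(fm1: float, f0: float, fp1: float) -> float:
    """Vertex offset of the parabola through three samples, clamped to ±0.5."""
    denom = fm1 - 2.0 * f0 + fp1
    if denom >= 0:  # not a maximum
        return 0.0
    return float(np.clip(0.5 * (fm1 - fp1) / denom, -0.5, 0.5))


def detect_spots(
    image: PlanarImage,
    mask: np.ndarray | None = None,
    params: SpotDetectionParams | None = None,
    species: str = "",
) -> SpotSet:
    """Detect spots in a planar image, optionally restricted to a mask.

    Returns local maxima of the scale-normalized LoG response at
    ``params.scale_um``, above threshold, inside the mask, non-maximum-
    suppressed at ``min_separation_um`` (ties broken by higher response,
    then ascending (y, x)), with quadratic sub-pixel position refinement.
    An empty mask yields an empty SpotSet; a scale below one pixel is an
    error.
    """
    if params is None:
        params = SpotDetectionParams()
    px = image.pixel_size_um
    sigma_px = params.scale_um / px
    if sigma_px < 1.0:
        raise ValidationError(
            f"scale_um={params.scale_um} is below one pixel ({px} µm)"
        )
    pixels = image.pixels.astype(float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pixels.shape:
            raise ValidationError("mask shape does not match image shape")
        if not mask.any():
            return SpotSet(spots=[], source_channel=image.channel_name, detection_params=params)

    # bright spots give positive response under -LoG; sigma^2 normalizes scale
    response = -(sigma_px**2) * ndimage.gaussian_laplace(pixels, sigma_px)

    if params.threshold_abs is not None:
        thresh = params.threshold_abs
    else:
        bg = response[mask] if mask is not None else response.ravel()
        mad = np.median(np.abs(bg - np.median(bg)))
        thresh = params.threshold_k * MAD_TO_SD * mad

    is_max = response == ndimage.maximum_filter(response, size=3)
    candidates = is_max & (response >= thresh) & (response > 0)
    if mask is not None:
        candidates &= mask
    # exclude the one-pixel border: no room for the quadratic fit
    candidates[0, :] = candidates[-1, :] = False
    candidates[:, 0] = candidates[:, -1] = False

    rows, cols = np.nonzero(candidates)
    if len(rows) == 0:
        return SpotSet(spots=[], source_channel=image.channel_name, detection_params=params)

    resp = response[rows, cols]
    order = np.lexsort((cols, rows, -resp))  # response desc, then (y, x)
    rows, cols, resp = rows[order], cols[order], resp[order]

    # greedy non-maximum suppression at the minimum separation
    min_sep_px = params.min_sep() / px
    kept: list[int] = []
    kept_xy: list[tuple[float, float]] = []
    tree: cKDTree | None = None
    for i in range(len(rows)):
        if kept:
            if tree is None or len(kept_xy) != tree.n:
                tree = cKDTree(kept_xy)
            d, _ = tree.query((cols[i], rows[i]), k=1)
            if d < min_sep_px:
                continue
        kept.append(i)
        kept_xy.append((cols[i], rows[i]))

    spots: list[Spot] = []
    for i in kept:
        r, c = int(rows[i]), int(cols[i])
        dx = _quadratic_offset(response[r, c - 1], response[r, c], response[r, c + 1])
        dy = _quadratic_offset(response[r - 1, c], response[r, c], response[r + 1, c])
        pos = np.array([(c + 0.5 + dx) * px, (r + 0.5 + dy) * px])
        spots.append(
            Spot(
                position=pos,
                peak_intensity=float(pixels[r, c]),
                species=species or image.channel_name,
                quality=float(response[r, c]),
            )
        )
    return SpotSet(spots=spots, source_channel=image.channel_name, detection_params=params)


def match_spots(
    detected: SpotSet | np.ndarray,
    truth: np.ndarray,
    radius_um: float,
) -> tuple[float, float, float]:
    """Greedy one-to-one nearest matching; returns (precision, recall, F1).

    Candidate pairs within ``radius_um`` are assigned in order of increasing
    distance, each detection and truth point used at most once. With no
    detections precision is 1 by convention; with no truth points recall
    is 1; F1 is 0 when precision + recall is 0.
    """
    if radius_um <= 0:
        raise ValidationError("radius_um must be positive")
    det = detected.positions() if isinstance(detected, SpotSet) else np.asarray(detected, float)
    det = det.reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)

    n_det, n_tru = len(det), len(tru)
    if n_det and n_tru:
        diff = det[:, None, :] - tru[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        pairs = np.argwhere(dist <= radius_um)
        order = np.argsort(dist[pairs[:, 0], pairs[:, 1]], kind="stable")
        used_d: set[int] = set()
        used_t: set[int] = set()
        tp = 0
        for i, j in pairs[order]:
            if i in used_d or j in used_t:
                continue
            used_d.add(int(i))
            used_t.add(int(j))
            tp += 1
    else:
        tp = 0
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_tru if n_tru else 1.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1
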