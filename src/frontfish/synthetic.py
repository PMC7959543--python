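"""Ground-truth synthetic scenes: leader-cell fronts, rendered smFISH
channels, and branched spheroid silhouettes.

The leader-cell scene emulates the geometry used to quantify front-biased
RNA localization: a front cytoplasm bounded by an invasive edge (where the
normalized distance d = 0) and a nuclear edge (d = 1), containing
diffraction-limited RNA spots whose d follows a chosen Beta distribution.

Geometry
--------
The front cytoplasm is an annular sector between two concentric circular
arcs: the invasive edge at inner radius ``R0`` and the nuclear edge at outer
radius ``R1 = R0 + L``. For any interior point at radius r the minimum
distances to the two arcs are exactly ``Id = r - R0`` and ``Nd = R1 - r``,
so the radial coordinate maps *exactly* onto the normalized distance
``d = Id / (Id + Nd) = (r - R0) / L``. Beta-distributed d draws therefore
are exact ground truth, with no geometric distortion, while the sector
still tapers naturally toward the invasive tip (the inner arc is shorter).
Transverse (angular) placement is uniform, matching the absence of any
transverse structure in the model.

A Beta(alpha, beta) law is used for the front bias because it lives on
[0, 1] exactly like d and has the analytic mean alpha/(alpha+beta) that
recovery tests compare against. Beta(1, 1) is uniform (an unbiased control
RNA); alpha < beta concentrates spots toward the invasive front.

Rendering uses an isotropic Gaussian approximation of the microscope PSF
plus additive Gaussian read noise on a constant background; the
signal-to-noise ratio (peak spot signal over noise sd) is the controlled
quantity. All randomness flows from the single ``SceneConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union
from skimage.draw import polygon as draw_polygon

from .errors import GenerationError, ValidationError
from .io import EdgeAnnotation, PlanarImage
from .spheroid import SpheroidShape

# chord spacing for polyline approximations of arcs, µm
_ARC_STEP_UM = 0.05


@dataclass
class SceneConfig:
    """Parameters of one synthetic leader-cell scene.

    ``bias`` maps each RNA species to the (alpha, beta) of the Beta
    distribution its normalized distances are drawn from; ``snr`` is the
    peak spot intensity divided by the read-noise sd.
    """

    protrusion_length_um: float = 30.0
    protrusion_width_um: float = 12.0
    n_spots_per_species: dict[str, int] = field(
        default_factory=lambda: {"target": 30, "control": 30}
    )
    bias: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"target": (2.0, 6.0), "control": (1.0, 1.0)}
    )
    psf_sigma_um: float = 0.25
    background_level: float = 100.0
    noise_sd: float = 10.0
    snr: float = 8.0
    pixel_size_um: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.protrusion_length_um > 0 and self.protrusion_width_um > 0):
            raise ValidationError("protrusion dimensions must be positive")
        for sp, (a, b) in self.bias.items():
            if not (a > 0 and b > 0):
                raise ValidationError(f"bias for {sp!r} needs alpha, beta > 0")
        for sp, n in self.n_spots_per_species.items():
            if n < 0:
                raise ValidationError(f"negative spot count for {sp!r}")
        if not self.psf_sigma_um > 0:
            raise ValidationError("psf_sigma_um must be positive")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def spot_amplitude(self) -> float:
        """Integrated spot intensity giving the configured peak SNR.

        With zero read noise a unit noise floor is assumed so ``snr`` still
        sets the peak pixel value.
        """
        sigma_px = self.psf_sigma_um / self.pixel_size_um
        noise_ref = self.noise_sd if self.noise_sd > 0 else 1.0
        return self.snr * noise_ref * 2.0 * math.pi * sigma_px**2


@dataclass
class SyntheticScene:
    """A generated scene: geometry, ground-truth spots, rendered channels.

    ``true_spots`` maps species to a frame with columns
    ``x_um, y_um, d_true`` (d_true is the exact normalized distance).
    """

    config: SceneConfig
    edge_annotation: EdgeAnnotation
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    true_spots: dict[str, pd.DataFrame]
    rendered: dict[str, PlanarImage]


# ---------------------------------------------------------------------------
# Leader-cell scenes
# ---------------------------------------------------------------------------


def _arc_points(center, radius, theta0, theta1) -> np.ndarray:
    n = max(int(abs(theta1 - theta0) * radius / _ARC_STEP_UM), 2)
    theta = np.linspace(theta0, theta1, n + 1)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def _scene_geometry(config: SceneConfig):
    """Arcs, sector polygon, nucleus band and the physical frame, in µm."""
    L = config.protrusion_length_um
    r_inner = 1.5 * L
    r_outer = r_inner + L
    half_w = config.protrusion_width_um / 2.0
    if half_w >= r_outer:
        raise GenerationError("protrusion wider than its bounding arc radius")
    phi = math.asin(half_w / r_outer)

    nucleus_depth = 0.25 * L
    margin = 2.0
    # frame before translation: x in [r_inner cos(phi), r_outer+depth]
    x0 = r_inner * math.cos(phi) - margin
    y0 = -(r_outer * math.sin(phi) + margin)
    center = (-x0, -y0)  # translate so the frame origin is (0, 0)

    invasive = _arc_points(center, r_inner, -phi, phi)
    nuclear = _arc_points(center, r_outer, -phi, phi)
    side_a = np.array([invasive[-1], nuclear[-1]])
    side_b = np.array([nuclear[0], invasive[0]])
    sector = np.vstack([invasive, side_a[1:], nuclear[::-1][1:], side_b[1:]])

    outer_band = _arc_points(center, r_outer + nucleus_depth, -phi, phi)
    nucleus = np.vstack([nuclear, outer_band[::-1]])

    width_um = r_outer + nucleus_depth + margin - x0
    height_um = 2.0 * (r_outer * math.sin(phi) + margin)
    shape_px = (
        int(math.ceil(height_um / config.pixel_size_um)),
        int(math.ceil(width_um / config.pixel_size_um)),
    )
    tip = np.array([center[0] + r_inner, center[1]])
    return {
        "center": center,
        "r_inner": r_inner,
        "r_outer": r_outer,
        "phi": phi,
        "invasive": invasive,
        "nuclear": nuclear,
        "sector": sector,
        "nucleus": nucleus,
        "shape_px": shape_px,
        "tip": tip,
    }


def _rasterize(poly_um: np.ndarray, shape_px, pixel_size_um: float) -> np.ndarray:
    rr, cc = draw_polygon(
        poly_um[:, 1] / pixel_size_um - 0.5,
        poly_um[:, 0] / pixel_size_um - 0.5,
        shape=shape_px,
    )
    mask = np.zeros(shape_px, dtype=bool)
    mask[rr, cc] = True
    return mask


def render_spots(
    spots_um: np.ndarray,
    config: SceneConfig,
    shape_px: tuple[int, int],
    rng: np.random.Generator | None = None,
    amplitude: float | None = None,
) -> PlanarImage:
    """Render point spots as Gaussian PSFs plus background and read noise.

    Each spot adds an isotropic Gaussian of sd ``psf_sigma_um`` whose sum
    over pixels (the integrated excess intensity) equals ``amplitude``;
    Gaussian noise of sd ``noise_sd`` rides on ``background_level``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if amplitude is None:
        amplitude = config.spot_amplitude
    spots_um = np.asarray(spots_um, dtype=float).reshape(-1, 2)
    h, w = shape_px
    extent = (w * config.pixel_size_um, h * config.pixel_size_um)
    if len(spots_um) and (
        (spots_um < 0).any()
        or (spots_um[:, 0] > extent[0]).any()
        or (spots_um[:, 1] > extent[1]).any()
    ):
        raise ValidationError("spot coordinates fall outside the image bounds")

    img = np.zeros(shape_px, dtype=float)
    sigma_px = config.psf_sigma_um / config.pixel_size_um
    half = int(math.ceil(4.0 * sigma_px))
    peak = amplitude / (2.0 * math.pi * sigma_px**2)
    for x_um, y_um in spots_um:
        cx = x_um / config.pixel_size_um - 0.5  # pixel-centre coordinates
        cy = y_um / config.pixel_size_um - 0.5
        c0, r0 = int(round(cx)), int(round(cy))
        rows = np.arange(max(r0 - half, 0), min(r0 + half + 1, h))
        cols = np.arange(max(c0 - half, 0), min(c0 + half + 1, w))
        if not len(rows) or not len(cols):
            continue
        dy = (rows - cy)[:, None]
        dx = (cols - cx)[None, :]
        img[np.ix_(rows, cols)] += peak * np.exp(
            -(dx**2 + dy**2) / (2.0 * sigma_px**2)
        )
    img += config.background_level
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=shape_px)
    return PlanarImage(pixels=img, pixel_size_um=config.pixel_size_um)


def make_leader_scene(config: SceneConfig) -> SyntheticScene:
    """Generate one ground-truth leader-cell scene from a seeded config.

    For each species, normalized distances are i.i.d. Beta(alpha, beta)
    draws mapped onto the radial axis of the sector, with uniform angular
    placement. Spot placement is verified against the front-region polygon
    (up to 100 angular redraws per spot before a generation error). Two
    calls with equal configs produce identical scenes.
    """
    rng = np.random.default_rng(config.seed)
    geo = _scene_geometry(config)
    sector_poly = Polygon(geo["sector"])
    if not sector_poly.is_valid:
        raise GenerationError("degenerate front-region polygon")

    annotation = EdgeAnnotation(
        invasive_edge=geo["invasive"],
        nuclear_edge=geo["nuclear"],
        front_region=geo["sector"],
        tip=geo["tip"],
    )
    nucleus_mask = _rasterize(geo["nucleus"], geo["shape_px"], config.pixel_size_um)
    cell_mask = (
        _rasterize(geo["sector"], geo["shape_px"], config.pixel_size_um) | nucleus_mask
    )

    center = np.asarray(geo["center"])
    L = config.protrusion_length_um
    true_spots: dict[str, pd.DataFrame] = {}
    rendered: dict[str, PlanarImage] = {}
    for species in sorted(config.n_spots_per_species):
        n = config.n_spots_per_species[species]
        alpha, beta = config.bias.get(species, (1.0, 1.0))
        d = rng.beta(alpha, beta, size=n)
        pts = np.empty((n, 2))
        for i, d_i in enumerate(d):
            r = geo["r_inner"] + d_i * L
            for _attempt in range(100):
                theta = rng.uniform(-geo["phi"], geo["phi"])
                p = center + r * np.array([math.cos(theta), math.sin(theta)])
                if sector_poly.covers(Point(p)):
                    pts[i] = p
                    break
            else:
                raise GenerationError(
                    f"could not place spot {i} of {species!r} inside the mask"
                )
        true_spots[species] = pd.DataFrame(
            {"x_um": pts[:, 0], "y_um": pts[:, 1], "d_true": d}
        )
        rendered[species] = render_spots(pts, config, geo["shape_px"], rng=rng)
        rendered[species].channel_name = species

    noise = rng.normal if config.noise_sd > 0 else None
    for name, mask in (("cellmask", cell_mask), ("dapi", nucleus_mask)):
        img = config.background_level + mask * (8.0 * config.noise_sd)
        img = img.astype(float)
        if noise is not None:
            img = img + noise(0.0, config.noise_sd, size=mask.shape)
        rendered[name] = PlanarImage(
            pixels=img, channel_name=name, pixel_size_um=config.pixel_size_um
        )

    return SyntheticScene(
        config=config,
        edge_annotation=annotation,
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        true_spots=true_spots,
        rendered=rendered,
    )


# ---------------------------------------------------------------------------
# Spheroid silhouettes
# ---------------------------------------------------------------------------


def make_spheroid_silhouette(
    n_branches: int,
    branch_length_um: float = 60.0,
    branch_width_um: float = 14.0,
    body_radius_um: float = 75.0,
    seed: int = 0,
    pixel_size_um: float = 1.0,
) -> SpheroidShape:
    """A disk body with radial invasive strands, as exact polygon + raster.

    The returned shape records the *exact* polygon perimeter and area as
    ground truth (shapely geometry), alongside a rasterized mask at
    ``pixel_size_um``. Overlapping strands are merged; if the union is not
    a simple polygon the strand angles are re-jittered up to 10 times.
    """
    if not branch_width_um < body_radius_um:
        raise ValidationError("branch_width_um must be smaller than body_radius_um")
    rng = np.random.default_rng(seed)
    for _try in range(10):
        parts = [Point(0.0, 0.0).buffer(body_radius_um, quad_segs=256)]
        angles = rng.uniform(0.0, 2.0 * math.pi, size=n_branches)
        for ang in angles:
            strand = box(
                0.0,
                -branch_width_um / 2.0,
                body_radius_um + branch_length_um,
                branch_width_um / 2.0,
            )
            parts.append(affinity.rotate(strand, math.degrees(ang), origin=(0, 0)))
        poly = unary_union(parts)
        if poly.geom_type == "Polygon" and not list(poly.interiors):
            break
    else:
        raise GenerationError("could not build a simple spheroid polygon")

    extent = body_radius_um + (branch_length_um if n_branches else 0.0)
    margin = 2.0 * pixel_size_um
    shift = extent + margin
    poly = affinity.translate(poly, xoff=shift, yoff=shift)
    coords = np.asarray(poly.exterior.coords)
    n_px = int(math.ceil(2.0 * shift / pixel_size_um))
    mask = _rasterize(coords, (n_px, n_px), pixel_size_um)
    return SpheroidShape(
        mask=mask,
        contour=coords,
        perimeter_um=float(poly.exterior.length),
        area_um2=float(poly.area),
        pixel_size_um=pixel_size_um,
    )
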