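# Methods

This note documents the models and procedures implemented in `frontfish`,
the choices made where the underlying methodology left the design open, and
what the synthetic-data tests do and do not establish about real data.

## Coordinate and unit conventions

All public interfaces use (x, y) coordinates in micrometres, origin at the
top-left pixel corner, with the centre of raster pixel (row, col) at
((col + 0.5)·px, (row + 0.5)·px). Raster indexing is 0-based (row, col).
Edge annotations may be written in pixel or µm units with an explicit
`units` field; they are converted to µm on read and never guessed.
Z-stacks are collapsed by maximum-intensity projection before any
quantification; no volumetric analysis is performed.

## Normalized front distance

For each RNA spot the distances to the invasive and nuclear edges are
minimum Euclidean point-to-polyline distances (segment-wise projection).
This is the plainest reading of "distance from the edge" for a manually
drawn open polyline; geodesic distances inside the cell mask would require
a segmentation the workflow deliberately does not assume.

Normalization is per spot: d = Id/(Id + Nd), so the protrusion length L is
measured through each spot individually rather than once per cell. The
alternative — averaging raw distances first and normalizing the averages —
is available via `summarize_cell(..., per_spot_normalization=False)` for
sensitivity analyses but is not the default. Spots whose total L falls
below a floor (default 0.1 µm, i.e. effectively sitting on both edges at
once) carry no directional information and are dropped with a log message.

Two exact invariants pin the scale: a spot on the invasive edge has d = 0
and a spot on the nuclear edge d = 1; swapping the two edges maps d to
1 − d; rescaling all coordinates leaves d unchanged.

Cells, not spots, are the statistical unit. Per-cell species means feed:

* **Density estimates** on [0, 1]: Gaussian KDE with boundary reflection
  at 0 and 1 (kernel mass leaving the support is folded back, preserving
  normalization on the bounded axis). Bandwidth follows Silverman's rule
  unless overridden; the discrete trapezoidal integral is renormalized to
  1 so downstream consumers can rely on it to ~1e-15. If all means are
  identical the KDE degenerates and a documented narrow-kernel fallback
  (sd 0.005) is returned with a warning.
* **Paired target-vs-control test**: two-sided Wilcoxon signed-rank on
  per-cell differences, paired strictly by cell id. Zero differences are
  dropped (classic Wilcoxon convention), ties are mid-ranked; the exact
  null distribution is used up to 25 informative pairs and the normal
  approximation with continuity correction above. The internal-control
  design matters: both species are measured in the same cell with the same
  edges, so segmentation and geometry errors cancel in the pairing.
* **Condition comparisons** (many-to-one against a named reference):
  one-way ANOVA with Dunnett's adjustment, or Kruskal–Wallis followed by
  Dunn's rank z-tests with Bonferroni correction over the (k − 1)
  comparisons. Dunnett's p-values involve a quasi-Monte-Carlo multivariate-t
  integral; the implementation seeds it so repeated calls agree exactly.

## Spot detection

The detector is a single-scale Laplacian of Gaussian at a scale matching
the expected spot radius (default 0.25 µm, about the diffraction-limited
PSF width), scale-normalized by σ². Candidate maxima above threshold are
non-maximum-suppressed at a minimum separation (default 2× scale), ordered
by response and then by (y, x) for determinism, and refined to sub-pixel
positions with a per-axis quadratic fit clamped to ±0.5 px.

The default threshold is 5 robust standard deviations (1.4826 × MAD) of
the LoG response inside the analysis mask. Because both the response and
its MAD scale linearly with the image, detection is invariant to
multiplying the image by any positive constant, and the LoG kernel removes
constant offsets — the two invariances the tests assert. At this threshold
pure-noise images essentially never produce detections (≥ 99/100 seeded
noise fields are empty).

Detection quality is scored by greedy one-to-one nearest matching against
ground truth within a radius (precision defined as 1 when there are no
detections). Spots closer together than the minimum separation are
intrinsically unresolvable at the diffraction limit and count against
recall; the generator's default density (30 molecules per species per
front cytoplasm) keeps the scene in the sparse single-molecule regime
where smFISH counting is meaningful.

## Synthetic leader-cell scenes

The front cytoplasm is modelled as an annular sector between two concentric
arcs: the invasive edge at inner radius R₀ = 1.5 L and the nuclear edge at
R₁ = R₀ + L, with L the protrusion length (default 30 µm) and the angular
span set so the width at the nuclear edge equals the configured protrusion
width (default 12 µm). The sector tapers toward the tip (the inner arc is
shorter), and — the reason for this geometry — the radial coordinate maps
*exactly* onto the normalized distance: for a point at radius r,
Id = r − R₀ and Nd = R₁ − r, so d = (r − R₀)/L with no distortion
anywhere in the region. Sampled Beta(α, β) draws of d are therefore exact
ground truth. Arcs are emitted as polylines with 0.05 µm chords, making the
polyline-vs-arc discrepancy (≲ 10⁻⁶ µm here) negligible against every
tolerance used.

The Beta family is the bias model because it lives on [0, 1] like d and
has the analytic mean α/(α + β) that recovery tests compare against;
Beta(1, 1) is the uniform, unbiased control. Transverse (angular)
placement is uniform — no transverse structure is modelled. Defaults
(target Beta(2, 6) vs control Beta(1, 1), 30 spots per species, peak
SNR 8) describe a clearly front-biased RNA co-detected with an unbiased
internal control at routine confocal signal-to-noise.

Rendering approximates the PSF by an isotropic Gaussian (default σ
0.25 µm) of unit discrete integral times an amplitude; noise is additive
Gaussian on a constant background, and the amplitude is derived from the
configured peak SNR (with a unit noise floor when noise is disabled).
Poisson shot noise, uneven illumination, autofluorescence and optical
aberrations are deliberately not modelled: the generator controls SNR, not
camera realism. Consequently, passing recovery tests demonstrate the
*analysis* is correct and well-calibrated — they do not certify detector
performance on real micrographs, where thresholds may need adjustment.

All randomness flows from the single integer seed in `SceneConfig`; equal
configs reproduce scenes bit for bit.

## Spheroid complexity

Complexity = P²/(4π·A), the reciprocal isoperimetric quotient: 1 for a
circle, 4/π for a square, unbounded as the boundary grows at fixed area.
It is dimensionless and invariant to uniform rescaling, which makes it a
pure shape (invasiveness) metric independent of spheroid size.

Segmentation of calcein-stained spheroids: Gaussian smoothing, Otsu
threshold, largest connected component, hole filling, minimum-area filter.
Measurement: the binary mask is smoothed with a 1 px Gaussian and the
contour extracted by marching squares at iso-level 0.5. The smoothing
matters: an iso-contour of the raw binary mask is a 45°/90° staircase that
overestimates a disk's perimeter by ~5% (and pixel-edge counting by up to
4/π); after smoothing, a rasterized disk of radius 100 px measures within
1% of 2πr and its complexity within 1% of 1.0, and branched silhouettes
agree with their exact generating polygons to better than 3%. Objects too
thin to survive smoothing fall back to the raw iso-contour; an isolated
pixel yields the marching-squares diamond through its four neighbour
midpoints (area = half a pixel) by documented convention. Masks touching
the image border are measured with a warning, since the visible perimeter
then underestimates the object's.

Because the absolute value depends on the perimeter estimator, comparisons
across software should be treated as ordinal; within this package the
estimator is fixed and values are directly comparable.

Synthetic silhouettes (disk body plus radial strands at seeded angles,
merged by polygon union) carry their exact shapely perimeter and area as
ground truth; complexity increases strictly with strand count at fixed
body radius.

## Perimeter profiles

The front-cytoplasm contour is resampled at 0.5 µm arc-length steps; at
each sample the intensity is averaged over a disk (default radius 1 µm)
of pixel centres — a disk rather than a normal-line transect because it is
rotation invariant and needs no stable normal estimate on a hand-drawn
contour. Positions are reported as signed arc length from the protrusion
tip (tip snapped to the contour, at most 1 µm away); reversing the
traversal direction mirrors the profile about 0.

Aggregation across cells: each profile is optionally normalized by its own
mean (default on — removing per-cell exposure differences, at the price of
absolute units), linearly interpolated onto a common grid, and summarized
by the per-grid-point mean and t-based 95% confidence band across cells,
with no multiplicity adjustment (a descriptive band, not a test). Grid
points supported by fewer than 3 cells are dropped.

## Peripheral Distribution Index

PDI = E_signal[r²] / E_uniform[r²], where r is the distance to the nucleus
centroid, the numerator is intensity-weighted over the signal restricted
to the cytoplasm, and the denominator averages over all cytoplasm pixels.
By construction a uniform signal scores exactly 1 (the anchor the
interpretation rests on); the index is invariant to uniform intensity
scaling and rigid motions, and strictly increases as signal mass moves
radially outward. Signal may be an intensity image, a detected spot set,
or raw point coordinates; points are filtered to the cytoplasm mask. The
second-moment-about-the-nucleus-centroid convention is documented here
precisely because peripheral-distribution indices in the literature vary
in detail; values are self-consistent within the package.

## GA-content scanning

Windows are fully contained (length − w + 1 values at step 1, default
w = 30 nt), percent GA = 100·(#G + #A)/w, case-insensitive, U read as T,
N counting as neither. Output coordinates are 0-based half-open. GA-rich
regions are maximal runs of supra-threshold windows converted to sequence
coordinates, merged when overlapping, and filtered by a minimum span.

## Problem sizes and calibration checks

The test suite validates calibration by simulation at sizes a desk machine
handles comfortably: 40 scenes for end-to-end bias recovery (grand-mean
recovered d within 3 standard errors of the Beta(2, 6) mean, paired test
rejecting at α = 0.01, pooled detection F1 ≥ 0.9); 200 null replicates at
n = 30 per group for type-I error of the paired and many-to-one tests
(observed rate ≤ 0.07 at nominal 0.05); 100 replicates of 23-cell profile
families for confidence-band coverage (≥ 93%); 10³ random configurations
for the point-to-polyline distance against a dense-sampling oracle
(agreement to 10⁻⁶ µm); 10⁴ uniform draws for the PDI diffuse anchor
(1.00 ± 0.02).

## Known limitations

* Edges are provided, not inferred: no automatic leader-cell
  identification or nuclear segmentation.
* 2-D only: all quantities are computed on maximum-intensity projections.
* The spot detector is single-scale and does not decompose dense clusters;
  heavily overlapping molecules are undercounted by design.
* Complexity values are estimator-dependent in absolute terms; use them
  comparatively.
* The synthetic generator's Gaussian-noise, Gaussian-PSF model omits shot
  noise and optical aberrations; it tests the analysis, not the camera.
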