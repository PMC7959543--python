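# frontfish

Quantification of front-biased RNA localization in invasive leader cells.

When cancer-cell spheroids invade a 3-D matrix collectively, the cell at the
tip of each invasive strand (the *leader cell*) can concentrate specific
RNAs — such as *RAB13* and *NET1* transcripts — in the cytoplasm that faces
the matrix. `frontfish` implements the image-quantification and
sequence-scanning computations used to establish and characterize that
phenotype, together with a fully seeded synthetic-scene generator so that
every stage can be verified end to end without any raw microscopy data.

## What it computes

**Normalized front distance.** For each single-molecule FISH spot *i* in a
leader cell's front cytoplasm, its minimum Euclidean distances to the
manually drawn invasive edge (*Id<sub>i</sub>*) and nuclear edge
(*Nd<sub>i</sub>*) give the per-spot normalized distance

> d<sub>i</sub> = Id<sub>i</sub> / (Id<sub>i</sub> + Nd<sub>i</sub>),

0 at the invasive edge and 1 at the nuclear edge. Per-cell species averages
feed boundary-reflected kernel density estimates, a paired Wilcoxon
signed-rank test against an internally co-detected control RNA, and
many-to-one condition comparisons (ANOVA/Dunnett or Kruskal–Wallis/Dunn).

**Spheroid invasion complexity.** The reciprocal isoperimetric quotient of
a segmented spheroid silhouette,

> complexity = P² / (4π·A),

equal to 1 for a circle and higher the more invasive strands the spheroid
sends out. Perimeter and area come from a sub-pixel marching-squares
contour.

**Perimeter intensity profiles.** Extracellular-matrix stain intensity
(laminin, fibronectin) sampled along the front-cytoplasm contour as signed
arc length from the protrusion tip, aggregated across cells with a t-based
95% confidence band.

**Peripheral Distribution Index (PDI).** A second-moment polarity score for
single cells: the signal's intensity-weighted mean squared distance from
the nucleus centroid divided by the same moment of a uniform distribution
over the cytoplasm. Diffuse signal scores 1; peripheral enrichment > 1.

**GA-content scanning.** Sliding-window (default 30 nt) percent-GA profiles
of 3'UTR sequences and GA-rich region calls — the coordinates antisense
morpholinos are designed against.

**smFISH spot detection.** Single-scale Laplacian-of-Gaussian detection
with robust (MAD-based) thresholding, non-maximum suppression and
quadratic sub-pixel localization.

## Worked example

Simulate twelve leader-cell scenes in which the target RNA's normalized
distance is drawn from Beta(2, 6) (front-biased, mean 0.25) and an internal
control from Beta(1, 1) (uniform), detect spots at peak SNR 8, and run the
full statistic:

```python
import numpy as np
from frontfish import (SceneConfig, SpotDetectionParams, make_leader_scene,
                       detect_spots, spot_edge_distances, summarize_cell,
                       paired_shift_test)

params = SpotDetectionParams(scale_um=0.25, threshold_k=5.0)
target, control = [], []
for i in range(12):
    scene = make_leader_scene(SceneConfig(seed=100 + i))
    for species, sink in (("target", target), ("control", control)):
        spots = detect_spots(scene.rendered[species], scene.cell_mask, params)
        recs = spot_edge_distances(spots, scene.edge_annotation, species=species)
        sink.append(summarize_cell(recs, f"cell{i}", species))

res = paired_shift_test(target, control)
print(f"target  mean d = {np.mean([s.mean_d for s in target]):.3f}")
print(f"control mean d = {np.mean([s.mean_d for s in control]):.3f}")
print(f"Wilcoxon signed-rank: W = {res.statistic:.1f}, n = {res.n_pairs}, "
      f"p = {res.p_value:.2e}")
```

prints

```
target  mean d = 0.257
control mean d = 0.504
Wilcoxon signed-rank: W = 0.0, n = 12, p = 4.88e-04
```

The detected target RNA sits at a mean normalized distance of 0.257 —
recovering the simulated front bias (truth 0.250) through rendering,
detection and geometry — while the internal control stays uniform (0.504),
and the paired test separates the two species at p < 10⁻³ with only twelve
cells. On the silhouette side:

```python
from frontfish import make_spheroid_silhouette
print(make_spheroid_silhouette(0, seed=0).complexity)   # 1.000 (round)
print(make_spheroid_silhouette(6, seed=0).complexity)   # 4.758 (invasive)
```

## Command line

The same stages are exposed as subcommands of a `frontfish` console script:
`simulate`, `spots`, `front-distance`, `complexity`, `profile`, `pdi`,
`ga-scan`, plus `run --config config.yaml` to execute a configured list of
stages. All subcommands emit CSV tables (and a JSON manifest where a
directory of outputs is produced); `--verbose` enables debug logging on
stderr.

```sh
frontfish simulate --config sim.yaml --out scene/
frontfish spots --image scene/target.tif --pixel-size 0.2 \
    --mask scene/cell_mask.tif --species target --out spots.csv
frontfish front-distance --spots spots.csv --edges scene/edges.json \
    --cell-id cell1 --out fd
frontfish ga-scan --fasta utr.fa --window 30 --threshold 60 --out scan
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator, the
numerical choices and the known limitations in detail.
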