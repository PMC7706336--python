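# stemscan

Post-harvest stem phenotyping for cereal field trials. After a combine pass,
the cut stems of a wheat microplot stand as short stubble; a submillimetric
nadir RGB image shows each stem cross-section as a bright ring (the stem
wall) around a darker lumen on a darker soil background. `stemscan` turns
such images — or bounding boxes produced by any external detector — into
plot-level structural traits and the statistics breeders use to judge them.

It is aimed at phenotyping engineers and quantitative geneticists who need
stem density, stem diameter distributions and biomass proxies at microplot
scale without manual counting.

## What it computes

**Detection.** Images are tiled into 1000×1000 px patches with 50 % overlap;
candidates from a matched annulus-template detector (zero-mean normalized
cross-correlation over a radius range, non-maximum suppression at IOU 0.2)
or from an external detections file are translated to parent coordinates,
cross-patch duplicates are eliminated at a 0.75 overlap fraction, and
candidates with confidence score < 0.80 are discarded.

**Diameter.** Each accepted box is converted to gray with
V = 0.2989 R + 0.5870 G + 0.1140 B; gray-value profiles through the box
center along 0°, 45°, 90° and 135° are bimodal, and the distance between the
two per-side intensity maxima (sub-sample refined), averaged over the valid
directions, gives the diameter of the ring-center circle. Ground resolution
(mm/px) converts to millimetres.

**Plot traits.** With sampled area *A* (m²) and *n* accepted stems:

- stem density ρ = n / A (stems/m²) — a proxy for ear density;
- the per-plot diameter law, fitted by maximum likelihood to gamma(k, θ)
  (mean = k·θ) and to a normal law, the better KS p-value selecting the
  family;
- basal area S = mean(π d²/4) · ρ (m² of stem section per m² of ground);
- biovolume B = S · h with plant height h (m), a structural proxy for
  above-ground biomass (AGB).

**Evaluation.** TP/FP/FN by greedy IOU matching at 0.5; precision,
recall and bias = 1 − recall/precision; estimate-vs-reference regression
with RRMSE = 100·RMSE/mean(reference); leave-one-out cross-validated linear
trait→AGB models; broad-sense heritability H² = Vg/(Vg+Ve) from a one-way
random-effects ANOVA with a harmonic-mean replicate divisor.

A synthetic module renders annotated stubble scenes (stems along rows 0.17 m
apart, diameters gamma(6, 0.35) mm, soil noise, straw streaks) and
replicated variety trials with designed heritability, so the whole pipeline
is testable without field data.

## Worked example

```python
from stemscan import (SceneSpec, render_scene, DetectorConfig,
                      run_detection_pipeline, measure_stems, plot_traits,
                      match_detections, detection_metrics)

spec = SceneSpec(seed=42, noise_sigma=8.0)          # 0.18 mm/px, 350 stems/m²
rgb, truth = render_scene(spec)
cfg = DetectorConfig.for_resolution(spec.resolution)
dets = run_detection_pipeline(rgb, cfg=cfg)
ms = measure_stems(rgb, dets, spec.resolution)
t = plot_traits("demo", ms, truth.area_m2, height_m=0.8)
m = detection_metrics(match_detections(dets, truth.boxes))
```

prints (via the obvious f-strings):

```
true stems: 11   detections: 11
precision 1.00  recall 1.00  bias +0.00
stem density : 339.5 stems/m^2 (truth 339.5)
mean diameter: 2.38 mm (truth 2.40)
diameter law : gamma (p=0.99)
basal area   : 1.56e-03 m^2/m^2
biovolume    : 1.25e-03 m^3/m^2
```

Every true stem in this noisy 0.0324 m² extract is found with no false
positives, so the density estimate equals the truth; the mean diameter is
recovered to 0.02 mm and the gamma family is (correctly) preferred for the
per-plot diameter distribution.

The same flow is available from the shell:

```sh
stemscan simulate --n-scenes 3 --out-dir scenes
stemscan detect scenes/scene_*.png --out det.csv
stemscan measure scenes/scene_*.png --detections det.csv --out meas.csv
stemscan traits --measurements meas.csv --heights heights.csv \
    --config cfg.yaml --out traits.csv
stemscan evaluate --mode detection --predicted det.csv --reference truth.csv
```

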