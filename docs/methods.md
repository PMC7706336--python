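# Methods

## Imaging model and coordinate conventions

All geometry uses 0-based, half-open pixel boxes `[xmin, xmax) × [ymin, ymax)`
with the origin at the top-left corner, x rightward and y downward — the
dominant imaging convention. Pixel cell `(i, j)` occupies the unit square
with continuous center `(j + 0.5, i + 0.5)`; profile sampling and the
synthetic renderer agree on this convention, so sub-pixel positions are
comparable across modules.

Ground resolution (GSD, mm/pixel) is the single scale parameter tying pixels
to the field. Typical values for this kind of imagery are 0.12–0.18 mm/px
(camera 1.2–1.8 m above the stubble); at those scales a 2 mm stem is an
11–17 px ring, which sets every radius default below.

## Detection post-processing

Large images are tiled into `patch_size` = 1000 px patches with 50 % overlap
(stride = patch_size·(1 − overlap); a final anchor is clamped to
`dim − patch_size`, and images smaller than a patch produce a single clipped
patch — clamping rather than padding avoids synthetic border content).
Candidates are translated to parent coordinates and duplicates are removed
at an **overlap fraction** ≥ 0.75, where overlap fraction =
intersection / min(area). The min-area denominator is deliberate: a box
nested inside another — the geometry cross-patch duplication produces —
scores 1.0, while IOU would dilute it. Elimination is greedy in
score-descending order (ties broken position-lexicographically), keeping the
higher-score member of each conflicting pair; the procedure is idempotent.
Finally the confidence cut keeps scores **≥ 0.80** (inclusive: only strictly
smaller scores are discarded). Duplicates are merged before the score cut by
default; the order is configurable because a candidate just above threshold
can suppress near-duplicates either way.

## The reference ring detector

The package's contract is "boxes + scores in, traits out", so any external
detector (typically a fine-tuned CNN run elsewhere) can feed it through the
CSV/JSON interface. The built-in reference detector is classical: stems are
identified by relative brightness, not color, so the gray image is matched
against Gaussian-profiled annulus templates
`exp(−(r − R)² / 2σ²)` at `n_radii` = 8 radii spanning
`[radius_min, radius_max]` using zero-mean normalized cross-correlation
(skimage `match_template`). ZNCC is gain/offset invariant, so uniform
illumination changes do not move detections (up to floating-point
tie-breaking of the argmax pixel). The per-pixel maximum response over radii
is peak-picked (`peak_local_max`, minimum distance = radius_min), each peak
becomes a square box of side `2R(1 + 0.25)` — the 25 % margin guarantees the
diameter profiles see background on both sides — with score
`(corr + 1)/2`, and candidates are thinned by NMS at IOU ≥ 0.2.
`DetectorConfig.for_resolution` brackets the radii as
`[0.45, 2.0] × (expected diameter / GSD / 2)`, covering the mass of a
gamma(6, 0.35) mm diameter law at either default resolution.

## Diameter from gray profiles

Boxes are converted to gray with the fixed luma combination
`V = 0.2989 R + 0.5870 G + 0.1140 B` (unrounded). Profiles are sampled by
bilinear interpolation at 0.5-px steps along the four compass directions
through the box center, clipped to the box. On each side of the center the
position of the maximum gray value marks one stem border; the border
position is refined by parabolic interpolation over the three samples around
the maximum (clamped to ±half a step). A side is unusable when it has fewer
than 5 samples, is flat, or its maximum sits at the outermost sample (a
border truncated by the box edge); ties are resolved toward the center. A
direction's distance is the separation of its two border positions; the stem
measurement is the arithmetic mean over usable directions and requires **at
least two** of the four (a stem at a patch border with one usable direction
is flagged invalid rather than measured from a single chord). No profile
smoothing is applied by default; a Gaussian σ (in sample units) is exposed
for noisy imagery.

The quantity recovered is the **ring-center diameter**: the intensity maxima
sit on the circle through the middle of the bright stem wall, not on its
outer edge. Synthetic ground truth is defined the same way; users
calibrating against caliper measurements of outer diameter should expect an
offset of roughly one wall thickness.

## Plot traits

Stem density is count/area. The sampled area of row segments is
`n_samples × rows_per_sample × row_spacing × length` (e.g. three samples of
two rows by 1.0 m at the 0.17 m default row spacing give 1.02 m²); for whole
image extracts it is the image footprint. Basal area uses the mean of the
per-stem section areas (not the area of the mean diameter; by Jensen the two
differ whenever diameters vary), and biovolume is basal area × height, in
m³ per m² of ground. Heights are accepted in metres; centimetre columns are
converted at ingest.

Diameter distributions are fitted per plot in millimetres by maximum
likelihood: gamma with location fixed at 0 (diameters are strictly
positive), and normal. No goodness-of-fit convention is canonical here, so
both families get a one-sample Kolmogorov–Smirnov p-value against their
fitted law and the larger p-value selects the family; KS with estimated
parameters is optimistic, but identically so for both families, and only the
comparison matters. Fits require ≥ 10 finite positive values and reject
degenerate (constant) samples.

## Evaluation statistics

Detections are matched to labeled boxes greedily in score-descending order,
each to the unmatched truth of highest IOU, requiring IOU **strictly
greater** than 0.5. Greedy matching can in principle fall below the optimal
assignment on pathological overlap chains; the tests bound it by an
exhaustive assignment oracle and verify exact agreement on unambiguous
scenes. Precision = TP/(TP+FP), recall = TP/(TP+FN), and
**bias = 1 − recall/precision** (negative when recall exceeds precision).
The algebraically reversed form 1 − precision/recall also circulates; it is
available via `formula="text"`, but the default is the form consistent with
the sign convention above.

Agreement metrics regress the reference on the estimate by OLS for slope,
intercept and R²; RMSE is the root mean squared estimate−reference
difference and RRMSE = 100·RMSE/mean(reference). Leave-one-out
cross-validation refits the linear model per held-out plot, pools the
out-of-fold predictions, and reports RMSE/RRMSE of the pooled errors and the
predictive R² `1 − SS_res/SS_tot` (per-fold R² is undefined when each fold
holds one plot; predictive R² is ≈ 0 — possibly slightly negative — for a
skill-less model, whereas squared correlation of LOO predictions is
misleadingly inflated). Rank-deficient predictor tables are rejected.

Broad-sense heritability uses a one-way random-effects ANOVA over genotypes:
Ve = within-genotype mean square, Vg = (between MS − within MS)/r̄ with r̄
the harmonic mean of the replicate counts (the standard divisor under
unbalanced replication, here 6–15 replicates), clipped at zero, and
H² = Vg/(Vg+Ve). H² is invariant to shifting or rescaling the trait.

## Synthetic data: what it emulates, and what it does not

Scenes place `round(density × area)` stems on vertical planting rows
0.17 m apart (row pattern centered; at these image sizes one or two rows
cross the frame), with 3 px lateral jitter, uniform positions along the row,
and a minimum center separation of 2.2 × the largest radius. Each stem is a
radial intensity profile `background + contrast·exp(−(r−R)²/2σ²)` plus a
lumen plateau slightly above background — high values at the stem border,
lower inside and outside. Defaults mirror realistic acquisitions: 0.18 mm/px
(0.12 supported), 350 stems/m², diameters gamma(6, 0.35) mm truncated to
[1, 4] mm (sub-millimetre stems are not biologically plausible and would be
invisible at these resolutions), background 70, ring contrast 130, ring
width σ = 1.2 px, Gaussian soil noise σ = 8 gray levels, two straw streaks.
Ground-truth boxes are squares of side 2R·1.25, matching the detector's
margin. Rendering is bit-deterministic per seed.

Trial tables draw genotype effects (variance Vg) and plot residuals
(variance Ve) per trait independently — defaults: density 561 ± (Vg 13520,
Ve 3380, designed H² 0.8), diameter 2.1 mm, height 0.8 m — then AGB =
β·biovolume·(1 + ε) with β = 7·10⁵ g/m³ and ε ~ N(0, 0.06), and ear density
= stem density + N(0, 20).

What passing synthetic tests shows: the post-processing, measurement and
statistical machinery is numerically correct and recovers designed
quantities under the stated image model. What it does not show: performance
on real stubble, where inclined stems, lodged straw, partial occlusion,
non-Gaussian soil texture and illumination gradients degrade both detection
and profile shape. The generator's streaks and noise are caricatures of that
clutter, not calibrated models of it.

## Problem sizes in the default test run

The test suite renders 1000×1000 px scenes (≈ 0.032 m², ~11 stems each): 20
clean and 20 noisy scenes for end-to-end recovery, 500 single-annulus
patches for diameter accuracy, 100 simulated plots of 300 stems for
family selection, 200 simulated 16-genotype trials for heritability, and
37-plot trials for the biomass models — sizes chosen to make Monte-Carlo
bands tight while keeping the whole suite a few-minute, single-CPU run.

## Known limitations

- No ellipse fitting or deprojection: inclined stems read as slightly
  elliptical rings and bias the four-direction mean upward.
- The reference detector assumes a bright closed annulus; heavily occluded
  or broken rings fall below the correlation floor and are missed (this is
  by design: such stems should come from a stronger external detector).
- KS-based family selection compares fit quality only; it is not a test of
  either family's truth.
- Greedy duplicate elimination and greedy matching are order-deterministic
  but not globally optimal.
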