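# Methods

## Segmentation

Plate scans are binarized by local-mean thresholding: a pixel is
foreground when it is darker than the mean of the square window (side
`window_um`, default 300 µm ≈ 46 px at 6.5 µm/px) centred on it by more
than `offset` (default 2%) of the image intensity range. The window is
roughly one worm-width scale above adult body thickness: large enough to
average over a whole body, small enough to track the illumination
gradients of stitched scans. Holes are filled before region extraction
so skeletons are never perforated. Polarity is dark-foreground by
default with an inversion flag.

Connected components (8-connectivity) become candidate worms after a
physical-unit filter: area 3,000–120,000 µm² and bounding-box diagonal
120–2,500 µm, bounds chosen to bracket L4-to-adult *C. elegans* at
6–7 µm/px (eggs are ~1,500 µm² and fall below the floor; merged clumps
typically exceed the ceiling). Border-touching components are dropped by
default because their shape parameters would be truncated. Components
smaller than the area floor are discarded before property computation,
which keeps noisy scans (thousands of 1–2 px specks) fast.

## Skeleton metrology

The filled mask is thinned (`skimage.morphology.skeletonize`,
`method="lee"`, which empirically yields single-pixel paths with clean
endpoints on elongated shapes). Spurs shorter than `spur_prune_um`
(default 40 µm) — thinning artifacts at wide heads — are removed
iteratively: each endpoint branch is walked to its junction and deleted
if short; because removals are sequential, a two-pronged tip keeps its
longer prong. The result is accepted only if it is a single
endpoint-to-endpoint path: objects with residual branch points (clumps,
crossing animals) or loops (coiled animals) are rejected with reason
`"branched"`, sub-2-px skeletons with `"degenerate"`. Rejection, not
splitting, is deliberate: crowding then produces undercounting rather
than misclassification, which is the failure mode that preserves the
sex ratio.

Two numerical corrections make the midline metrologically honest:

* **Endpoint extension.** Thinning erodes the skeleton back from each
  worm tip by roughly the local half-width (worst at blunt male tails).
  Both path ends are therefore extended along their end tangents until
  they leave the mask. The extension lengths are retained on the
  skeleton (`end_offsets_um`).
* **Chord-corrected arc length.** Summing per-pixel steps (1
  orthogonal, √2 diagonal) overestimates oblique digital curves by up
  to ~8% (staircase bias). Arc length is instead accumulated over
  3-pixel chords, which is exact on straight orthogonal and diagonal
  runs and unbiased on oblique ones. `step_lengths` keeps the raw
  digital steps; `total_length_px` and `cumulative_um` use the chord
  parametrization. On 120 generator worms this puts length errors in
  [−2%, +3%] (digital steps alone: up to +8.7%).

Thickness is area/length. The diameter at arc position *s* from an end
is twice the Euclidean distance-transform value at the nearest skeleton
pixel, with no sub-pixel interpolation; probe positions are measured
from the *raw* thinning endpoints (not the tangent extensions), which
keeps constant-width shapes at ratio 1 and matches how a thinning-based
implementation naturally indexes its skeleton. The tail ratios probe
X1 = 20 µm and X2 = 120 µm from each end; the larger per-end ratio is
R2. Objects shorter than 2·X2 = 240 µm are rejected (`"too_short"`)
rather than probed with crossing windows. Diameter quantization is
±1 px; at 6.5 µm/px the 20-µm probe sees a ~2 px diameter, so
individual ratios carry large relative quantization noise (mean probe
error stays within 1 px across a 100-worm suite; ~8% of single probes
on curved worms exceed it). The ratio direction D(X1)/D(X2) makes
tapered tails small and blunt male tails large.

## Classification

Per-class sample means and unbiased covariances over
(length, thickness, r1, r2) are fitted from a labelled table requiring
all three classes with ≥ 5 records each; records are sorted before
fitting so the model is input-order independent. Covariances estimated
from a few dozen worms can be near-singular, so when the condition
number exceeds 10⁸ the smallest ridge from a doubling schedule
(starting at 10⁻¹² of the mean variance) is added to the diagonal.
Distances use a linear solve, not an explicit inverse. Assignment is
nearest class; exact ties break by the fixed order hermaphrodite >
male > larva and are flagged. Per-class (rather than pooled) covariance
is used: the three classes genuinely differ in spread (larvae span a
wide length range, adults do not). No distance-based reject option
exists; instead the margin (runner-up minus winner distance) ranks
calls for the manual-review export.

The male percentage is 100·males/(males+hermaphrodites): larvae are a
nuisance class, not part of the adult sex ratio, and the value is
reported missing when no adults were classified.

## Synthetic plates

A worm is a curvature-bounded random midline (persistent random turning
at 3 µm steps, smoothed, clipped to `curvature_per_um`, rescaled to the
sampled length) with a half-width profile: a body plateau joined to
per-end tapers that pass through the target diameters at 20 and 120 µm
of arc. Tips are capped at 5 µm half-width regardless of probe-position
bluntness — real tails come to a point, and blunt rendered caps would
extend the mask past the midline end and bias length truth. The mask is
rasterized by stamping discs along the midline (no anti-aliasing), so
the raster truth is exact. Default class recipes (engineering choices
reproducing the qualitative adult/male/larva ordering, not literature
measurements): hermaphrodites 900–1200 µm long, half-width 30–40 µm,
both ends tapered (D(X1)/D(X2) = 0.33); males 700–900 µm, 22–30 µm,
one blunt end (0.63); larvae 280–600 µm, 10–20 µm. A spec-set validator
enforces that the male blunt end is blunter than any hermaphrodite end.

Plates place worms uniformly at random. The spaced layout enforces
three worm-widths of clearance by rejection sampling; the crowded
layout lets bodies touch and cross but caps pairwise overlap at 15% of
the new body's area (solid bodies cannot coincide). Eggs are ~50×30 µm
ellipses — below the segmentation area floor unless touching a worm —
optionally glued to hermaphrodite body ends to reproduce the
egg-at-tail failure mode (the merged blob reads as a blunt tail and
inflates male calls). Debris are few-pixel specks. The background is
bright field (0.82 of full scale) with optional linear illumination
ramp and Gaussian sensor noise; one `default_rng(seed)` stream drives
everything, and the truth file records the seed.

The generator does **not** emulate bacterial-lawn texture, motion blur,
anti-aliased optics, or behavioural aggregation (real worms cluster
actively; synthetic crowding is geometric). Passing tests therefore
demonstrate correctness of the measurement chain under known geometry
and the stated confounders, not performance on any particular
microscope's images — for those, the classifier should be retrained
from a labelled table measured under the target imaging conditions,
which is the supported workflow (`train` on a features CSV).

The shipped 131-row training table (46 hermaphrodites / 46 males /
39 larvae, `data/training_synthetic.csv`) is synthetic: generated by
rendering single worms at seed 0 and measuring them with the package's
own morphometry. It mirrors the class structure of a typical labelled
training set and is regenerable with
`synth.generate_training_records`.

## Statistics layer

Strain tables print (male %, n); male counts are reconstructed by
nearest-integer rounding of pct·n/100 (the round-trip error is at most
half an animal). Each mutant is compared with the wild-type reference
by a Pearson chi-square on the 2×2 table male/non-male × strain,
df = 1, **without** continuity correction (with thousands of animals
per strain the correction is immaterial; a flag enables it), flagged at
raw p < 10⁻⁴ with no multiple-testing adjustment — the screen is
defined at that raw threshold. Agreement between counting methods is
the Pearson r of paired per-strain male percentages (computed over all
28 rows by default; excluding wild-type moves it by < 0.001) and the
maximum absolute discrepancy, reported at full precision and rounded to
two significant figures for display.

The per-well error analysis takes records of manual/automatic
male+hermaphrodite counts, drops wells with an undefined ratio on
either side, and reports: the manual-vs-automatic correlation of male
percentages, the share of wells with error below 10 points, the
error-vs-male-percentage correlation after excluding wells with fewer
than `min_animals` (default 10) manually counted animals, and the
error-vs-total-count correlation. Constant inputs (e.g. zero error
everywhere) yield NaN correlations rather than warnings. External
per-well tables load from CSV or XLSX through a configurable column
mapping; tests exercise the layer on a schema-identical synthetic well
set (binomial sexes, detection probability dropping from 0.95 to 0.75
above 150 animals/well).

## Experiment sizes and tolerances

Test-suite experiment sizes are chosen to make the checked properties
statistically meaningful at desk scale: 50-seed segmentation count
suite; 100-worm metrology and paired tail-ratio suites; 1,000-case
Mahalanobis oracle at 10⁻¹⁰ relative; 20 seeded 50/50 train/holdout
splits of a 170-worm labelled pool (hermaphrodite and male recall
≥ 0.85 in every split); 20 crowded plates of 200 animals on a 3200-px
(20.8 mm) canvas — about the worm-accessible area of one well of a
6-well plate. On crowded plates every seed undercounts (≈ 70% of
animals accepted) while the *mean* male-percentage deviation stays
within 3 points; per-seed deviations fluctuate by the binomial noise of
~140 accepted adults (sd ≈ 3.4 points), so the robustness claim is
about the absence of bias, not per-plate variance.

## Known limitations

* Crowded plates carry a small positive sex-ratio bias (~+2 points at
  200 animals/well): hermaphrodites, being larger, join clumps slightly
  more often than males, and crossing-distorted shapes are
  occasionally called male.
* Tail ratios are quantization-limited at 6–7 µm/px; a 90° rotation
  can move an individual ratio by up to ~0.2 while length and
  thickness stay within ~2%.
* Touching/coiled animals are rejected, never untangled; heavily
  crowded wells are undercounted by design.
* Body-size mutants (e.g. dumpy) and blistered animals will not match
  a wild-type-derived training table; retrain from matching labelled
  data.
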