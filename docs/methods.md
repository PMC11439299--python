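# Methods

## Scope and model

`nucyto` quantifies the subcellular distribution of a GFP-fusion protein in
transiently transfected adherent cells from two-channel epifluorescence /
confocal fields: a blue nuclear counterstain (Hoechst 33342 imaged on a
DAPI-like channel) and a green channel (FITC) carrying the fusion-protein
signal. Each cell receives one categorical call — NUCLEAR, CYTOPLASMIC,
BOTH, or UNLABELED (untransfected) — and inference runs on per-well
percentages of labeled cells, the plate well being the experimental unit.
Calls are categorical by design; no continuous nuclear-to-cytoplasmic
intensity ratio is computed, matching how such assays are scored by eye.

## Synthetic data generator

Because localization studies of this kind typically publish only summary
tables, the generator is the package's benchmark substrate. It emulates:

- **Field geometry.** 512×512 px, 16-bit, default 30 cells per field
  (cells-per-field at 40× is a free parameter; 30 gives the "tens of cells,
  sub-confluent" look of a 70–80% confluent well without touching cells).
  Cells are disks: a nucleus disk (radius uniform in 8–12 px) inside a cell
  disk (1.8× the nucleus radius). Dart-throwing placement enforces a centre
  separation of at least 2× the largest cell radius, so nuclei — and even
  whole cell regions — never overlap and the ground truth of every pixel is
  unambiguous. Overlapping nucleus specifications are rejected with an
  error rather than rendered.
- **Signal model.** Background 100 units per channel; nuclear stain
  1500–3000 units; GFP signal 1000–3000 units (10–30× background, a typical
  widefield dynamic range that keeps Otsu separation easy but not
  degenerate). Green signal placement follows the true class: nucleus disk
  only, cytoplasmic annulus only, whole cell disk, or absent. BOTH is
  rendered as uniform whole-cell signal. Noise: additive Gaussian read noise
  (SD 20) plus optional Poisson shot noise; values clipped to [0, 65535].
- **Experiment design.** Defaults mirror the assay layout the package
  models: four groups (wildtype construct, variant construct, a
  diffuse-GFP positive control dominated by whole-cell localization, and an
  untransfected negative control), 3 wells per group per experiment split
  2+1 across two plates, 2 independent experiments (6 wells/group), 15
  fields per well. Transfection rate defaults to 0.4 — a mid-range
  lipofection efficiency for an epithelial line; each cell is labeled
  i.i.d., so realized per-well class counts are multinomial draws from the
  group's class mixture.
- **Mixtures.** Treatment mixtures are (NUCLEAR, CYTOPLASMIC, BOTH)
  probabilities for labeled cells. Mixtures entered from rounded published
  percentages may sum slightly off 1 (e.g. 0.9989); sums within 0.02 of 1
  are renormalized exactly, anything further off is rejected.
- **Seeding.** Every field's seed is
  `SeedSequence([master_seed, experiment, treatment_index, well, field])`
  masked to 31 bits (treatments indexed in sorted-name order), so a single
  field is regenerable in isolation and whole experiments are
  byte-reproducible.

What the generator does *not* model: realistic cell shapes, touching or
dividing cells, z-structure, photobleaching, channel bleed-through, or
spatially varying illumination. Passing tests therefore demonstrate that
the pipeline implements its stated rules correctly and recovers known
ground truth under idealized geometry and noise — not that segmentation
would be error-free on dense or irregular real tissue.

## Segmentation

Global Otsu thresholding (the blue channel is strongly bimodal), closing
with a radius-2 disk, hole filling, connected components, and a minimum
area of 25% of a nominal nucleus (π·10² / 4 ≈ 79 px) applied to component
sizes after labeling. A distance-transform watershed split for touching
nuclei is available (`split_touching=True`) but off by default: default
synthetic fields have disjoint nuclei, and on real data the split should be
a deliberate choice since it can fragment irregular nuclei. A constant
(contrast-free) image yields an empty label map with a warning, not an
exception. Nuclei touching the image border are kept but flagged; the
classifier excludes them by default because their cytoplasm ring is
truncated, which would bias f_cyt downward.

## Classification

- **Cell regions.** Nuclei are expanded by `ring_width` px with nearest-
  nucleus (Voronoi) assignment of contested pixels. Default ring width is
  0.8× the median equivalent nucleus radius of the field — matching the
  synthetic cell bodies (cell radius = 1.8× nucleus radius); it is exposed
  in config because real cytoplasmic extent varies by cell type.
- **Green-positive pixels.** Background level and noise scale are the
  median and MAD-based robust SD of pixels outside all cell regions; a
  pixel is positive above `median + 3·SD`. Both statistics scale linearly
  with the data, making calls invariant to a global intensity rescaling.
  With no background pixels (confluent field) the rule falls back to a
  global Otsu threshold with a warning.
- **Thresholds.** τ_nuc = τ_cyt = 0.2: low enough to register a partially
  filled compartment, high enough to ignore rim bleed from slight nucleus
  over-segmentation (a 1-px rim on a 10-px nucleus is ≈0.17 of its area).
  "Both" is interpreted as *presence in both compartments*, the weaker of
  the two possible readings of whole-cell fluorescence; a strict-uniformity
  reading would need an intensity-homogeneity criterion that categorical
  visual scoring does not define.

## Statistics

Per well: `pct_class = 100 · n_class / n_labeled`; wells with zero labeled
cells are flagged and excluded with a warning. Per group: arithmetic mean
and SE (sample SD / √n) over wells; n ≥ 2 required. Between groups: a
two-tailed independent-samples t-test per class, pooled-variance Student t
by default (df = n₁ + n₂ − 2), Welch–Satterthwaite optionally; computed via
`scipy.stats.ttest_ind_from_stats` from (mean, SE, n) so the same routine
serves per-well data and published summary tables. Degenerate zero-variance
inputs return p = 1 (equal means) or p = 0 with a warning (unequal). With
6 wells per group, pooled and Welch tests round to the same two-decimal
p-values on the reference summaries, so the choice is inert there. The
fold-ratio effect size is larger mean / smaller mean, rounded half away
from zero to one decimal, as such ratios are conventionally quoted. No
multiple-testing correction is applied across the three classes — the
comparison report carries the three raw p-values, as is standard for this
assay's single pre-specified contrast.

The 6-wells-per-group default reads "triplicate wells across two plates in
two separate experiments" as 3 wells × 2 experiments pooled as independent
units; plate/experiment nesting is deliberately not modeled (no
mixed-effects layer), consistent with treating wells as exchangeable
replicates. Well count and test variant are configurable.

## Numerical and reporting choices

- Percentages per well always sum to 100 within rounding; p-values are
  carried at full precision internally and rounded half-away-from-zero to
  two decimals in reports, ratios to one decimal.
- All CSV output is UTF-8, comma-separated, with a header row; every CLI
  step writes a `run_config.json` capturing the resolved parameters.
- Field processing is order-invariant: per-cell records are canonically
  sorted by (experiment, plate, well, field, cell id).

## Problem sizes in the shipped checks

The test suite and the acceptance script regenerate everything they
measure: segmentation/classification error rates use 50 seeded
default-noise fields of 30 cells; the end-to-end recovery experiment uses
two groups × 6 wells × 15 fields of 30 cells (≈180 labeled cells per well
at transfection rate 0.4), which puts the Monte-Carlo SE of a recovered
group-mean percentage near 0.6–2 points depending on the class frequency;
the power check uses 500 replicate simulated experiments against the
analytic noncentral-t power. The reduced in-suite experiment (5 fields per
well) keeps the default test run fast while leaving ≈60 labeled cells per
well, ample for 3-SE recovery checks.

## Known limitations

- Disk geometry makes segmentation nearly error-free at default noise;
  reported precision/recall near 1.0 characterizes the pipeline's
  correctness, not its robustness to crowded or irregular real fields.
- The positive-pixel-fraction operationalization of the qualitative
  visual rule introduces two thresholds (τ, k·SD) that a purely visual
  protocol never states; both are exposed in config and echoed in output
  metadata so any re-analysis can vary them.
- Untransfected cells are detected only as absence of green signal; very
  dim transfectants below the 3-SD threshold are indistinguishable from
  untransfected cells and fall out of the denominator.
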