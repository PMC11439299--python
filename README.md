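# nucyto

Quantify where a GFP-fusion protein sits in transfected cells — nucleus,
cytoplasm, or both — from two-channel fluorescence microscopy, and test
whether two constructs distribute differently.

The package is aimed at cell-biology groups running transient-transfection
localization assays: cells expressing a GFP-tagged protein are counterstained
with a blue DNA dye (Hoechst 33342 / DAPI channel), fields are imaged per
plate well, and every cell is scored by where its green (FITC) signal lies
relative to the stained nucleus. Because such assays rarely deposit raw
images, `nucyto` also ships a seeded synthetic image generator with per-cell
ground truth, so the whole pipeline is testable and its error rates
measurable without real data.

## Method

1. **Nuclear segmentation** (blue channel): global Otsu threshold → binary
   closing → hole filling → minimum-area filter → connected components
   (optional distance-transform watershed for touching nuclei). The nuclear
   compartment of a cell is the area covered by the blue stain.
2. **Cell regions**: each nucleus is expanded outward by a ring width
   (default 0.8× the median nucleus radius), contested pixels going to the
   nearest nucleus (Voronoi partition); cytoplasm = expanded region minus
   nucleus.
3. **Per-cell call**: with f<sub>nuc</sub>, f<sub>cyt</sub> the fractions of
   green-positive pixels (intensity > background + 3 robust SD) in each
   compartment and thresholds τ<sub>nuc</sub> = τ<sub>cyt</sub> = 0.2,

   - BOTH if f<sub>nuc</sub> ≥ τ<sub>nuc</sub> and f<sub>cyt</sub> ≥ τ<sub>cyt</sub>
   - NUCLEAR if only f<sub>nuc</sub> ≥ τ<sub>nuc</sub>
   - CYTOPLASMIC if only f<sub>cyt</sub> ≥ τ<sub>cyt</sub>
   - UNLABELED otherwise (untransfected cell)

4. **Statistics**: the experimental unit is the plate well. Per well,
   percentages of labeled cells per class (UNLABELED cells enter neither
   numerator nor denominator); per treatment, mean ± SE over wells; between
   treatments, a two-tailed independent-samples t-test per class
   (pooled-variance Student t with df = n₁ + n₂ − 2 by default; Welch via
   `--welch`) and a fold-ratio effect size (larger mean / smaller mean,
   1 decimal).

## Worked example

Compare two constructs directly from published-style group summaries
(mean %, SE %, n wells per class):

```bash
nucyto compare --from-summary summary.csv --group-a WT --group-b RISK
```

where `summary.csv` holds one row per class and group
(`class,group,mean,se,n`). Output:

```
| Group | Nuclei labeled (%) | Cytoplasm labeled (%) | Nuclei and Cytoplasm labeled (%) |
|---|---|---|---|
| WT | 6.21 ± 2.31 | 45.12 ± 6.14 | 48.67 ± 7.46 |
| RISK | 3.86 ± 2.23 | 67.29 ± 6.61 | 28.74 ± 5.75 |
| p-value | 0.48 | 0.03 | 0.06 |
| ratio (larger/smaller) | 1.6 | 1.5 | 1.7 |

n = 6 wells (WT), 6 wells (RISK); two-tailed independent-samples t-test, df = 10, 10, 10.
```

Reading the table: the variant construct is found in the cytoplasm 1.5×
more often than wildtype (45.12% vs 67.29% of labeled cells, p = 0.03),
while whole-cell (nuclear *and* cytoplasmic) localization is 1.7× more
frequent for wildtype (48.67% vs 28.74%, p = 0.06); the nuclear-only
difference is not significant (p = 0.48).

A full in-silico run — generate a four-group experiment (2 experiments ×
3 wells over 2 plates × 15 fields/well), quantify every field, compare two
groups — is one command:

```bash
nucyto all --out run/ --seed 7 --group-a WT --group-b RISK
```

or stepwise: `nucyto simulate --design design.yaml --out images/`,
`nucyto quantify --in images/ --out quant/`,
`nucyto compare --wells quant/wells.csv --group-a WT --group-b RISK`.
Outputs are CSV (per-cell records, per-well summaries, comparisons), a
Markdown report, and a `run_config.json` provenance record per step.

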