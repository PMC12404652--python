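# endopheno

Quantitative analysis of punctate versus cytoplasmic protein localization in
fluorescence microscopy, with replicate-aware statistics, flow-cytometry
receptor-trafficking readouts, and protein sequence feature analyses.

## The problem

Many endosomal proteins shift between a diffuse cytoplasmic pool and bright
endosomal puncta, and the degree of that shift is the phenotype of interest
in structure-function studies: mutate a regulatory motif, image GFP-tagged
protein in cells, and ask whether the protein now accumulates on endosomes.
`endopheno` packages the analysis side of that workflow for cell biologists:

- **Signal-accumulation metric.** For each cell ROI, the maximal pixel
  intensity divided by the median pixel intensity of the tagged channel,

  `score = max(I_cell) / median(I_cell)`

  computed on raw pixels over the whole cell. A homogeneous cell (free GFP)
  scores exactly 1; a protein concentrated in puncta scores high. The ratio
  is invariant under multiplicative intensity scaling.
- **Phenotype classifier.** A deterministic surrogate for blinded scoring:
  each cell is called `cytoplasmic`, `distributed`, or `clustered`
  (punctate signal confined to three or fewer contiguous structures), from
  a median-relative threshold, an area filter, and connected-component
  counting after a small merging dilation.
- **SuperPlot statistics.** Cells are nested in biological replicates, so
  all tests (paired t, repeated-measures ANOVA with Dunnett or Tukey
  adjustment, unpaired Dunnett) consume replicate means only; cell-level
  values are kept for plotting. Significance bands: `*` p ≤ 0.05 through
  `****` p ≤ 0.0001.
- **Flow-cytometry trafficking.** Expression gating against a
  non-expressing control, geometric means of surface label per condition,
  and the assay estimators `internalization = 1 − Internalized/Total`,
  `recycling = (Recycled − Internalized)/(Total − Internalized)`.
- **Sequence features.** Disorder consensus across structure models,
  motif search, phospho-capable (S/T/Y) residue counting, triplet
  alanine-scan mutant generation, truncation construct arithmetic, and a
  modal-residue conservation profile.
- **Synthetic scenes.** A seeded generator producing microscopy fields
  (elliptical cells, log-normal expression, tunable punctate fraction,
  distributed or perinuclear-clustered arrangements, Poisson + Gaussian
  noise, a colocalized marker channel) and flow event tables with known
  ground truth, used to validate every estimator by recovery.

## Worked example

Simulate a two-construct experiment — a mostly cytoplasmic construct
(punctate fraction φ = 0.1) versus a strongly endosomal one (φ = 0.9),
three biological replicates of 30 cells each — then score, summarize and
compare:

```python
import pandas as pd
from endopheno import (SceneSpec, accumulation_score, compare,
                       fold_change, replicate_means, simulate_field)

rows = []
for construct, phi in (("FL", 0.1), ("mut", 0.9)):
    for rep in (1, 2, 3):
        spec = SceneSpec(n_cells=30, punctate_fraction={construct: phi},
                         replicate=rep, field_shape=(640, 640),
                         seed=100 + 10 * rep + (phi > 0.5))
        image, regions, _ = simulate_field(spec)
        rows.append(accumulation_score(image, regions))
scores = pd.concat(rows, ignore_index=True)
means = replicate_means(scores.rename(columns={"score": "value"}))
print(means)
print(compare(means, "paired_t_two_tailed").comparisons)
print(fold_change(means, "FL"))
```

Output:

```
construct  replicate       mean
       FL          1   4.679600
       FL          2   4.441255
       FL          3   4.325174
      mut          1 126.655963
      mut          2 127.421251
      mut          3 138.506985
group_a group_b  statistic    p_adj band
     FL     mut -32.305949 0.000957  ***
construct  fold_ratio_of_means  fold_mean_of_ratios
       FL             1.000000              1.00000
      mut            29.197036             29.25979
```

The per-replicate means of the accumulation score separate cleanly (≈4.5
for the diffuse construct versus ≈130 for the punctate one), the paired
two-tailed t-test on the three replicate means gives p ≈ 0.001 (`***`),
and the punctate construct scores ~29-fold above the reference. The same
cells can be phenotype-classified (`classify_all`) into
cytoplasmic/distributed/clustered calls with the structure counts that
produced them.

A shell workflow is available through the `endopheno` command
(`simulate-images`, `simulate-flow`, `score`, `classify`, `linescan`,
`stats`, `flow`, `seq`, `disorder`, `conservation`); see `endopheno --help`.

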