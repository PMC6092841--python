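# ycapture

Evaluation toolkit for **Y-chromosome capture-enrichment of ancient-DNA
sequencing libraries**.

Ancient-DNA libraries are typically dominated by environmental (microbial)
molecules: the endogenous fraction is often below 1%, and the Y chromosome —
present in one copy per male cell and rich in repeats — is the hardest
compartment to recover. Targeted hybridization capture (YCC, optionally after
whole-genome capture, WGC) can raise the yield of on-target Y reads by orders
of magnitude, but only when the starting library has enough complexity
(distinct template molecules) and endogenous content. This package implements
the full analytical layer needed to evaluate such experiments, together with a
truth-labeled simulator so every stage is testable without any sequence
download:

- **simulation** (`ycapture.synthio`) — finite template pools with
  endogenous/exogenous origins, truncated-normal fragment lengths,
  class- and length-dependent capture retention (logistic bias centered at
  the 105-bp probe length), sequencing by sampling with replacement so PCR
  duplicates arise from pool size alone, and genotype pileups over a
  haplogroup phylogeny;
- **accounting** (`ycapture.accounting`) — coordinate deduplication,
  ≥1-bp-overlap on-target classification against a BED target design,
  seeded down-sampling replicates at the per-individual minimum read count,
  per-library metrics with Wilson binomial confidence intervals, and a
  paired t-test for fragment-length shifts;
- **enrichment** (`ycapture.enrichment`) — fold-enrichment between
  conditions, `fold(c1, c2) = mean on-target(c1) / mean on-target(c2)`, with
  the zero-denominator convention (a zero baseline reports the numerator
  itself) and half-up one-decimal display rounding;
- **complexity** (`ycapture.complexity`) — library-size estimation from the
  duplicate-count histogram by a zero-truncated negative-binomial EM fit,
  `L = D / (1 - p0)` with expected yield `L (1 - (1 + tμ/r)^(-r))`, a linear
  fallback for duplicate-free libraries, histogram-bootstrap median/variance
  curves, and enrichment curves (ratios of yield-curve medians);
- **sex and haplogroups** (`ycapture.ychrom`) — the
  `Ry = n_Y / (n_X + n_Y)` statistic with its 0.075 male-consistency
  threshold, haploid genotype sampling (one random base per site, base
  quality ≥ 13), and most-derived-SNP haplogroup assignment on a rooted
  Y-SNP tree;
- **pipeline / CLI** (`ycapture.pipeline`, `ycapture` console script) —
  end-to-end orchestration with per-stage seeds and a manifest; subcommands
  `simulate`, `account`, `enrich`, `complexity`, `sex`, `haplogroup`, `run`.

## Worked example

Published-table arithmetic — a library with a down-sampled mean of 16,191
unique on-target reads after Y capture against a pre-capture baseline of 2.3:

```python
>>> from ycapture.enrichment import fold_enrichment
>>> fold_enrichment(16191.0, 2.3, display=True)
7039.6
>>> fold_enrichment(12.0, 0.0, display=True)   # zero-denominator rule
12.0
```

A full reduced-scale simulated experiment (two samples: one well-preserved at
1.54% endogenous, one poorly preserved at 0.03%):

```python
from ycapture import pipeline
config = pipeline.demo_config(seed=1, output_dir="demo_out")
report = pipeline.run_pipeline(config)
print(report["enrichment_table"][["sample", "condition_1", "condition_2",
                                  "on_target_mean_1", "on_target_mean_2",
                                  "fold_enrichment_display"]].to_string(index=False))
```

```
sample condition_1 condition_2  on_target_mean_1  on_target_mean_2  fold_enrichment_display
 SIM-A         YCC pre-capture             224.0              33.4                      6.7
 SIM-A         YCC         WGC             224.0              41.6                      5.4
 SIM-A         YCC     WGC+YCC             224.0              70.0                      3.2
 SIM-A         WGC pre-capture              41.6              33.4                      1.2
 SIM-A     WGC+YCC pre-capture              70.0              33.4                      2.1
 SIM-A     WGC+YCC         WGC              70.0              41.6                      1.7
 SIM-B         YCC pre-capture               1.0               0.0                      1.0
 SIM-B         YCC         WGC               1.0               0.0                      1.0
 SIM-B         YCC     WGC+YCC               1.0               0.0                      1.0
 SIM-B         WGC pre-capture               0.0               0.0                      0.0
 SIM-B     WGC+YCC pre-capture               0.0               0.0                      0.0
 SIM-B     WGC+YCC         WGC               0.0               0.0                      0.0
```

The rich library (SIM-A) is enriched ~7-fold by Y capture at this miniature
scale (fold magnitudes grow with pool size and target span; the dilution of a
real experiment is orders of magnitude larger). The poor library (SIM-B)
yields almost nothing under any condition — its YCC/pre-capture cell shows the
zero-denominator convention at work — and a second capture round costs
complexity (WGC+YCC vs YCC). Sex and haplogroup calls from the same run:

```
SIM-A Ry=0.711 consistent-with-XY
SIM-B Ry=0.500 indeterminate
SIM-A haplogroup: H3 via M2737
SIM-B haplogroup: H7 via M5717
```

`demo_out/` additionally contains the target BED, the haplogroup tree,
per-replicate metrics with Wilson CIs, bootstrap yield and enrichment curves
(TSV), and a manifest with every stage seed — rerunning with the same seed
reproduces every file byte for byte.

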