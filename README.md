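# nbselect

Population-genetic analysis of NBS-LRR disease-resistance genes in a
structured resequencing panel.

Plant NBS-LRR genes (nucleotide-binding site plus leucine-rich repeat) are
the largest family of disease-resistance genes in cereals. In a panel of
inbred genotypes spanning a domestication gradient — a wild/weedy group, a
landrace group and an improved group, plus an outgroup species — their
evolution leaves two opposite footprints: **purifying/directional selection**
(diversity stripped from the cultivated groups, elevated group
differentiation) and **balancing selection** (multiple alleles held at
intermediate frequency in ancestral and descendant populations).
`nbselect` implements the full scan that separates these regimes and the
comparative analyses around it:

* per-gene summary statistics: nucleotide diversity θπ, Watterson's θw,
  Tajima's D per group, and Hudson's F<sub>ST</sub> (1 − Hw/Hb) for the three
  group comparisons (wild vs landrace = domestication, landrace vs improved =
  improvement, wild vs improved = both);
* empirical-tail classification: purifying = θπ in the lower 5% tail of the
  derived group **and** F<sub>ST</sub> in the upper 5% tail of the matching
  comparison; balancing = θπ, θw in the upper 25% and D in the upper 5% in
  the ancestral group, diversity maintained in a cultivated group, and
  F<sub>ST</sub> below the 90th percentile everywhere;
* maximum-likelihood HKA validation: per-locus polymorphism
  S<sub>i</sub> ~ Pois(a₁·k<sub>i</sub>·θ<sub>i</sub>) and divergence
  D<sub>i</sub> ~ Pois(θ<sub>i</sub>(T+1)), selection parameters k tested by
  likelihood ratio (2ΔlnL ~ χ² with df = number of selected loci);
* codon-level analyses: large-effect variant classes (premature stop,
  start/stop loss, splice site, frameshift), protein-variant counts, NG86
  Ka/Ks with Jukes–Cantor correction, 4DTv duplicate dating
  (recent < 0.497), pseudogene and gene-loss calls from 100-bp read depth;
* gene families: 200-kb clusters, single-linkage families at 70% nucleotide
  identity and coverage, cross-species ancestry (sorghum/maize/rice),
  neighbor-joining trees of the conserved NBS domain;
* disease-QTL co-location: cM→bp projection over a framework marker map,
  QDR genome fraction, and χ² enrichment of NBS genes in QTL space.

A first-class synthetic-data module simulates the whole study — coalescent
haplotypes, bottlenecked cultivated groups, planted sweeps and balanced
polymorphisms, injected coding variants, clustered gene layouts, marker maps
and QTL — with known truth labels, so every stage is testable end to end
without any external download.

## Worked example

Run the full synthetic reproduction (simulate → stats → scan → families →
coding → QTL → report) from the shell:

```bash
nbselect run-all --seed 11 --out-dir work/
```

or from Python:

```python
from nbselect.pipeline import run_pipeline
from nbselect.synthetic_data import SimulationConfig

report = run_pipeline(SimulationConfig(seed=11), "work/")
```

With the default study conditions (208 genes: 10 swept, 10 balanced, 188
neutral incl. 4 pseudogenes and 4 novel genes; 44 ingroup genotypes + 2
outgroup samples) the report contains, among others:

```
selection_calls     {"balancing": 9, "neutral": 188, "purifying": 11}
confusion           {"purifying->purifying": 9, "balancing->balancing": 8,
                     "neutral->neutral": 185, ...}
hka (purifying)     lrt = 78.8, df = 10, p = 8.6e-13, mean k_hat = 0.52
hka (balancing)     lrt = 180.1, df = 8,  p = 9.6e-35, mean k_hat = 2.66
qdr_fraction        0.061
nonfunctional_range [0.022, 1.0]
```

Reading: 9 of the 10 planted sweeps and 8 of the 10 planted balanced genes
are recovered with 3 false positives among 188 neutral genes. The HKA fit
validates both candidate sets against 38 neutral loci: the swept candidates
carry *less* polymorphism than their divergence predicts (mean k̂ = 0.52 < 1),
the balanced candidates carry an excess (k̂ = 2.66 > 1), and both selection
models beat the neutral model decisively. About 6% of the synthetic genome
falls under projected disease QTL, and per-gene non-functional allele
frequencies span 2% to 100% (the planted pseudogenes).

Each stage can also be run on its own against the files of the previous
stage: `nbselect simulate|stats|scan|families|coding|qtl|report --out-dir work/`.

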