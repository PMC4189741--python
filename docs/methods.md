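# Methods

This note documents the statistical models, the rules and their boundary
behaviour, the synthetic-data generator, and the design choices made where
more than one defensible option existed. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Panel model and coordinates

The panel is haploid-coded: the genotypes are inbred lines, so homozygous
diploid calls collapse to a single allele and heterozygotes become missing
(`strict_het` turns them into errors instead; the right choice depends on
how a real panel was filtered upstream, which is why both modes exist).
All internal coordinates are 0-based half-open; VCF and GFF3 conventions
are converted at the I/O boundary. Multi-allelic records are rejected —
every statistic here is defined on biallelic sites.

## Summary statistics

* **θπ** — mean per-site pairwise difference within a group, computed with
  pairwise deletion: a site contributes only over the pairs with both calls
  present, and sites with fewer than two non-missing calls are removed from
  the accessible length. The estimate is per accessible site (window length
  minus skipped sites), so invariant positions count; this is the
  normalization that makes the neutral calibration E[θπ] = θ exact.
* **θw** — S / a₁ / L with a₁ = Σ_{i<n} 1/i.
* **Tajima's D** — (π_total − S/a₁) / √(e₁S + e₂S(S−1)) with the 1989
  variance constants computed from the group sample size; per-site allele
  counts use the non-missing calls. Undefined (NaN) when S = 0 or n < 4;
  undefined values are excluded from all empirical distributions.
* **F<sub>ST</sub>** — Hudson's ratio of sums 1 − ΣHw/ΣHb, where Hw averages
  the two groups' unbiased within-group pairwise diversities and Hb is the
  between-group pairwise diversity. With the unbiased within-group form the
  estimator is slightly negative (order −1/n) for identical populations and
  is bounded in [−0.5, 1]; it equals 1 only when within-group diversity is
  zero at every retained site. Hb = 0 returns 0. Weir–Cockerham could be
  swapped in behind the same interface.

**Empirical tails** use the nearest-rank quantile (upper tail fraction f:
threshold is the ⌈(1−f)·N⌉-th order statistic) with *strict* membership, so
a tail never exceeds its nominal size and massive ties yield an empty tail
rather than an inflated one. This is deliberately conservative for
enrichment arithmetic.

**χ² enrichment** is Pearson's statistic on the 2×2 table, 1 df, no Yates
correction, matching genome-scale contingency use; a zero expected cell
returns an undefined marker with a warning. The discrete test is mildly
anti-conservative at small counts (exact level up to ~0.06 at expected
cells of ~15), which is inherent to the statistic; its null calibration is
asserted in the regime where the χ² approximation holds.

## Selection classification

Tails are built from the full filtered gene set (all simulated genes), not
only NBS genes, mirroring genome-wide empirical distributions.

* **Purifying**: θπ in the lower 5% tail of the *derived* group of a
  comparison AND F<sub>ST</sub> in the upper 5% tail of that comparison.
  Fired comparisons map to phase: wild-vs-landrace → domestication,
  landrace-vs-improved → improvement, wild-vs-improved contributes both
  flags; both flags → phase "both".
* **Balancing**: θπ and θw in the upper 25% and D in the upper 5% of the
  *ancestral* (wild/weedy) group, θπ in the upper 25% of at least one
  cultivated group ("multiple alleles maintained in descendant
  populations"), and F<sub>ST</sub> strictly below the 90th percentile in
  all three comparisons. The group scope is a design decision: bottlenecked
  cultivated groups have genome-wide inflated D, so the intermediate-
  frequency signature is informative in the ancestral group, while
  maintenance in descendants is expressed through their diversity tail and
  the non-extreme differentiation. The rule is a pure function of the tail
  sets — gene order never changes a call.

Purifying is checked first; a gene that satisfies neither rule is neutral.
Genes with missing statistics are never promoted to a selection call.

## Maximum-likelihood HKA

Per locus i: S_i ~ Poisson(a₁·k_i·θ_i), D_i ~ Poisson(θ_i(T+1)); k_i ≡ 1
for neutral loci and for all loci under the neutral model, free k_i > 0
(clamped to [10⁻³, 10³]) for selected loci under the selection model. Given
T and k, the per-locus θ̂ = (S+D)/(a₁k+T+1) is closed form, and for a
selected locus k̂(T) = S(T+1)/(a₁D); the remaining one-dimensional profile
likelihood in T is maximized on a 60-point log grid refined by bounded
Brent. Because the selection model's profile dominates the neutral one
pointwise in T, lnL_sel ≥ lnL_neut holds structurally, and
LRT = 2ΔlnL ~ χ²(#selected). Divergence counts for the pipeline are fixed
differences between the ingroup majority consensus and the outgroup over
the gene, excluding sites missing in the outgroup. D = 0 at a selected
locus drives k̂ to its upper bound rather than infinity; S = 0 to the lower
bound. The original program's MCMC is replaced by this profile ML — a
deliberate substitution that preserves the LRT structure.

## Codon-level analyses

Effects are computed on the strand-corrected CDS with the standard nuclear
code. Large-effect classes: premature stop (alternate codon is a stop
before the terminal codon), start loss (annotated initiator ATG changed),
stop loss (terminal stop to sense), splice site (the 2-bp intron edges),
and frameshift (CDS indel with length ≢ 0 mod 3). Indels with length ≡ 0
mod 3 are in-frame; everything outside CDS and splice edges is noncoding.

**NG86 Ka/Ks.** Site counting excludes stop-creating point changes from the
mutational opportunity: each codon position contributes one site split by
the synonymous fraction of its non-stop alternatives. Multi-difference
codons are averaged over all substitution pathways with equal weight,
pathways through stop codons excluded (if all are blocked, stop steps count
as nonsynonymous). pS and pN get the Jukes–Cantor correction, undefined at
p ≥ 3/4 — note a single saturated codon pair is therefore undefined by
construction. The neutral simulator used in calibration draws mutations
uniformly over exactly this opportunity space, making the ω = 1 check a
genuine consistency test; calibration pairs are long (1500 codons, 400
substitutions per lineage) because the plug-in ratio's Jensen bias is of
order 1/S_d and does not average out over replicates. The record carries a
method tag so an HKY-based variant could be added alongside.

**4DTv** is the uncorrected transversion fraction at third positions whose
codon is fourfold-degenerate in both sequences; a pair is flagged a recent
duplicate below 0.497.

**Protein variants** are distinct translated CDS haplotypes obtained by
applying each sample's substitution alleles; samples missing any coding
call are excluded, and samples carrying CDS indels are the subject of the
functional-status path instead (a frameshifted "protein" is not a variant
count, it is a non-functional allele).

**Functional status / pseudogenes / gene loss.** A sample's allele is
non-functional iff it carries a large-effect or frameshift alternate allele
or has lost > 50% of the gene. Gene loss is called from 100-bp depth bins:
lost when the fraction of bins with depth < 2 strictly exceeds 0.5 (both
thresholds configurable; there is no canonical cutoff for depth-based loss
calls, so the defaults mirror the > 50%-of-gene deletion rule). Exactly 50% low
bins is not lost. A pseudogene is a gene whose every non-missing sample is
non-functional; an all-missing gene is undefined, not False.

## Families, clusters, trees

Clusters chain genes whose consecutive midpoints lie within 200 kb
(midpoints are robust to gene-length variation; start-to-start or gap rules
are a parameter away). Families are single-linkage components over edges
with identity ≥ 0.70 AND coverage ≥ 0.70 from a global end-gap-free DNA
alignment (match +1, mismatch −1, gap open −2, extend −0.5; identity =
matches over aligned columns excluding end gaps, coverage = aligned span
over the longer sequence — the conservative denominator that keeps
fragments from inflating families). In the pipeline an alignment-score
prefilter (score < 0.07·min length) skips the traceback for pairs that
cannot mathematically reach the 70/70 threshold. Ancestry: all three
species in a clade → ancestral; two → cross-species; one →
species-specific (one reading of "ancestral", recorded in the outputs).

Neighbor joining is Saitou–Nei with Q-matrix ties broken on the lowest
current index pair and negative branch lengths clamped to zero with the
deficit moved to the sister branch; on additive matrices reconstruction is
exact (topology and branch lengths), which the tests verify against random
trees and against an independent implementation. Tree distances for the
pipeline are p-distances (1 − identity) on the conserved NBS-domain region,
whose coordinates come from the annotation input.

## QTL projection and co-location

QTL spans in cM are projected to bp by linear interpolation between
framework markers, extrapolated from the terminal marker pair outside the
map and clamped to [0, chromosome length]. Markers violating joint cM/bp
monotonicity are dropped with a warning, never reordered. Point QTL are
expanded by ±1 cM by default. Overlap is half-open; the QDR fraction is the
union of projected intervals over the genome, with the fractions covered by
≥ 2 QTL and ≥ 2 traits computed by a sweep line. Enrichment of a gene set
in QTL space is the Pearson χ² on the in-set × in-QTL table.

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (config, seed); every stage's inputs
are written in the standard formats the readers consume.

* **Neutral genes.** A founder pool of haplotypes is drawn from a
  single-locus Kingman coalescent with infinite-sites mutation (time in
  units of 2N, mutation rate θ/2 per site, mutations placed on branches
  proportionally to length). The wild group takes pool haplotypes directly
  and is therefore exactly calibrated: E[θπ] = E[θw] = θ (default 0.005),
  E[D] ≈ 0. Landrace and improved groups resample restricted founder
  subsets (7 and 4 founders, nested) — domestication and improvement
  bottlenecks that lower cultivated diversity while sharing polymorphism
  with the wild group, giving moderate neutral F<sub>ST</sub>.
* **Purifying genes.** The swept group(s) (both cultivated groups for
  domestication-phase genes, improved only for improvement-phase) are fixed
  for one founder haplotype carrying additional post-sweep substitutions
  (0.006/site) — the drift that elevates Hb and hence F<sub>ST</sub> — plus
  rare private mutations at sweep_factor·θ (default 0.1·θ), which skews the
  AFS to singletons. A sweep factor of 1.0 disables the sweep entirely, so
  the class is then statistically identical to neutral.
* **Balancing genes.** Two haplotype classes, each its own small coalescent
  (0.3·θ within class), separated by fixed differences at 0.025/site, both
  classes near 50% in every group. This realizes elevated θπ/θw, strongly
  positive D and low F<sub>ST</sub> without simulating frequency-dependent
  dynamics. Class divergence and within-class θ were fixed by a design
  calculation so the planted classes express the signature the classifier's
  rules test for; they were frozen before the recovery tests were written.
* **Hitchhiking.** Off by default (swept genes are laid out in isolation).
  With flank_sweep_factor < 1, neutral genes within 100 kb of a swept gene
  share the sweep's diversity collapse (without its drift substitutions);
  the footprint is physical distance, matching the 100-kb flank analysis.
* **Coding variants, depth, presence.** Large-effect and frameshift
  variants are injected at configured per-gene rates with rare-skewed
  carrier frequencies (carriers restricted to the wild group for swept
  genes, preserving the planted signature); pseudogene-class genes carry a
  frameshift fixed across the panel; novel genes get group-structured
  presence patterns realized as zero-depth bins.
* **Families and species.** NBS genes sharing a cluster share a family
  ancestor CDS (5% within-family divergence); a configurable number of
  maize/rice orthologs (10% divergence) realize ancestral and cross-species
  clades.
* **Markers and QTL.** Monotone random marker maps (40/chromosome over
  150 cM); 30 QTL of ±0.15–0.4 cM centered on genes with 95% bias toward
  NBS genes. These widths were set so that planted enrichment exists as a
  detectable signal rather than saturating the gene-occupied genome.

What the generator does **not** emulate: recombination within genes (each
gene is one genealogy), gene conversion between paralogs, linkage between
genes beyond the shared layout, sequencing error, annotation error, or
realistic depth covariates (GC, mappability). Passing recovery tests
therefore demonstrate the correctness and calibration of the estimators and
rules under the model's assumptions — not performance on real resequencing
data, where window choice, filtering and missingness structure dominate.

## Problem sizes and numerical choices

The default synthetic genome is 208 genes (180 neutral + 10 purifying + 10
balancing + 4 pseudogene + 4 novel) on five 30-Mb chromosomes, with a
44-genotype ingroup (14 wild, 15 landrace, 15 improved) plus 2 outgroup
samples, gene length 1.5 kb and CDS 900 bp — sizes chosen so a full
pipeline run, the 20-seed classifier recovery and the 200-replicate
calibrations all execute in minutes on one CPU while keeping per-gene
variant counts (~30 segregating sites) in the regime where the estimators
are informative. HKA calibration uses 20 loci at per-locus θ in [2, 10] and
T = 5, so Poisson means are large enough for the χ² asymptotics of the LRT.
Optimization tolerances: T profile refined to 1e-10; nesting guarded at
1e-6; NJ exactness asserted at 1e-9; estimator-oracle agreement at 1e-10.
Degenerate inputs (empty windows, zero divergence, all-missing samples,
zero fourfold sites, empty strata) yield undefined markers (NaN/None), and
undefined values are excluded from tails and enrichment rather than being
coerced to zero.
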