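# Methods

## Problem setting

`allotrack` implements a clonal-tracking analysis for alloreactivity
studies built on three data layers from one patient: (i) a mixed-lymphocyte
reaction (MLR) profiled by paired single-cell RNA/TCR sequencing, which
defines candidate alloreactive clones as the expanded, proliferating
clonotypes; (ii) bulk TCRβ repertoires (immunoSEQ-style template counts)
from blood over time and from tissue biopsies, in which those clones are
tracked; and (iii) paired single-cell RNA/TCR data from blood, in which the
circulating phenotype of tracked clones is read out against precomputed
cluster labels. Clustering, embedding and batch correction are upstream of
this package: cluster labels are inputs.

## Clonotype model and cross-platform matching

A chain's identity is (chain, V gene, J gene, CDR3 nt, CDR3 aa) with gene
names normalized to IMGT spelling and allele suffixes stripped; Adaptive
spellings (`TCRBV05-01*01`) are converted by a rule-based normalizer with a
packaged exception table for orphons. A cell's clonotype is its resolved
(α, β) pair; cells with more than one contig per chain keep the
highest-UMI contig (ties: reads, then lexicographic CDR3 nt). Matching a
single-cell clone into a bulk TCRβ repertoire uses the beta chain under a
configurable key:

- `nt` / `nt+vj` — CDR3 nucleotide (± V/J concordance), for
  within-platform tracking;
- `aa` / `aa+vj` — CDR3 amino acid (± V/J), for cross-platform matching.

The default is `aa+vj`: nucleotide reporting windows differ between 10x
and immunoSEQ, while CDR3 aa plus allele-stripped V/J is stable across
both. Matched frequency sums all matching productive bulk rows. A clone
"found" in a bulk sample means ≥ 1 productive template matches; presence
calls use no frequency floor.

All repertoire frequencies are productive-template frequencies:
nonproductive rows are retained in tables but excluded from numerator and
denominator alike.

## Repertoire statistics

- **Inverse Simpson diversity** D = 1/Σp², the effective number of equally
  abundant clones. Computed on productive frequencies without rarefaction.
- **Morisita-Horn overlap** over the union of clone keys,
  MH = 2Σxᵢyᵢ / ((d_x + d_y)·X·Y) with d = Σcᵢ²/C². Bounded [0, 1],
  symmetric, 1 iff compositions are identical.
- **Fold expansion** is the frequency ratio source/reference; a zero count
  is replaced by a pseudocount (default 0.5) before forming the frequency,
  denominators unchanged. The direction is an explicit argument — the
  pipeline reports MLR/blood.
- **Clone dynamics** between two samples classifies each clone detected in
  at least one of them:
  - *emerged*: zero reference templates and ≥ `min_detect` (default 2)
    in the later sample — the detection floor suppresses singleton
    artifacts;
  - *absent*: zero reference templates and fewer than `min_detect` later
    templates (seen in neither sample at a trustworthy level);
  - *expanded* / *contracted*: two-sided Fisher's exact test on
    [(k₁, N₁−k₁), (k₂, N₂−k₂)], Benjamini-Hochberg corrected across all
    clones of the comparison, q < α (default 0.05) **and** fold ≥
    threshold (default 2) or ≤ 1/threshold;
  - *stable*: everything else.

  The Fisher test is computed via the conditional hypergeometric
  distribution, vectorized by grouping tables with identical margins, and
  follows the standard two-sided convention (sum of outcomes with
  probability ≤ observed, with 1+1e-7 relative tie tolerance). It agrees
  with an exact integer-enumeration oracle to < 1e-10 on every 2×2 table
  with row margins ≤ 50, and with `scipy.stats.fisher_exact` on random
  larger tables. The explicit test + BH procedure is this package's
  choice; a descriptive emerged/contracted call needs no test, but the
  screen over ~10³–10⁵ clones does.

## Single-cell scoring

QC retains cells with mitochondrial fraction < `mito_max` and feature
count strictly above `features_min` (and below `features_max` when set).
Defaults follow the 25% / 200-feature convention for MLR-like data and
15% / 200–5000 for larger blood datasets; for the synthetic bundle the
feature floor is 50 because the simulated gene panel has only ~250 genes.
Normalization scales each cell to 10,000 counts and applies log1p.

Module scores come in two modes. `mean` (default) is the arithmetic mean
of normalized expression over the signature genes present in the matrix
(absent genes are dropped with a warning). `bin_control` subtracts the
mean of expression-matched control genes: genes are ranked by average
expression and cut into 24 equal-occupancy bins; 25 control genes per
signature gene are drawn (seeded) from the signature gene's bin. The two
modes are both exposed because "average expression" descriptions of
module scoring in the literature often refer to implementations that in
fact subtract binned controls; on a constant matrix `bin_control` scores
are exactly 0.

Cell-cycle phase uses bin-control S and G2/M scores: S if s > g2m and
s > 0; G2M if g2m ≥ s and g2m > 0 (the tie resolves to G2M,
deterministically); else G1.

Cluster markers are one-vs-rest Wilcoxon rank-sum tests
(`scipy.stats.mannwhitneyu`, asymptotic, tie-corrected) with Seurat-style
filters applied before testing: log fold-change
ln(mean expm1 in + 1) − ln(mean expm1 out + 1) > 0.25 and detection in
≥ 20% of the tested cluster; BH correction is applied within cluster over
the tested genes. Clusters under 3 cells are skipped.

## Tracking and phenotype integration

The tracking matrix is clone × sample (columns ordered by compartment,
then timepoint) over the union of the labeled clone sets plus any bulk
clone above a frequency floor (default 0.001, to keep outputs
desk-sized). Cluster distributions of matched clones are computed per
timepoint with proportions normalized within group × timepoint, alongside
a found-count (how many set clones appear in ≥ 1 cell). Emerged-vs-stable
phenotype comparison tests each cluster's cell counts
(emerged vs stable × in-cluster vs out) by Fisher's exact test with BH
across clusters — a cell-level statistic mirroring proportion bar plots
while making the comparison explicit.

## Synthetic study generator

The generator emulates the statistical structure of the study, not its
biology:

- **Clone abundances**: log-normal (σ = 2.0) for 980 background clones —
  a standard heavy-tail repertoire model. 15 viral-like clones are scaled
  20× (large, stable public-virus-type clones present everywhere).
  20 alloreactive clones are drawn from a narrower log-normal (σ = 0.5,
  unscaled, i.e. ~7× below the background mean): rare but detectable
  circulating memory clones. Rarity matters twice — it reproduces the
  study's premise (alloreactive clones near the detection floor in
  blood), and it keeps the alloreactive share of the MLR modest so the
  frequency-ratio fold estimator is diluted by less than 2× (a 50-fold
  expansion of a subset mechanically shrinks every other clone's relative
  frequency; the estimator is biased low by exactly that dilution).
- **Compartments**: blood pre/post timepoints share one abundance vector
  (alloreactive clones absent pre-treatment, present ×3 post); kidney
  shares 50% of background clones with blood and carries alloreactive
  clones at ×10; tumor-containing lymph node and skin share 30% and carry
  none. Dropped background clones are replaced by compartment-private
  clones so tissues are not blood subsets. Template counts are
  multinomial draws at 10⁵ (blood/MLR) or 3×10⁴ (tissues).
- **MLR**: the post-treatment blood counts with alloreactive weights
  multiplied by `allo_fold` = 50 before multinomial resampling.
- **Single cells**: cells are drawn from the repertoire's clone
  distribution; each cell's cluster follows its clone's class
  (alloreactive → proliferating cluster in the MLR, 70%/30%
  ZNF683-like/proliferating in blood; viral-like → cytotoxic/CTL;
  background → resting clusters). Expression is negative-binomial with
  dispersion α = 0.5 (var = μ + αμ², NB size 1/α) and multiplicative
  cluster-program shifts (effect 4.0, i.e. programs at 5× baseline);
  cycling cells additionally express their phase program, which is
  disjoint from the cluster programs so phase is identifiable.
  Mitochondrial fractions are Beta(2, 12) per cell with MT- gene means
  scaled to hit the target in expectation; 3% of cells are emitted at
  ~1% depth so the QC feature floor has true positives. TCRs are captured
  for 90% of cells; 10% of captured cells get a decoy extra chain with
  strictly lower UMIs. Bulk files use Adaptive gene spellings, contigs
  IMGT, so the bundle exercises the name normalizer end to end.
- **Determinism**: every random stream is `default_rng([seed, h])` with
  `h` a SHA-256-derived constant per (operation, sample) — outputs are a
  pure function of the seed, byte for byte, and independent of call
  order.

What the generator does *not* emulate: V(D)J recombination statistics and
generation probabilities, sequencing error, ambient RNA, doublet
transcriptomes, batch effects, and any real covariance between programs.
Passing recovery tests therefore demonstrates the pipeline's correctness
against a known truth under realistic marginal distributions — not
performance on real data.

## Numerical and design choices

- Problem sizes in tests and the acceptance script: 10⁵-template bulk
  samples, 1000-clone universes, 1500 MLR + 4000 blood cells — the
  generator's default study scale.
- Zero-count fold changes use pseudocount 0.5 on the zero side only.
- Clone IDs are content hashes (SHA-1 of canonical chain keys), stable
  across runs and platforms.
- `classify_dynamics` drops clones with zero counts in both samples (no
  signal); its BH family is all remaining clones of the comparison.
- Bulk parsing aggregates duplicate (CDR3 nt, V, J) rows by summing
  templates and sorts canonically, so parsing is row-order independent.
- The run log records package and library versions and the full
  configuration, but no timestamps — reruns are byte-identical.

## Known limitations

- The Adaptive→IMGT normalizer covers regular names plus a small orphon
  exception table; exotic ambiguous calls pass through allele-stripped.
- `wilcoxon_markers` densifies the matrix; it targets panel-sized
  matrices (10²–10⁴ genes), not genome-wide sparse data.
- The emerged/stable enrichment treats cells as independent, ignoring
  clone-level correlation; with few large clones its p-values are
  anti-conservative, which is why the pipeline reports the per-clone
  distributions alongside the test.
- Diversity is not depth-rarefied; compare samples at similar depth or
  downsample first.
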