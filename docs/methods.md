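# Methods

## Problem and overall design

The package asks whether the co-expression structure of a transcriptome
— which genes vary together across individuals — differs between sexes
and age groups, using six stratified networks of identical size as the
unit of comparison.  The pipeline is: gene filtering → quantile
normalization → six-way split → per-stratum mutual-information network →
cross-network comparison → bootstrap connectivity nulls → gene-set
over-representation.  Filtering and normalization happen on the full
cohort *before* splitting, so all six networks live on one shared gene
universe and differences between them cannot be artifacts of different
gene panels.

## Synthetic cohort generator

`coexpnet.simulate` emulates a sex- and age-stratified bulk RNA-seq
cohort.  Defaults follow the motivating design: six strata with sample
sizes F: 39/134/87 and M: 93/245/205 (803 samples).

Generative model, per stratum s:

- Gene baselines: log m_g ~ Uniform(log 50, log 2000), shared across
  strata (one transcriptome).
- Library size: ℓ_j ~ LogNormal(0, σ), σ = `libsize_sigma` (default
  0.2), per sample.
- Modules: disjoint blocks of genes.  A module is either active in one
  stratum or in all strata (`stratum_specific_fraction` controls the
  mix; specific modules are assigned round-robin FY, FM, …).  For each
  active module m and sample j, a latent factor z_mj ~ N(0,1) shifts the
  log-mean of every member gene by β·z_mj (β = `beta`, default 1.5).
- Counts: NB(mean μ_gj = ℓ_j·exp(log m_g + β·z_mj), size = `dispersion`,
  default 10), drawn as a gamma–Poisson mixture, so
  Var = μ + μ²/dispersion.

All randomness flows from one root seed through SHA-256-keyed
`SeedSequence` streams (per stratum, per module), so adding a stratum
never perturbs another stratum's draws, and identical configs are
byte-identical.

What the generator does *not* emulate: batch effects, cell-type
composition shifts, hub-and-spoke regulatory topology, correlated
module overlap, or any realistic marginal distribution of a specific
tissue.  Passing tests on this generator demonstrate that the pipeline
recovers planted dependence structure under NB noise — not that it
would recover any particular biology from real data.  Note one
deliberate consequence of the library-size factor: ℓ_j is shared by all
genes of a sample, so *every* gene pair is weakly positively dependent
when σ > 0; "independence by construction" holds only at σ = 0, and the
background-independence checks are run there.

## Preprocessing

- Gene filters (both evaluated on the same input matrix): mean count ≥
  10 across all samples, and zero counts in at most 50% of samples.
  The conjunction is order-independent and idempotent.
- Quantile normalization: the reference distribution is the across-
  column mean of sorted columns; each column's values are replaced by
  reference values at their ranks.  Tied values receive the mean of the
  reference values at their tied rank positions, which makes the result
  independent of sort stability.  Consequence: for tie-free columns
  every column's sorted values equal the reference exactly; columns with
  ties deviate from the reference exactly at tie blocks (the averaging
  is the tie rule, not an error).  A single column is returned
  unchanged.
- Age-bracket mapping: decade brackets map Y ← {20-29, 30-39},
  M ← {40-49, 50-59}, E ← {60-69, 70-79}, overridable per run — the
  upper bound of "elderly" is a cohort-definition choice, not something
  the code can infer.

## MI estimator

Plug-in (maximum-likelihood) mutual information over a joint histogram
of equal-frequency bin assignments, in nats.  Binning: average ranks cut
into `n_bins` equal-width rank intervals (`floor((rank−1)·B/n)`); a tie
group shares one average rank and therefore always lands in a single
bin — ties that would span a boundary go to the lower bin.  A constant
vector occupies one bin and yields MI = 0.  Because binning depends only
on ranks, MI is invariant under strictly monotone transforms of either
input.

The `auto` bin count is floor(√n) clamped to [2, 20] and additionally to
n/4, so every bin can hold at least four samples; calls that cannot
satisfy that floor raise rather than return an unstable estimate.
Absolute MI values depend on this estimator choice; only the edge
*ranking* feeds downstream, and rankings are far more stable across
estimator variants than values.

`mi_matrix` computes all pairs exactly (one BLAS product per gene row
over one-hot bin encodings); it is O(G²·n·B²) time and is meant for
desk-scale gene panels (hundreds to a few thousand genes), not the full
transcriptome on the original study's scale.

## DPI pruning and top-k

DPI with mark-then-sweep semantics: every triple is evaluated against
the *input* table and removals applied afterwards, so the result is
independent of gene enumeration order.  Edge (i,j) is removed iff some k
has MI(i,j) < min(MI(i,k), MI(j,k))·(1−ε); ties survive (strict
inequality).  Default ε = 0.

Top-k retains the k largest surviving entries; ties at the cutoff break
by canonical (lexicographic) pair order, making edgelists reproducible
bit-for-bit.  Networks are stored and written as canonical unordered
pairs (gene_a < gene_b) with MI weights, sorted by descending weight.

A structural caveat that drives two choices elsewhere: under the
single-latent-factor module model all within-module edges have
near-equal MI, so each is "indirect" relative to two slightly stronger
neighbours and strict DPI removes most of a planted clique.  The
parameter-recovery benchmark therefore measures the MI ranking with DPI
disabled, and the `analysis/` protocol uses ε = 0.2, which spares edges
within 20% of the strongest alternative path and preserves planted
cliques (measured module recall ≈ 0.94–1.0 at ε = 0.2 vs ≈ 0.18 at
ε = 0) while still pruning weakly supported triangles.  On real data,
where co-expression is not literally one shared factor per module, the
appropriate ε is an empirical choice.

## Network comparison

Edge identity everywhere is the unordered gene pair; weights are
ignored in comparisons (a conserved edge keeps the minimum weight
across inputs, as the weakest observation of the interaction).
Gene-mode overlap uses endpoint genes of the size-matched networks, not
the full universe.  Component statistics come from union-find (tested
against networkx); genes are edge endpoints by construction, so there
are no isolated nodes and an empty network has zero components.

## Connectivity null model

For a unique subnetwork with E edges and observed LCC size L, the null
draws E edges uniformly without replacement from the parent stratum
network (with replacement available behind a flag), computes the LCC
gene count per draw, and reports both empirical tails with the add-one
rule p = (#extreme + 1)/(n_sims + 1), which never returns exactly zero.
Both tails are always reported; "larger/smaller than chance" is a
presentation decision downstream.  Default n_sims = 100,000; the
analysis drivers use 10,000, which resolves p down to 10⁻⁴ —
calibration (p-values of null-drawn observations vs uniform) is
checked by KS distance in the tests and the acceptance script.

## Over-representation

Hypergeometric upper tail P(X ≥ k) with parameters (N = |universe|,
K = |term ∩ universe|, n = |query|, k = |term ∩ query|); BH-FDR across
all tested terms; significance at adjusted p < 0.05 (strict).  The
universe is the filtered gene set (the genes that could have appeared in
any network), not the whole annotation; query genes outside it are
dropped with a warning.  Gene sets come from standard GMT files; gene
symbols are upper-cased on parse.  No annotation database is bundled —
term-level results are only comparable within one library version.

## Analysis-scale choices

The numbered drivers and the acceptance script run at: 600 genes,
twelve 15-gene modules (six stratum-specific, six shared), β = 1.5,
k = 1,000, ε = 0.2, 10,000 null replicates.  k is chosen (a) below the
DPI-surviving edge count of every stratum so all six networks are truly
size-matched, and (b) small relative to the gene universe so unique
subnetworks stay sparse enough for the hypergeometric test to
discriminate — at 1,000 edges over 300 genes, a unique subnetwork
touches nearly every gene and enrichment is uninformative by
construction.  These sizes are the package's desk-scale protocol; all
operations accept larger inputs.

## Known limitations

- O(G²) MI computation: no sparse pre-filtering or multicore fan-out.
- The plug-in MI estimator is positively biased at small n; the bias is
  shared across pairs of equal sample size and so mostly cancels in
  rankings, but MI values should not be compared across strata of
  different size.
- The null model resamples edges, not degree sequences; it answers "is
  this subnetwork more connected than a random same-size edge subset",
  not "than a random subgraph with the same degrees".
- Enrichment is a plain hypergeometric ORA; no ontology-aware
  redundancy reduction, no ranked (GSEA-style) statistics.
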