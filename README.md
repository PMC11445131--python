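# coexpnet

Sex- and age-stratified gene co-expression network analysis of bulk
RNA-seq, built around skeletal-muscle aging as the motivating system.
Skeletal muscle is postmitotic, which makes it a natural tissue for
asking how the *functional organization* of the transcriptome — not just
expression levels — changes with age, and whether it changes differently
in men and women.

The package takes a raw gene × sample count matrix plus per-sample sex
and age attributes (real data in GTEx-style TSV/GCT format, or a
built-in synthetic cohort with planted co-expression modules) and runs:

1. **Preprocessing** — remove genes with mean count < 10 or zeros in
   more than half the samples; quantile-normalize all samples onto one
   reference distribution; split into six strata
   (sex ∈ {F, M} × age group ∈ {Young 20–39, Middle 40–59, Elderly 60+}).
2. **Network inference** — for each stratum, plug-in mutual information
   I(X;Y) = Σᵢⱼ pᵢⱼ ln(pᵢⱼ / pᵢ·p·ⱼ) over equal-frequency (quantile) bin
   assignments for every gene pair; Data Processing Inequality pruning
   (in each triangle, remove edge (i,j) if
   MI(i,j) < min(MI(i,k), MI(j,k))·(1−ε)); retain the k strongest edges
   so the six networks are size-matched.
3. **Comparison** — pairwise shared-edge/shared-gene counts and Jaccard
   matrices; interactions conserved within men, within women, and across
   all six networks; each stratum's unique-interaction subnetwork and
   its connected-component statistics.
4. **Connectivity null model** — is a unique subnetwork's largest
   connected component (LCC) bigger than expected by chance?  Draw
   random edge subsets of matched size from the parent network, compute
   the null LCC distribution, and report add-one empirical tail
   probabilities p = (#extreme + 1)/(n_sims + 1).
5. **Over-representation** — hypergeometric upper-tail test of each
   subnetwork's genes against a user-supplied GMT gene-set library with
   Benjamini–Hochberg FDR, plus UpSet-style accounting of which terms
   are significant in which networks.

## Worked example

The `analysis/` scripts run the whole protocol on a synthetic cohort
that mirrors the muscle study design — 803 samples
(F: 39/134/87, M: 93/245/205 across the three age groups), 600 genes,
twelve planted 15-gene modules (six active in a single stratum, six in
all) — with networks size-matched at k = 1,000 edges:

```bash
cd analysis
python 01_simulate.py --seed 1
python 02_preprocess.py
python 03_infer_networks.py
python 04_compare_networks.py
python 05_null_models.py --seed 1
python 06_enrichment.py
```

Selected output (seed 1):

```
conserved interactions: men=628, women=568, all=567
network  unique_edges  unique_genes  lcc_genes  n_components
     FY           426           394        205            59
     FM           367           359         93            82
...
FY: observed LCC 205 vs null 129.2 +/- 25.5 (larger than chance; p_ge=0.0001, p_le=1)
...
FY: 394 unique-subnetwork genes; 1 module(s) over-represented at FDR<0.05: MODULE_00 (q=0.02)
FM: 359 unique-subnetwork genes; 1 module(s) over-represented at FDR<0.05: MODULE_01 (q=0.0048)
```

Reading this: the six 1,000-edge networks share a conserved core of 567
interactions (the planted shared modules), each stratum's
unique-interaction subnetwork over-represents exactly the module planted
specifically in that stratum, and the young-female unique subnetwork is
substantially more connected than a random same-size edge subset of its
parent network (empirical p ≈ 10⁻⁴).

The same stages are available as a CLI
(`coexpnet simulate|preprocess|infer|compare|unique|nulltest|enrich|run-all`)
for real count matrices; `coexpnet run-all --config run.yaml` executes
every stage from one YAML file and writes a manifest with a SHA-256
checksum per output, so identical configs give verifiably byte-identical
runs.

## Layout

- `src/coexpnet/` — the library: `simulate`, `preprocess`, `inference`,
  `networks`, `compare`, `nullmodel`, `enrich`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite, including oracle-based acceptance tests.
- `docs/methods.md` — model, estimator and design notes.
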