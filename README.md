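# seedgcn

Seed-gene co-expression network analysis for case/control expression
cohorts.

Many cancer transcriptomics studies ask what a single gene of interest — the
*seed*, for example the glycolytic enzyme ALDOA in non-small-cell lung
cancer — is doing at the network level: which differentially expressed genes
co-vary with it inside tumors, whether those genes form densely
interconnected modules with a coherent function (such as the cell cycle),
which of them are topological hubs, whether the association survives
adjustment for an obvious confounder (glycolytic flux, proxied by HK2 or
PKM), and whether the resulting signature stratifies patients by outcome.
`seedgcn` implements that whole chain as a tested, reusable pipeline, plus a
synthetic-cohort generator so every stage can be validated without any
external download.

## The analysis chain

Given a normalized log2 expression matrix (genes × samples) with
case/control labels:

1. **Differential expression** — per-gene empirical-Bayes moderated t:
   residual variances s²_g (d_g = n − 2 df) are shrunk toward a prior
   (d₀, s₀²) estimated by moments matching on log s²_g,
   s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), t = logFC / (s̃_g √(1/n₁ + 1/n₂))
   on d₀ + d_g df; Benjamini–Hochberg adjustment; DEGs have adjusted
   p < 0.05 and |FC| > 1.5.
2. **Seed association** — Pearson correlation of every DEG with the seed
   over case samples only; significant genes (p < 0.05) split into
   positively and negatively correlated sets; the positive set feeds the
   network.
3. **Co-expression network (GCN)** — undirected graph connecting gene pairs
   with Pearson r ≥ r_min (default 0.7) in cases; degree and unnormalized
   Brandes betweenness; hubs = (top-k by degree) ∩ (top-k by betweenness),
   tie-closed, k = 10.
4. **Cohesive clusters** — greedy growth of node groups maximizing
   f(V) = w_in/(w_in + w_bound + 2|V|), overlap merging
   (|A∩B|²/(|A||B|) > 0.8), filters: size ≥ 3, density ≥ 0.5, and a paired
   one-sided rank test (internal vs boundary incident weight per member)
   at p < 0.05.
5. **Enrichment** — hypergeometric over-representation of each cluster
   against a user-supplied GMT collection, Bonferroni-corrected.
6. **Partial correlation** — first-order
   r_p = (r_xy − r_xz r_yz)/√((1−r²_xz)(1−r²_yz)) between seed and hub
   genes given a confounder gene z, with t = r_p √(n−3)/√(1−r²_p).
7. **Classification** — agglomerative clustering of samples on the
   hubs-plus-seed signature, cut into two classes, confusion against the
   true labels.
8. **Survival** — median high/low dichotomization, Kaplan–Meier curves with
   Greenwood variance, log-rank tests, the combined high/high (HH) marker
   group, and fixed-horizon (3- and 5-year) overall-survival Z-tests
   z = (Ŝ_A(h) − Ŝ_B(h))/√(V̂_A + V̂_B).

The synthetic generator plants all of this structure explicitly: a
seed-correlated factor module, a confounder pathway whose genes associate
with the seed only through a "glycolysis-like" latent driver, per-gene case
shifts, decoy gene sets, and exponential survival whose hazard follows the
signature score. See `docs/methods.md` for the model and parameter choices.

## Worked example

Run the full pipeline on a freshly generated synthetic cohort (90 cases, 60
controls, 500 genes, 20-gene planted module):

```bash
seedgcn simulate --seed 1 --out cohort/
seedgcn run-all --config cohort_config.yaml --synthetic --out run1/
```

or from Python:

```python
from seedgcn.pipeline import recovery_config, run_synthetic
report = run_synthetic(recovery_config(rng_seed=1, out_dir="run1"))
print(report["stages"])
```

A seed-1 run prints stage counts like:

```
differential_expression  n_degs=60  (45 up, 15 down)
seed_association         n_positive=29
network                  n_nodes=29  n_edges=226
clustering               n_clusters=2  sizes=[20, 9]
hubs                     n_hubs=17
enrichment               top term of cluster 1 = TERM_MODULE (Bonferroni p ~ 2e-34)
classification           misclassification 31.3%
survival                 HH-vs-others log-rank p = 0.0015; 5-yr OS gap 0.21
```

Reading: the 60 DEGs are the planted signal genes (20 module + 8
confounder-mediated + seed + confounder readout + 30 background shifts); 29
of them correlate positively with the seed in cases; the largest detected
cluster is exactly the planted 20-gene module and its planted gene-set term
ranks first; the confounder-mediated genes form the second, smaller
cluster; and patients high on both the seed and the top hub gene have
significantly worse survival, as built into the generator.

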