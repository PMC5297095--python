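# Methods

This note documents the statistical machinery behind each pipeline stage,
the synthetic cohort the test suite runs against, and the design choices
made where the procedure was genuinely open. Nothing here states an
empirical result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Differential expression: moderated t

Each gene is a two-group comparison on the log2 scale. With n₁ case and n₀
control samples, logFC is the difference of group means, and the pooled
residual variance s²_g has d_g = n₁ + n₀ − 2 degrees of freedom. An
inverse-chi-square prior (d₀, s₀²) is estimated once from the whole gene
ensemble by moments matching on z_g = log s²_g: after removing the known
chi-square bias (digamma/log terms), the mean of z identifies s₀² and the
excess of its variance over trigamma(d_g/2) identifies trigamma(d₀/2),
inverted by Newton iteration. A non-positive excess means the observed
variances are no more dispersed than sampling noise alone, and d₀ = +∞
(every posterior variance collapses to s₀²). The posterior variance is the
degrees-of-freedom-weighted blend s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g),
and the moderated t uses d₀ + d_g degrees of freedom. Two degenerate limits
are testable and tested: d₀ = 0 recovers the classical pooled t exactly,
and d₀ → ∞ makes all posterior variances equal s₀².

Genes with zero variance in both groups keep t = 0, p = 1 when their logFC
is 0, and otherwise fall back to the prior variance rather than being
dropped silently. Only the two-group design is supported — no covariates,
matching the contrasts the pipeline is built for.

DEG calling is the joint rule: Benjamini–Hochberg adjusted p < α (default
0.05) and |logFC| > log2(fc_min) with fc_min = 1.5, i.e. the fold-change
cut lives on the linear scale.

## Seed association and the network

The screen correlates every DEG with the seed gene over **case samples
only** — the co-expression of interest is the within-tumor program, and the
suite verifies that permuting control samples cannot change the result. The
significance cut applies to the raw correlation p by default; a config
switch (`aa_use_adjusted`) moves it to the BH-adjusted p, since either
convention is defensible. Only the positively correlated significant genes
become network candidates.

Edges connect candidate pairs with Pearson r ≥ r_min in cases, ties at the
threshold included; candidates with no qualifying partner are dropped, so
the graph has no isolated nodes. Topology is unweighted — correlations are
kept as edge metadata only — so degree is an edge count and betweenness is
the standard Brandes accumulation over unweighted shortest paths with
fractional credit across equal-length alternatives, each unordered pair
counted once (the suite checks it against exhaustive path enumeration in
exact rational arithmetic on all graphs up to 12 nodes). Hub genes are the
intersection of the top-k lists by degree and by betweenness, both closed
under ties at the k-th rank so the result is order-independent; k defaults
to 10 and is configurable.

## Cohesive clusters

Cluster detection greedily maximizes the cohesiveness objective
f(V) = w_in/(w_in + w_bound + p|V|) with penalty p = 2 (unit weights by
default; a flag switches to correlation weights). Growth starts from each
uncovered vertex in decreasing-degree order, considers adding any external
neighbour or removing any member except the original seed, applies the
single best strictly improving move (ties: additions before removals, then
smallest gene id), and stops at a local maximum. Grown groups whose overlap
score |A∩B|²/(|A||B|) exceeds 0.8 are merged transitively. Survivors must
have ≥ 3 members, internal density ≥ 0.5 and a quality p < 0.05.

The quality test pairs each member vertex's internal incident weight with
its boundary incident weight and applies a one-sided exact Wilcoxon
signed-rank test for internal dominance. The paired form matters: an
unpaired rank-sum comparison of the pooled weight lists reaches nominal
significance (p = 1/70) for any four vertices of a detached path, so sparse
noise graphs would routinely yield "significant" clusters; with pairing,
the minimum achievable p at four vertices is 1/16, and on Erdős–Rényi noise
(n = 50, p = 0.05) the detector reports nothing in ≥ 95 of 100 seeded
replicates while isolated cliques of six or more remain clearly
significant. A consequence worth knowing: at α = 0.05 no cluster of fewer
than five members can pass the quality filter.

## Enrichment

Per cluster and term, the upper hypergeometric tail P[X ≥ overlap] with the
background fixed to the genes of the analysed matrix (the screen's actual
universe, not the genome), Bonferroni-multiplied by the number of terms
tested. The EASE-style (count − 1) deflation is available behind a flag but
off by default. Gene sets come from standard GMT files.

## Partial correlation

First-order partial correlation with one conditioning gene at a time,
r_p = (r_xy − r_xz r_yz)/√((1−r²_xz)(1−r²_yz)), two-sided p from
t = r_p√(n−3)/√(1−r²_p). The suite checks the formula against the
residual-regression identity (correlation of OLS residuals after projecting
on {1, z}) to 10⁻¹⁰. "Association retained" means p < 0.05 on the partial
p. Simultaneous multi-confounder adjustment is deliberately out of scope;
the sample sizes involved make plain sample correlations adequate.

## Classification

Samples are clustered on the hubs-plus-seed signature after per-gene
z-scoring (toggleable), with average linkage on correlation distance by
default (complete/single and euclidean available), and the dendrogram is
cut at its root into two classes. Class 1 is the control-majority class
(larger class on ties); the misclassification count is the number of
samples whose label differs from their class majority. Two caveats are
documented rather than hidden: correlation distance sees profile *shapes*,
so a shift that is uniform across the signature genes is invisible to it
after z-scoring; and a root cut of an agglomerative tree is unstable when
the group separation is comparable to the noise — on the default synthetic
cohort (shift-to-noise around 2.7 per gene over ~10 genes) expect
misclassification in the 25–40% range, while strongly separated cohorts
classify perfectly.

## Survival

Median dichotomization uses a strict rule — "high" is expression strictly
above the median, values equal to the median go to "low" — because the
behaviour of exact-median values must be pinned down somewhere. The
Kaplan–Meier estimator uses the product-limit form with censoring ties at
an event time counted at risk; the variance is Greenwood's
V̂(t) = Ŝ(t)²·Σ d_i/(n_i(n_i−d_i)), with V̂ reported as 0 once Ŝ reaches 0.
Two-group comparisons use the standard log-rank test. The fixed-horizon
comparison of overall-survival rates (3 and 5 years by default) is
z = (Ŝ_A(h) − Ŝ_B(h))/√(V̂_A(h) + V̂_B(h)) with a two-sided normal p; the
Greenwood variance at the horizon is the conventional choice for this test
and is stated as a choice, since log-transformed or binomial variances are
also seen in practice. The combined marker group "HH" contains patients
above the median on both the seed and a partner hub gene; everyone else is
"others".

## The synthetic cohort

A two-factor Gaussian model on the log2 scale. Per sample, two independent
standard-normal latent factors: f (the co-expression module driver) and h
(a confounder pathway, "glycolysis-like"). Gene values are
baseline + δ_g·[case] + loading·factor + ε with ε ~ N(0, σ²):

| component | count | loading | driven by |
|---|---|---|---|
| seed gene | 1 | 0.9 on f, 0.5 on h | both factors |
| module genes | 20 | U[0.6, 0.9] on f | module factor |
| confounder readout | 1 | 2.0 on h | confounder factor |
| confounder-mediated genes | 8 | 0.8 on h | confounder factor only |
| background DE genes | 30 | — | noise (shifted) |
| background genes | rest of 500 | — | noise |

with σ = 0.7 and 90 cases vs 60 controls. Case shifts δ_g are drawn per
gene from U[0.8, 3.0] log2 (the magnitude range typical of top cancer vs
normal fold-change tables); the seed's shift is pinned at the range
midpoint so the anchor of the whole analysis never sits on the filter
boundary by draw. Shifts vary per gene deliberately: identical shifts would
leave case and control profile shapes identical, which both misrepresents
real cohorts and blinds correlation-distance clustering structurally.

The factor construction makes ground truth exact rather than approximate:
two module genes with loadings a, b have population correlation
ab/√((a²+σ²)(b²+σ²)) (verified against sample correlations at large n); the
confounder-mediated genes correlate with the seed marginally (through h)
but have true partial correlation 0 given h, so conditioning on the
noisy confounder readout should — and in tests does — dissolve their
significance while module genes keep theirs. The readout's high loading
(2.0) keeps residual confounding after conditioning on a *measured* proxy
small; with a weaker readout the partial correlation would only shrink, not
vanish, which is a property of proxy adjustment, not of the estimator.
Survival times are exponential with hazard 0.15·exp(β·z) per year, z the
z-scored mean expression of seed plus module genes, β = 1 by default, under
independent uniform censoring on [0, 10] years.

What the generator does not emulate: array-specific artifacts (probe
saturation, batch effects, normalization quirks), heavy-tailed or
heteroscedastic noise, correlated censoring, and any overlap structure
between the module and the confounder pathway. Passing tests therefore
demonstrate correctness of the machinery under a clean factor model, not
robustness to the messiness of real cohorts.

## Recovery analysis settings

The pipeline's default edge threshold r_min = 0.7 is meant for strongly
co-expressed real modules. Under the generator's conditions the *maximum*
attainable population correlation between module genes is
0.81/(0.81+0.49) ≈ 0.62, so a 0.7 threshold cannot form any planted edge;
the recovery configuration (`recovery_config`) instead uses r_min = 0.3,
chosen between the null sampling tail at n = 90 (sd ≈ 0.11, so a null pair
needs ~2.8 sd to cross) and roughly one sampling sd below the weakest
planted correlation (≈ 0.42). With that setting the module subgraph
saturates, the planted module is recovered as the largest cluster and the
highest-loading gene carries the highest degree mass.

## Problem sizes and determinism

All simulations are seeded (`numpy.random.default_rng`); the same spec and
seed reproduce a cohort bit for bit. The test suite's Monte-Carlo sizes —
2000 null genes for moderated-t calibration, 10 000 null pairs for the
correlation screen, 1000 replicates for log-rank and fixed-horizon Z-test
calibration, 100 replicates for noise-graph and survival-direction
properties, 10 replicates of the full pipeline for module recovery — were
chosen to keep each check's Monte-Carlo error comfortably inside its
asserted interval while the whole suite stays in the tens of seconds.
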