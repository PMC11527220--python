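# Methods

`netgen` implements a network-based systems-genetics workflow for
prioritizing disease risk genes from GWAS and molecular-QTL evidence and for
screening repurposable drugs, with downstream validation on longitudinal
patient records. This note documents the models, the defaults, and the
choices made where the design was genuinely open.

## Interactome

The substrate of all network computation is an undirected, unweighted graph
over gene symbols. Loading upper-cases and strips symbols, drops self-loops,
and collapses duplicate or reversed pairs; no alias resolution is attempted
(aliasing is the caller's job). All downstream stages operate on the largest
connected component (LCC), so shortest paths and degree-based permutation
nulls are always defined. Node order is lexicographic everywhere, which
makes adjacency matrices, trained weights and scores reproducible across
runs independent of input row order.

The graph convolution uses the symmetrically normalized adjacency
`Â = D^(-1/2) A D^(-1/2)`. On a k-regular graph this reduces to `A/k`.

## GWAS-xQTL mapping

Variants are filtered at a suggestive-significance threshold (default
`p < 1e-5`, strict inequality; configurable). LD clumping is greedy by
ascending p: the best remaining SNP becomes a lead and removes same-chromosome
SNPs within a 1 Mb window with `r² > 0.1`; proxies of a lead require
`r² > 0.8`, strict. LD is consumed as a pairwise table (computing LD from
reference genotypes is out of scope); a missing pair reads as `r² = 0`.

SNP-linked QTLs (eQTL, pQTL, sQTL) join to GWAS variants on rsID. Interval
QTLs (methylation, histone acetylation) are assigned to the nearest
protein-coding gene body on the same chromosome: distance is the gap between
the interval and the gene body (0 when overlapping), ties break
lexicographically by symbol and are logged. GWAS/QTL positions are 1-based
inclusive; BED inputs are 0-based half-open and converted at read time.
Strand is ignored. When several GWAS studies are concatenated a SNP keeps
its minimum p.

## Module learning

The model partitions the interactome into functional modules. Each layer
aggregates neighborhood orders 0–2:

    H(i+1) = ReLU( Σ_{j=0..2} Â^j H(i) W_j(i) )

with depth L = 2 — one layer already reaches second-order neighbors, and in
triangle-rich interaction networks higher orders are largely redundant with
the first two. A jumping-knowledge concatenation `H̄ = H(1) ‖ H(2)` lets
each node draw on both neighborhood radii. Module membership is a softmax
head on `H̄`.

Because no labels exist, training is self-supervised with

    loss = − soft-modularity(P, A) + λ · BCE(σ(z_u · z_v), A_uv)

where P are the soft memberships, the modularity term is
`(1/2m)[tr(PᵀAP) − ‖dᵀP‖²/2m]`, and the reconstruction term scores a linear
embedding head on equal samples of edges and non-edges each epoch
(λ = 1 by default). Both terms are computable from the graph alone and both
push representations toward community structure.

The network is implemented in numpy with hand-written backpropagation and an
Adam optimizer; a finite-difference check in the test suite guards the
gradients. Input features are one-hot node identities up to 512 nodes, and a
Gaussian random projection to width 128 above that. Defaults: hidden width
32, embedding width 16, learning rate 1e-3, 200 epochs, 512 edge samples per
epoch. All randomness — initialization and edge sampling — flows from the
single seed argument, so a run is bit-reproducible. The module count K is a
config value (2–8 on fixtures; on a real interactome it should be chosen by
the best soft modularity over a small grid such as {50, 100, 200}).

## Risk scoring

A gene's raw score aggregates module-level evidence concentration:

    score(g) = Σ_m P(g∈m) · e(m),   e(m) = Σ_{v∈evidence} P(v∈m) / Σ_v P(v∈m)

so genes in modules where QTL-regulated evidence genes concentrate score
high. This is our operationalization of "functional similarity to the
evidence genes through shared modules"; it is invariant to module
relabeling and reduces to simple membership counting for hard partitions.

Per-seed scores are min-max scaled to [0,1] (no seed dominates), averaged
across seeds, and standardized to a Z across genes using the population
standard deviation (so the Z column has mean 0, sd exactly 1). Risk genes
are called at Z ≥ 1.645 (one-sided 5%) by default, or by a fixed top-n.
AUROC against a benchmark set is the rank-sum form, ties counting one half;
benchmark genes outside the scored universe are dropped with a logged count.
The disease module is the induced subgraph of risk genes with self-loops and
isolated nodes removed.

## Expression specificity and enrichment

Tissue specificity of gene i in tissue t standardizes expression across
tissues: `z_it = (E_it − Ē_i)/σ_i`, then clamps negatives to zero —
"specific" means above the gene's own cross-tissue average. The standard
deviation uses ddof = 1 (sample sd; configurable), constant genes get z = 0
with a log line, and the pre-clamp values are retained for diagnostics.
"Highly expressed" means strictly positive post-clamp. The input matrix is
expected to be per-tissue means already. The statistic is invariant to
adding a constant to a gene's row and to positive scaling.

Gene-set enrichment is a one-sided (greater) Fisher exact test with the
interactome gene universe as the background; Benjamini–Hochberg q-values are
available for families of tests.

## Drug proximity

Proximity of a drug target set T to disease proteins S is the closest
distance `d(S,T) = (1/|T|) Σ_{t∈T} min_{s∈S} sp(s,t)`, unweighted shortest
paths in the LCC. Significance is a Z-score against distances of
degree-matched random (S,T) pairs: both sets are permuted (the established
proximity methodology; T-only permutation is switchable), which deflates
the bias toward well-studied hub proteins. Degree bins sweep degrees in
ascending order and close once they hold at least 20 nodes; on graphs
smaller than one bin this degrades gracefully to uniform subset sampling.
Sampling within a draw is without replacement; an exhausted bin widens to
the nearest unused degree.

Defaults: 1,000 permutations; `Z = (d−μ)/σ` from the sample moments;
one-sided normal p from Z (used for screening, because the screening rule
couples Z and p) plus an empirical `p = (1+#{d_perm ≤ d_obs})/(n_perm+1)`.
The screen keeps approved drugs with Z < −3 and p < 0.05, ranked by
ascending Z. Per-drug RNG substreams derive from the master seed by stable
hashing, so a library screen is reproducible under any evaluation order.
For graphs up to 3,000 nodes an all-pairs distance matrix is cached;
larger graphs fall back to per-call multi-source BFS.

## Trial emulation

Longitudinal patient tables (patients, coded diagnoses, prescriptions) are
structured into emulated target trials per candidate drug:

- **Eligibility**: at least one index-disease code, age ≥ 50 at the first
  such code, no exclusion diagnosis strictly before it; missing birth dates
  exclude the patient and are counted.
- **Dates**: initiation = first disease code minus six months (182 days, for
  determinism), absorbing diagnostic latency; index = first prescription of
  the drug; requires index after initiation and first outcome strictly after
  index. Baseline window = [initiation, index).
- **Cohorts**: treated = exposed to the tested drug; controls = exposed to a
  same-ATC-level-3 comparator (first four ATC characters) but not the tested
  drug; dual-exposed patients count as treated (configurable; the
  first-exposure alternative would split them). Drugs under 100 users are
  skipped (threshold configurable; fixture-scale runs use 20).
- **Covariates**: binary comorbidity flags (ICD prefixes in the baseline
  window), binary medication flags, male sex, age at index, days from
  initiation to index; absent evidence codes to 0.
- **Matching**: ridge-penalized logistic propensity model on standardized
  covariates; greedy 1:1 nearest-neighbor matching without replacement on
  the logit-propensity scale with a 0.2-sd caliper (the usual choice);
  balance requires at most 2% of covariates with SMD > 0.2, where SMD =
  |mean₁−mean₀|/√((v₁+v₀)/2) on the matched sample. IPTW weights are
  computed and exportable, but the default estimator runs on the matched
  sample — matching is what constructs the control group; the exact division
  of labor between weighting and matching is ambiguous in the published
  description and is flagged here as a design decision.
- **Estimation**: Cox proportional hazards with treatment as the sole
  covariate; follow-up from index to first outcome or last recorded
  encounter. The 95% CI is a percentile interval over patient-level
  bootstrap resamples (default 1,000; reduced on fixture-scale runs);
  whether the published analysis bootstrapped patients or whole trials is
  not recoverable, and patient-level is implemented.
- **Replication**: 100 emulations per drug by default, each re-subsampling
  80% of the control pool under a seed-derived substream; drugs with fewer
  than 10 balanced trials are excluded; the reported effect is the median
  hazard ratio over balanced trials, with CI endpoints the medians of the
  per-trial bootstrap endpoints.

A caveat on interpretation: with heterogeneous baseline hazards the marginal
hazard ratio from a two-group Cox fit is attenuated toward 1 relative to the
conditional (covariate-specific) ratio even under perfect balance
(non-collapsibility), so recovery of a planted conditional HR of 0.5 lands
near 0.54 rather than exactly 0.5.

## Synthetic fixtures

Every input format has a generator that is a pure function of (spec, master
seed); substreams derive by stable hashing of the fixture name, so
regenerating one fixture never perturbs another.

- **Interactome**: planted-partition graph (default 2 blocks of 30,
  p_in = 0.3, p_out = 0.01), patch-connected if fragmented, with labels for
  recovery checks. Risk-scoring demonstrations use 5 blocks of 30 so the
  evidence module is a minority of the scored universe — with only two
  equal modules, ties within the non-evidence half bound AUROC near 0.83
  regardless of recovery quality.
- **Genetics**: evidence genes drawn from one module receive eQTL links from
  genome-wide-significant SNPs placed in their (synthetic, tiled) gene
  bodies; some gain pQTL/sQTL links and overlapping methylation/acetylation
  peaks; clumpable LD partners, strong-LD proxies, and non-significant decoy
  SNPs give the filters real work.
- **Expression**: lognormal-ish baseline TPM with the planted genes elevated
  by 3 noise-sd in one target tissue; other tissues exchangeable.
- **Drugs**: one planted drug targets the evidence genes' direct
  neighborhood; the rest draw targets uniformly; a quarter are unapproved.
- **Cohort**: 8,000 patients, ~25% treated. Four measured binary confounders
  (prevalence 0.35) raise both treatment odds (log-odds 1.0 each) and the
  outcome hazard (log-hazard 0.7 each), so the naive hazard ratio is biased
  toward the null while the matched pipeline can recover the planted effect.
  Event times are exponential (baseline 0.25/year, treated hazard multiplied
  by the true HR), censoring exponential (0.15/year) truncated at 8 years;
  confounders are recorded as baseline-window diagnoses so the covariate
  extractor can see them. Planted eligibility violations (age < 50, prior
  exclusion diagnosis) must all be rejected.

What the fixtures do **not** emulate: realistic LD structure, real ICD
ontologies and code hierarchies, realistic TPM distributions, measurement
error in diagnosis dates, unmeasured confounding, or treatment
non-adherence. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted signal under the stated generative
model — not performance on real consortium data.

## Numerical choices and problem sizes

Training uses float64 throughout; softmax is computed with max-subtraction;
BCE uses the logits-stable form. Fixture problem sizes (60–300 node graphs,
8,000-patient cohorts, 12 trial replicates, 60-resample bootstraps,
100-draw null calibrations at 300–500 permutations) were chosen so the
whole suite runs in minutes on a single CPU while leaving each statistical
check adequately powered; all are configurable upward.

## Known limitations

- The self-supervised loss is our concrete choice for an objective the
  antecedent framework leaves unspecified; other graph-clustering losses
  would be defensible.
- The evidence-concentration score is one operationalization of
  "module-mediated similarity to evidence genes"; alternatives (e.g.
  diffusion from evidence seeds) are not implemented.
- Proximity screening on very large interactomes falls back to per-call
  BFS, which is correct but slow for thousand-drug libraries.
- The emulation estimator targets the marginal hazard ratio of the matched
  population; see the non-collapsibility caveat above.
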