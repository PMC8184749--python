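# Methods notes

This note documents the models, defaults and numerical choices behind
`netban`, and what the synthetic studies do and do not establish.

## Pipeline model

The pipeline treats causal-gene nomination as a conjunction of three kinds of
evidence for a gene at a GWAS locus:

1. **network centrality to known biology** — the gene's local Bayesian-network
   neighborhood is enriched for curated bone genes (a BAN);
2. **genomic proximity** — the gene lies within 1 Mbp of a GWAS lead SNP;
3. **shared genetic regulation** — the gene's eQTL colocalizes with the GWAS
   association (PPH4 ≥ 0.75).

Each stage is deliberately modular: expression filtering and adjustment,
module detection, per-module structure learning, neighborhood enrichment,
colocalization, and locus integration are separate library functions with
file-level interfaces, so any stage can be swapped or run on real data.

## Preprocessing

Counts are filtered twice: an expression filter (more than 6 reads **and**
more than 0.1 TPM in more than 20% of samples; all inequalities strict) and a
network filter (drop genes with fewer than 10 reads in more than 90% of
samples, and genes off autosomes/X). Normalization is `log2(CPM + 1)`
followed by per-gene ordinary-least-squares residualization of the nuisance
covariates (batch) with protected covariates (sex, age) retained. This
replaces a variance-stabilizing transform plus empirical-Bayes batch
correction with a closed-form, deterministic equivalent at first order;
correlation-based networks are insensitive to the difference in variance
stabilization, which is the only property used downstream. The adjustment is
exactly idempotent and raises a named error when an adjustment covariate is
confounded with a protected one (the batch design must be crossed, not
nested).

## Module detection

Signed adjacency with power β = 4 (5 for the male-network preset), standard
topological overlap, average-linkage clustering of `1 − TOM`. Two published
parameters are kept verbatim: minimum module size 30 and eigengene merge
height 0.15 (modules merge while any eigengene pair has `1 − cor < 0.15`,
closest pair first; the module count strictly decreases so merging
terminates).

The dendrogram cut is a static height. The default height is chosen by a
plateau rule: scan the merge heights and cut at the center of the height
interval that maximizes the number of clusters meeting the minimum size. Low
cuts fragment modules below the size threshold and high cuts fuse modules
with noise genes, so the count of size-qualified clusters peaks on a plateau
between the within-module merges and the late merges; homogeneous data
degenerate to a single module. A fixed fraction of the maximum merge height
(e.g. 0.99) was evaluated first and discarded: on planted five-module data
with unclustered background genes it cuts inside the noise-merge continuum
and absorbs background genes into modules (adjusted Rand index 0.23–0.46
versus ≥ 0.97 for the plateau rule). `cut_height` remains an explicit
parameter for users who want a fixed height. Dynamic tree cutting (the
common practice) is intentionally out of scope; its parameters are
data-dependent and unneeded at these scales.

Eigengenes are unit-norm first principal components of the gene-standardized
module submatrix, sign-aligned to the module's mean expression profile; in
the degenerate case of an exactly zero alignment (two perfectly
anticorrelated genes) the sign follows the first gene in identifier order.
Module labels are M1, M2, … by decreasing size. Eigengene–trait tables use
Spearman correlation with asymptotic two-sided p-values and no multiplicity
adjustment (the tables are descriptive, as in common practice).

## Bayesian networks (MMHC)

Structure learning is Max-Min Hill Climbing: an MMPC skeleton (forward
max-min candidate growth, backward conditional-independence shrinkage,
AND-symmetrization) from Fisher-z partial-correlation tests, then greedy
hill climbing over {add, delete, reverse} on the Gaussian BIC, with edge
additions restricted to skeleton pairs, every state acyclic, and a
lexicographic (operator, source, target) tie-break so results are exactly
reproducible and invariant to gene order up to score-equivalent
orientations.

Defaults: conditioning sets up to size 3; ridge 1e-8 on correlation-matrix
solves (near-collinear module genes); modules above 1000 genes are refused
rather than silently subsampled. The CI-test level defaults to **α = 0.01**:
each absent edge in a sparse true graph hinges on a single
conditional-independence test, so the probability of a spurious edge grows
roughly linearly in α across seeds and nodes; at n in the thousands the
power loss from 0.05 → 0.01 is negligible (true-edge z-statistics are in the
tens) while exact skeleton recovery on small graphs becomes reliable. Both
α and the cap are configurable.

The per-node BIC penalty counts `|parents| + 2` parameters (coefficients are
`|parents|`, plus intercept and residual variance). Residual variances come
from Schur complements of the MLE covariance; a variance floored at 1e-12
guards exact collinearity.

## BAN analysis

Neighborhoods are 3-step, undirected, and include the gene itself. Direction
is ignored deliberately: the learned DAGs are correlation-driven and edge
orientation within an equivalence class is arbitrary, so directed
neighborhoods would be unstable under score-equivalent reorientations.
Pruning is two-stage — drop neighborhood size ≤ 2, then drop sizes more than
one sample standard deviation (n−1 denominator) below the mean of the
survivors — computed per network set over genes pooled across that set's
modules. The enrichment p is the exact hypergeometric upper tail
`P(X ≥ overlap)` with `m` = bone genes among the set's network genes and the
universe equal to the pre-pruning network gene count. The BAN threshold is
nominal p ≤ 0.05 with no multiplicity correction, matching how the statistic
is used (a screening tier, not an inferential claim). The connectivity
comparison (bone vs non-bone neighborhood sizes) is a one-sided Wilcoxon
rank-sum test with tie correction; the all-tied degenerate case returns
p = 1.

## Colocalization

Per-SNP Wakefield log approximate Bayes factors with prior effect SD
W^0.5 = 0.15 (quantitative-trait convention) and per-SNP priors
p1 = p2 = 1e-4, p12 = 1e-5. The five-hypothesis posterior uses log-sum-exp
stabilized sums; the H3 term `S1·S2 − S12` is computed as
`exp(log S1 + log S2) · (1 − exp(log S12 − log S1 − log S2))` and clamped at
zero (it vanishes identically with one SNP). The analysis window is ±200 kb
of the lead, inclusive at both boundaries; one causal variant per trait is
assumed (no conditioning or masking). When only p-values are available, |z|
is reconstructed from the two-sided p and the variance approximated by
`1/(2·n·maf·(1−maf))`; the ABF depends on z² only, so the unknown sign is
immaterial. PPH4/PPH3 ratios are reported but never used for calling; the
call is PPH4 ≥ 0.75.

## Locus integration

Coordinates are 0-based half-open internally (BED convention); summary-stat
positions are 1-based at the file boundary. Gene-to-lead proximity uses the
whole gene interval (minimum distance, inclusive ≤ 1 Mbp), not the TSS.
Enrichment odds ratios are cross-product (sample) ORs with two-sided Fisher
exact p; a zero margin is reported as not estimable with p = 1 and a zero
off-diagonal product as an infinite-OR sentinel. The interval-overlap null
re-places each locus (length preserved) uniformly at random, chromosome
chosen proportional to placeable length, intervals free to overlap; the
percentile uses the ≤ convention appropriate to a discrete null.

## Synthetic data: what it emulates, and what it does not

* **Expression** — a negative-binomial observation layer (shared dispersion
  0.05, log-normal baselines) over log-scale latents; latents are either a
  one-factor model per module (loading λ drawn from a configured range, so
  within-module latent correlation is λ²) or a planted linear-Gaussian SEM
  per module. In SEM mode each bone-module DAG is a hub-and-chains tree: the
  driver's direct children carry the bone-gene labels and the remaining
  genes extend four long chains, so the driver's 3-step neighborhood stays
  dominated by bone genes while peripheral genes see few — giving the BAN
  statistic a planted positive and plenty of planted negatives. Batch adds
  seeded per-gene shifts (SD 0.3) crossed with sex.
* **Genotypes/LD** — two haplotypes per individual, each thresholded from a
  latent AR(1) Gaussian at Φ⁻¹(MAF); the latent autocorrelation is
  calibrated per adjacent pair (bisection on the bivariate-normal rectangle
  probability) so the realized dosage correlation matches the requested
  `ld_rho` where the Fréchet bound for the two allele frequencies permits
  it. With MAFs drawn from U(0.05, 0.5) many adjacent pairs cannot reach
  correlations above ~0.6, so high-LD settings are faithful in a
  matched-MAF sense; this is a one-parameter LD model, not a coalescent.
* **Summary statistics** — exact marginal OLS per SNP on two independent
  cohorts (no sample overlap, matching a GWAS-consortium vs eQTL-panel
  setting). Causal effects are standardized so a variance-explained v yields
  a causal z of about √(n·v/(1−v)).
* **Reference study sizes** — 200 samples, 5 × 40-gene modules + 60
  background genes, three driver loci (shared-variant pairs) and three
  BAN-prone decoy loci (two-independent-variant pairs), eQTL/GWAS cohorts of
  5000 with 2% variance explained and LD 0.9 over 100 SNPs. These sizes keep
  a full run to a few seconds while leaving every stage's signal close to
  its decision boundary (driver enrichment p ~ 1e-4–1e-2, decoys rejected
  by the posterior, not by construction).

Not emulated: realistic human LD maps and allele-frequency spectra,
cell-type mixtures, gene-length/GC biases, trans effects, overlapping
GWAS/eQTL samples, and annotation-aware gene placement. Passing tests
demonstrate that the algorithms recover planted structure under their own
generative assumptions — linear-Gaussian dependence, one causal variant per
trait, modular expression — not that they would at real-data effect sizes.

## Determinism

Every generator is a pure function of its arguments including the seed
(numpy `SeedSequence` with fixed spawn keys per stage); the pipeline writes
reports with sorted keys and no timestamps, and reruns with the same config
and seed are byte-identical. Stage outputs are cached by a content hash of
their inputs and parameters; caching only skips recomputation and cannot
change results.

## Known limitations

* The static module cut is coarser than dynamic tree cutting on real-scale
  (>10⁴ genes) expression; block-wise decomposition is not implemented.
* MMPC's subset search is exponential in the candidate-set size; the
  max-sepset cap (3) bounds it but can in principle leave spurious edges in
  dense graphs.
* Single-causal-variant colocalization under-reports PPH4 when multiple
  causal variants share a window.
* The hypergeometric BAN test conditions on the learned network; uncertainty
  in the network itself is not propagated (no bootstrap averaging).
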