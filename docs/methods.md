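# Methods

This note documents the models implemented in `chondrotime`, the
assumptions behind them, the tunable parameters with their defaults, the
design decisions taken where the method family leaves choices open, and
the limits of what the synthetic-data checks demonstrate.

## Study design assumed

A short differentiation time course: four ordered timepoints (default
labels D0 < D4 < D8 < D12, taken from the design file's declaration
order, never sorted lexicographically) with three replicates each for
expression and five per group for the metabolite panel. Expression input
is an already-normalized non-negative abundance matrix (FPKM-like);
alignment and counting are upstream and out of scope. All gene and
metabolite identifiers are opaque strings.

## Differential expression (`diffexpr`)

Abundances are transformed to log2(x + 1); the pseudocount bounds
fold-changes for zero-abundance genes and makes group-mean differences
act as log2 fold-changes. The test is a per-gene two-group contrast with
empirical-Bayes variance moderation: with d residual degrees of freedom
per gene, the marginal model s²_g ~ s₀²·χ²_{d₀}/d₀ implies known
digamma/trigamma moments for log s²_g, which are matched and inverted
(Newton on the trigamma) to estimate (d₀, s₀²). The posterior variance
(d₀s₀² + d s²_g)/(d₀ + d) feeds a t statistic on d₀ + d degrees of
freedom (a normal reference when d₀ is effectively infinite). Forcing
d₀ = 0 recovers the classic pooled-variance t exactly, which is the
oracle the tests use; d₀ estimated on data where all genes share one true
variance correctly diverges, pooling fully.

Degenerate genes (zero variance in both groups and zero difference) get
t = 0, p = 1 rather than NaN. The DEG filter is |log2FC| ≥ 1 (boundary
inclusive) AND raw p < 0.05 (boundary exclusive); adjusted p values
(Benjamini–Hochberg, per comparison) are always reported and a flag
switches the filter to them. Filtering on raw p mirrors the analysis
convention this pipeline reproduces; at n = 3 replicates the BH-gated
power is intrinsically low (the test suite documents a ~0.2 fixed point
for a 2-sd shift), so the raw-p gate is also what the power checks use.
All six pairwise timepoint comparisons are computed. The qPCR helper
returns 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref) − (Ct_target,cal −
Ct_ref,cal).

## Temporal clustering (`timeclust`)

Profiles are per-timepoint means of log2 abundance, z-standardized per
gene with the sample (n−1) standard deviation; zero-variance genes are
excluded and reported. Clustering is standard fuzzy c-means on Euclidean
distance: memberships u_ij = 1/Σ_k (d_ij/d_kj)^{2/(m−1)}, centers the
u^m-weighted means, convergence when the largest membership change drops
below 1e-6, hard stop at 300 iterations. A profile coinciding with a
center receives crisp membership there. Initial centers are data points
chosen by a seeded k-means++-style spread (uniform seeding was found to
merge archetypes occasionally; the spread makes planted-archetype
recovery reliable across seeds). Defaults c = 4 and m = 1.25: c mirrors
the four temporal archetypes this analysis targets (no automatic model
selection); m = 1.25 is in the range reference implementations estimate
for standardized expression data — the method family does not publish a
value, so this is a package choice, exposed in the API. Hard labels are
argmax memberships with ties to the lowest cluster index; genes whose
best membership falls below 0.3 are 'unassigned'.

## Regulatory states (`grn`)

A transcriptional state is one consecutive comparison (D4 vs D0, D8 vs
D4, D12 vs D8) with its DEG set split by log2FC sign and the subset of
DEGs annotated as TFs. TF-family over-representation reports both the
upper-tail cumulative hypergeometric P(X ≥ k) (N = annotated TF universe,
K = family size, n = subset size) and Fisher's exact two-sided p on the
same table, with BH across families as the significance gate — the two
statistics agree one-sidedly to machine precision and both are reported.

Promoter scanning: supplied 1 kb upstream sequences (the package never
extracts from a genome) are scored on both strands with log2-odds against
the motif-library background, PWM probabilities floored at 1e-4 and
renormalized. N bases contribute log-odds 0 (background probability).
Per-score p-values are exact under the background model: per-position
scores are discretized to 1e-3-bit bins and convolved position by
position (each column contributes a 4-point distribution), giving the
full null distribution of the window score; a hit is any window with
tail probability ≤ 1e-4 (default). The reverse strand is scored with the
reverse-complement matrix and its own null. The discretization trades
exactness for O(width × range) work; the tests verify agreement with
exhaustive k-mer enumeration at the same discretization, so the only
approximation is the 1e-3 binning itself. The scan threshold and
both-strand default are package choices; the TF → motif mapping is an
input file.

Edges require (a) a differentially expressed TF, (b) a DEG target, and
(c) a motif hit for one of the TF's motifs in the target's promoter
(best hit by p-value retained). Sign: activation when the TF's and
target's DEG directions agree in the comparison, inhibition otherwise —
only the signs enter, never magnitudes. Pair counts per state and TFs
active in more than one state are reported.

## DNB analysis (`dnb`)

All correlations are Pearson across replicates within one timepoint with
the sample (n−1) sd convention; zero-variance genes get correlation 0 and
a flag. For a module M at timepoint t: SDin = mean member sd, PCCin =
mean |r| over member pairs, PCCout = mean |r| over member × non-member
pairs within the analyzed gene set, and CI = SDin·PCCin/max(PCCout, ε)
with ε = 0.05 guarding the division (configurable). Candidate modules
come from average-linkage hierarchical clustering on 1 − |r|, the tree
cut at heights {0.2, 0.4, 0.6, 0.8}, keeping clusters of 5–100 genes; if
the correlation structure is so noisy that no cut yields a cluster in the
size band (common at 3 replicates), the same tree is re-cut at doubling
fixed cluster counts. The analyzed set defaults to the DEG union in the
pipeline. Per timepoint the best module maximises CI (ties: larger
module, then lexicographically smallest member list); the tipping point
is the timepoint of the maximum best-CI, earliest on a full tie (with a
warning). The member-centered network is the induced subgraph on members
plus their first-neighbor DEGs from the supplied interaction network;
members absent from the network remain isolated nodes and their count is
reported, since deposited interaction databases typically lack some
members.

Three replicates make these correlation estimates very noisy; the
package runs at n = 3 but the recovery guarantees quoted in the tests are
established at 10 replicates, and the null behaviour (tip uniform over
timepoints in the absence of a planted module) is verified by simulation.

## Enrichment (`enrichment`)

ORA is the upper-tail hypergeometric against an explicit universe, BH
across sets, sets with fewer than 3 (or more than 500) in-universe
members skipped, out-of-universe query genes dropped with a warning.
Per-sample scoring is a rank-weighted single-sample KS walk: within a
sample, genes are ranked by expression (descending, stable ties); in-set
steps are weighted (N − pos)^τ normalized to sum 1 (τ = 0.25), out-of-set
steps are −1/(N−K); the score is the maximum-magnitude deviation, signed.
This is an ssGSEA-style statistic: rank-based, hence invariant to any
strictly monotone within-sample transform; it deliberately replaces the
kernel-CDF formulation of the GSVA family with a simpler walk, and every
check in this package is against this definition. When the walk's
positive and negative extremes tie exactly, the reported sign is a
convention (first maximum). Score trends across timepoints reuse the
moderated t on the score matrix, significant at BH-adjusted p ≤ 0.05
(boundary inclusive).

## Metabolite screening (`metabolomics`)

Concentrations are analyzed on the raw scale (targeted-panel convention,
no log transform); variables are mean-centered and unit-variance scaled
before OPLS-DA, constants dropped with a warning. The fit is NIPALS with
orthogonal signal removal: predictive weight w ∝ X'y, orthogonal weight
the part of the X loading orthogonal to w, orthogonal component removed,
repeated n_orth times (default 1), then a single predictive component on
the filtered matrix. Orthogonal scores are orthogonal to predictive
scores to machine precision on every fit. Cross-validated Q² (K-fold,
test folds projected through the training orthogonal filter) is provided
as a sanity statistic; permuted labels give Q² ≤ 0 on average. With one
unit-norm predictive component VIP_j = sqrt(p)·|w_j|, so Σ VIP² = p
identically — the tests assert this on randomized fits.

Pairwise DRMs: fold-change is the raw group-mean ratio (B over A);
the call is (FC ≥ 2 or FC ≤ 0.5) AND VIP > 1, FC boundaries inclusive,
VIP boundary exclusive. The lower threshold is 0.5 — the reciprocal of
2, the standard symmetric convention — and is configurable; the screen
records the value used. Multi-group DRMs: one-way ANOVA across all
timepoints, raw p < 0.05, AND VIP > 1 taken by default from the
first-vs-last timepoint OPLS-DA (configurable). Set accounting reports
UpSet-style exclusive intersections over the six pairwise DRM sets, the
metabolites consistently called increased in every same-baseline
comparison, and the fraction of all DRM calls that are increases. No QC
drift correction is applied: the input is assumed calibrated.

## Integration (`integration`)

Each pathway's gene side and metabolite side are tested separately by
ORA against their own universes (metabolite universe = the detected
panel, not a full compound database), BH within side across pathways.
The *joint* flag (both adjusted p ≤ α = 0.05) and the Fisher combination
χ² = −2(ln p_g + ln p_m) on 4 df are formalizations introduced by this
package for a relationship usually reported qualitatively, and outputs
label them as such. A per-pathway projection table lists every member
gene with its per-comparison log2FC and every member metabolite with its
FC and direction ('NA' for members absent from the data). A simple
sign-concordance fraction over (gene, metabolite) pairs is provided,
again package-defined — metabolite and enzyme-gene changes are not
expected to be synchronized.

## Synthetic data (`simulate`)

All generators are pure functions of (config, seed). The noise model is
log-normal: multivariate normal on the log2 scale, exponentiated, which
matches non-negative abundances and makes planted fold-changes additive
on the log scale. Cluster genes follow one of four archetype mean
profiles (dip-recover, monotone up, monotone down, pulse; default 100
genes each at log2 noise sd 0.3 around baseline 2^6). The DNB module
(default 20 genes) is flat in mean but shares a per-timepoint factor:
members load sqrt(ρ_in) (ρ_in = 0.2 off-tip, 0.9 at the tip, default tip
index 1 = D4), outside genes load ρ_out/sqrt(ρ_in) (ρ_out = 0.1), and
member sd is multiplied by 3 at the tip. This single-factor construction
realizes exactly the requested member–member and member–outside
correlations and is positive semi-definite by construction; configs whose
implied loading exceeds 1 are rejected with the offending constraint
named. Promoters are i.i.d. background sequence (default background
0.3/0.2/0.2/0.3) with one exact-consensus instance per TF → target pair
inserted at a recorded offset with probability `insertion_rate`; one
motif per TF with probability 0.97 on the consensus base. The metabolite
panel (default 50, 14 planted up at +2 log2 from D4 on, 2 planted down at
−1.5, CV 0.1, 5 per group) records as truth every metabolite whose
planted |log2FC| ≥ 1 per comparison.

What this does *not* emulate: mean–variance trends and count noise of
real RNA-seq, correlated gene programs outside the planted module,
motif degeneracy and promoter composition bias, batch effects, missing
values and drift in metabolomics. Passing the planted-recovery tests
therefore demonstrates correctness of the algorithms under their own
assumptions, not performance on real data.

## Pipeline and reproducibility

`run_pipeline` executes the seven stages from one config (YAML or
programmatic), validates every referenced input before any stage runs,
writes per-stage TSVs with a fixed float format, and emits a manifest
with parameters, seed, and SHA-256 checksums of all outputs; reruns with
the same config are byte-identical. Stage failures abort with the stage
name, keeping upstream outputs. Problem sizes in the test suite and
acceptance script (e.g. 300-gene / 50-run tipping-point recovery,
2000-gene null batteries, 800-gene clustering) are chosen as the smallest
scales at which the sampling claims are stable; they complete in seconds.
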