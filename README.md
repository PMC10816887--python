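# chondrotime

A time-course multi-omics analysis toolkit built around the computational
chain used to study chondrocyte differentiation: bulk expression profiles
and a targeted metabolite panel measured over a short differentiation
course (days 0, 4, 8, 12; three replicates) are mined for differentially
expressed genes, temporal expression archetypes, TF-driven regulatory
states, a dynamic-network-biomarker (DNB) tipping point, per-sample
gene-set activity, differentially regulated metabolites, and pathways in
which genes and metabolites move together.

The package is aimed at computational biologists who have an expression
matrix (e.g. FPKM), a sample design, and the usual satellite files
(promoter FASTA, motif PWMs, TF annotation, interaction network, GMT gene
sets, metabolite concentrations, pathway membership) and want a tested,
reproducible implementation of each stage — plus synthetic-data
generators that plant known ground truth so every stage can be verified
end to end.

## The statistics at the core

- **Moderated differential expression.** Per gene, a two-group contrast
  on log2 abundances with empirical-Bayes variance moderation: gene-wise
  variances s²_g are shrunk toward a prior (s₀², d₀) fitted by matching
  the moments of log s²_g to a scaled inverse-chi-square, giving
  s²_post = (d₀s₀² + d·s²_g)/(d₀ + d) and a t statistic with d₀ + d
  degrees of freedom. DEGs pass |log2FC| ≥ 1 and p < 0.05 (BH-adjusted p
  reported alongside).
- **Fuzzy c-means temporal clustering** of z-standardized per-timepoint
  mean profiles, memberships u_ij = 1/Σ_k (d_ij/d_kj)^{2/(m−1)},
  fuzzifier m = 1.25, c = 4 archetypes by default.
- **Regulatory states.** For each consecutive comparison, TF-family
  over-representation (upper-tail hypergeometric + Fisher's exact, BH),
  PWM scanning of 1 kb promoters with exact p-values from a
  dynamic-programming null score distribution, and TF → target edges
  signed *activation* when TF and target DEG directions agree,
  *inhibition* otherwise.
- **DNB criticality index.** For a candidate module at a timepoint,
  CI = SDin · PCCin / PCCout: mean member standard deviation across
  replicates, mean absolute within-module Pearson correlation, and mean
  absolute member-to-outside correlation. The timepoint where the best
  module's CI peaks is the tipping point.
- **Per-sample gene-set scores** from a rank-weighted Kolmogorov–Smirnov
  walk over each sample's expression ranking (invariant to monotone
  transforms), tested across timepoints with the moderated t.
- **OPLS-DA / VIP metabolite screening.** NIPALS fit with orthogonal
  signal removal; VIP_j = sqrt(p · Σ_a SSY_a w²_aj / Σ_a SSY_a)
  (so mean VIP² = 1). Pairwise DRMs: FC ≥ 2 or ≤ 0.5 and VIP > 1;
  multi-group DRMs: ANOVA p < 0.05 and VIP > 1.
- **Joint pathway projection.** Hypergeometric enrichment run separately
  on a pathway's gene and metabolite sides; *joint* pathways are
  significant on both after BH, with Fisher's combined χ² reported.

## Worked example

`examples/` contains one narrative script per capability. Generate the
planted-truth inputs once, then run any stage:

```bash
cd examples
python 01_simulate_inputs.py
python 05_dnb_tipping_point.py
```

which prints

```
CI per timepoint:
D0     0.591
D4     1.378
D8     0.435
D12    0.477
detected tipping point: D4 (planted: D4)
```

i.e. the criticality index over the four timepoints peaks at day 4 — the
planted critical transition — even at the realistic three-replicate
design. `07_metabolite_screen.py` similarly reports
`pairwise DRMs (FC >= 2 or <= 0.5, VIP > 1): 16 — 16 of 16 planted
recovered`, and `03_temporal_clustering.py` reports
`adjusted Rand index vs planted archetypes: 1.000`.

The same flow is available from the shell:

```bash
chondrotime simulate --seed 11 --out simdir
chondrotime run --config run.yaml      # paths + thresholds in YAML
```

`run` executes all seven stages (differential expression → clustering →
regulatory network → DNB → enrichment → metabolomics → integration),
writing per-stage TSVs and a `manifest.json` with parameters, the seed,
and SHA-256 checksums of every output, so a rerun with the same config is
verifiably byte-identical.

## Layout

- `src/chondrotime/` — `core` (types/validation), `io` (TSV/GMT/FASTA/
  MEME readers and writers), `simulate` (planted-truth generators),
  `diffexpr`, `timeclust`, `grn`, `dnb`, `enrichment`, `metabolomics`,
  `integration`, `pipeline`, `cli`.
- `docs/methods.md` — models, assumptions, parameter choices, and what
  the synthetic data does and does not emulate.
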