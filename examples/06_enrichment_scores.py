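"""Over-representation analysis and per-sample enrichment scoring."""

from chondrotime import diffexpr, enrichment, io

matrix = io.read_expression("example_data/expression.tsv", "example_data/design.tsv")
logm = diffexpr.log_transform(matrix)
sets = io.read_gmt("example_data/gene_sets.gmt")

results = diffexpr.all_pairwise(logm, matrix.design)
union = diffexpr.union_degs({c: diffexpr.filter_degs(r) for c, r in results.items()})

ora = enrichment.ora(set(union), sets, set(matrix.gene_ids))
print("over-representation of the DEG union (hypergeometric, BH):")
print(ora.table[["k", "K", "p_hyper", "p_adj"]].round(4))

scores = enrichment.sample_scores(logm, sets, tau=0.25)
print("\nper-sample enrichment scores (rank-based KS walk):")
print(scores.round(2).iloc[:, :6])

sig = enrichment.score_significance(scores, matrix.design)
print("\nscore trends across timepoints (moderated t, BH <= 0.05):")
print(sig[sig["significant"]][["set_id", "contrast", "delta", "p_adj"]].round(4))
# archetype sets whose member expression drifts over the course surface here
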