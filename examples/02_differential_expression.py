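"""Pairwise moderated-t differential expression on the simulated course.

Run examples/01_simulate_inputs.py first.
"""

from chondrotime import diffexpr, io

matrix = io.read_expression("example_data/expression.tsv", "example_data/design.tsv")
logm = diffexpr.log_transform(matrix)

results = diffexpr.all_pairwise(logm, matrix.design)
deg_sets = {comp: diffexpr.filter_degs(res) for comp, res in results.items()}
for comp, degs in deg_sets.items():
    print(f"{comp}: {len(degs)} DEGs  (prior df {results[comp].prior_df:.1f})")
union = diffexpr.union_degs(deg_sets)
print(f"union over all six comparisons: {len(union)} DEGs")
# a DEG passes |log2FC| >= 1 (boundary included) and raw p < 0.05, the
# thresholds used throughout; BH-adjusted p is reported alongside

fold = diffexpr.ddct_relative_expression(25, 20, 27, 20)
print(f"qPCR 2^-ddCt example (Ct 25/20 vs calibrator 27/20): fold = {fold}")
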