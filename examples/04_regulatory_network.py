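"""TF-family enrichment, promoter scanning and a directional state network.

The state covers the first consecutive comparison (D4 vs D0): an edge
needs a differentially expressed TF, a DEG target, and a motif hit in the
target's 1 kb promoter; activation when both move the same way.
"""

import pandas as pd

from chondrotime import diffexpr, grn, io

matrix = io.read_expression("example_data/expression.tsv", "example_data/design.tsv")
logm = diffexpr.log_transform(matrix)
promoters = io.read_fasta("example_data/promoters.fasta")
pwms = io.read_pwm("example_data/motifs.meme")
annot = io.read_tf_annotation("example_data/tf_annotation.tsv")
tf_map = pd.read_csv("example_data/tf_motif_map.tsv", sep="\t")
tf_to_motifs = tf_map.groupby("tf")["motif"].apply(list).to_dict()

res = diffexpr.moderated_ttest(logm, matrix.design, "D0", "D4")
degs = diffexpr.filter_degs(res)
direction = {g: "up" if res.table.loc[g, "log2_fc"] > 0 else "down" for g in degs}
tfs = frozenset(g for g in degs if annot.is_tf(g))
state = grn.TranscriptionalState("state1", "D4_vs_D0", direction, tfs)

fam = grn.tf_family_enrichment(set(tfs), annot, set(annot.family_of))
print("TF family enrichment (hypergeometric / Fisher):")
print(fam.round(4))

hits = grn.pwm_scan(promoters, pwms, p_threshold=1e-4)
print(f"\nmotif hits at p <= 1e-4: {len(hits)}")

edges = grn.build_state_network(state, hits, tf_to_motifs)
counts, multi = grn.count_pairs(edges)
print("\nregulatory pairs per state:")
print(counts)
# activation = TF and target share the DEG direction; inhibition = opposite
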