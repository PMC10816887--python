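"""Joint DEG-DRM pathway projection: which pathways move on both sides."""

from chondrotime import diffexpr, integration, io
from chondrotime import metabolomics as mb

matrix = io.read_expression("example_data/expression.tsv", "example_data/design.tsv")
logm = diffexpr.log_transform(matrix)
met = io.read_metabolites("example_data/metabolites.tsv", "example_data/met_design.tsv")
pmap = io.read_pathway_map("example_data/pathway_map.tsv")

results = diffexpr.all_pairwise(logm, matrix.design)
union = set(diffexpr.union_degs({c: diffexpr.filter_degs(r) for c, r in results.items()}))
screens = mb.all_pairwise_screens(met, met.design)
drms = set().union(*(s.drms for s in screens.values()))

joint = integration.joint_enrichment(
    union, drms, pmap, set(matrix.gene_ids), set(met.metabolite_ids)
)
print("joint pathway enrichment (both sides BH <= 0.05):")
print(joint[["gene_k", "p_gene_adj", "met_k", "p_met_adj", "joint", "p_combined"]].round(5))

proj = integration.pathway_projection_table(results, screens, pmap, "pw_planted")
print(f"\nprojection table for pw_planted: {len(proj)} rows "
      "(one per member per comparison)")
print(proj.head(8).to_string(index=False))
# genes carry log2 fold-changes, metabolites raw fold-changes + direction
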