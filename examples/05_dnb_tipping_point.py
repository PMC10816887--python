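"""Dynamic network biomarker analysis: CI curve and tipping point.

The criticality index CI = SDin * PCCin / PCCout peaks at the timepoint
where a gene module fluctuates most, self-correlates most, and decouples
from the rest — the planted transition in the simulated course.
"""

import json

from chondrotime import diffexpr, dnb, io

matrix = io.read_expression("example_data/expression.tsv", "example_data/design.tsv")
logm = diffexpr.log_transform(matrix)
truth = json.loads(open("example_data/truth.json").read())

result = dnb.criticality_curve(logm, matrix.design)
print("CI per timepoint:")
print(result.ci_curve.round(3).to_string())
print("detected tipping point:", result.tipping_timepoint,
      "(planted:", truth["dnb_tipping_timepoint"] + ")")
members = set(result.members)
overlap = members & set(truth["dnb_members"])
print(f"module size {len(members)}, overlap with planted members {len(overlap)}")

network = io.read_edges("example_data/network.tsv")
degs = set(logm.index)  # use all simulated genes as the DEG background here
nodes, edges = dnb.dnb_neighborhood(result.members, network, degs)
print(f"member-centered neighborhood: {len(nodes)} nodes, {len(edges)} edges")
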