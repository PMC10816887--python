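"""Generate a full set of planted-truth pipeline inputs.

Writes expression/design/metabolite tables, promoters, motifs, a TF
annotation, an interaction network, gene sets, a pathway map and
truth.json into ./example_data.  Every downstream example loads from
this directory.
"""

from chondrotime.pipeline import write_simulation
from chondrotime.simulate import SimulationConfig

truth = write_simulation(SimulationConfig(seed=11), "example_data")
print("planted DNB tipping point:", truth["dnb_tipping_timepoint"])
print("planted DNB members:", len(truth["dnb_members"]))
print("planted motif instances:", len(truth["planted_motif_hits"]))
# the tipping point is the timepoint at which the planted module's
# correlation and variance spike; downstream examples should rediscover it
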