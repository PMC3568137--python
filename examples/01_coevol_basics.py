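"""Score co-evolution for one coupled position pair.

Simulates 120 binding sites of length 6 on the five-mammal tree with a hard
preferred-pair constraint between positions 1 and 3 (A/A or G/G only), then
scores every position pair.  The coupled pair should stand far above the
rest: a positive CoEvol means the two positions' substitution histories
track each other more than independence predicts.
"""

import numpy as np

from cisevol import Coupling, PhyloModel, SimulationConfig, coevol_for_pair, simulate_siteset

model = PhyloModel.default()
res = simulate_siteset(
    SimulationConfig(
        phylo=model, n_sites=120, length=6, seed=7,
        couplings=[Coupling(1, 3, frozenset({(0, 0), (2, 2)}), 0.0)],
    )
)
ss = res.siteset

print("pair   scope   CoEvol")
for i in range(ss.length):
    for j in range(i + 1, ss.length):
        rec = coevol_for_pair(ss, model, i, j)
        flag = "  <-- coupled" if (i, j) == (1, 3) else ""
        print(f"({i},{j})   {j-i}      {rec.value:8.2f}{flag}")

print(
    "\nThe coupled pair's CoEvol is the summed log-ratio of joint vs"
    "\nindependent tree likelihoods over all 120 sites; uncoupled pairs"
    "\nfluctuate around the (positive) finite-sample baseline."
)
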