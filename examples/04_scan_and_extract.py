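"""Scan a promoter for motif matches with exact p-values and build a site set.

A toy GC-box-like motif is scanned over a simulated 5-species promoter
alignment; matches are filtered to gapless alignment slices and collected
into the archive format used throughout the package (5 aligned rows per
site, blank-line separated).
"""

import io

import numpy as np

from cisevol import PWM, PhyloModel
from cisevol.simulate import simulate_promoter_alignments
from cisevol.sites import scan_alignment, select_sites, write_site_archive

model = PhyloModel.default()
proms = simulate_promoter_alignments(model, n_promoters=4, length=400, seed=99)

# strong 6-bp motif (counts; columns prefer G,G,G,C,G,G)
pwm = PWM(
    id="GCBOX",
    matrix=np.array([
        [1, 1, 1, 1, 1, 1],
        [2, 2, 2, 40, 2, 2],
        [40, 40, 40, 2, 40, 40],
        [1, 1, 1, 1, 1, 1],
    ], dtype=float),
)

pairs = []
for aln in proms:
    pairs.extend(scan_alignment(aln, pwm, p_threshold=1e-3))
print(f"{len(pairs)} matches at p <= 1e-3 across {len(proms)} promoters")

ss = select_sites(pairs, pwm_id=pwm.id, max_n=1000)
if ss is None:
    print("no gapless matches survived -- rerun with a looser threshold")
else:
    print(f"retained {ss.n} gapless sites of length {ss.length}")
    buf = io.StringIO()
    write_site_archive(ss, buf)
    print("\nfirst archive block (human, chimp, mouse, rat, dog):")
    print("\n".join(buf.getvalue().splitlines()[:6]))
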