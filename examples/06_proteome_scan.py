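"""Classifying proteins by the direction of the phosphorylation effect.

Runs the delta-B_LC scan on the two synthetic preset geometries: a
Ki-67-like repeat (phosphosites C-terminal of the basic tract) and an
NPM1-like IDR (phosphosites inside the basic tract).  The scan reports
whether mitotic hyperphosphorylation enhances or reduces the charge
blockiness of each disordered region, plus a designated-block size
summary.
"""

import pandas as pd

from chargeblocks import PhosphositeTable, block_size_summary, scan, scan_to_frame
from chargeblocks.synthetic_constructs import (
    ki67_r12_like_sites,
    ki67_r12_like_unit,
    npm1_like_idr,
    npm1_like_sites,
)

seqs = [
    ki67_r12_like_unit().replace(phosphosites=frozenset()),
    npm1_like_idr().replace(phosphosites=frozenset()),
]
table = PhosphositeTable(
    pd.concat([ki67_r12_like_sites().frame, npm1_like_sites().frame], ignore_index=True)
)
records = scan(seqs, table, {s.id: (1, len(s)) for s in seqs})
print(scan_to_frame(records).to_string(index=False))
for state in ("interphase", "mitotic"):
    print(state, "block sizes:", block_size_summary(records, state))
print(
    "\n'enhancing' means hyperphosphorylation adds/deepens charge blocks "
    "(stronger LLPS); 'reducing' means it cancels a block (weaker LLPS)."
)
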