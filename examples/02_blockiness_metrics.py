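"""Charge-patterning statistics before and after hyperphosphorylation.

Computes B_LC (blockiness of like charges), D_seg (degree of charge
segregation), SCD and kappa for the synthetic R12-like repeat unit in
both states.  The mitotic increase in B_LC quantifies how
hyperphosphorylation converts the unit into a strong diblock ampholyte:
a positive block followed by a newly formed negative block.
"""

from chargeblocks import block_census, charge_profile, compute_report, segment_blocks
from chargeblocks.synthetic_constructs import ki67_r12_like_unit

unit = ki67_r12_like_unit()
for state in ("interphase", "mitotic"):
    rep = compute_report(unit, state=state)
    print(
        f"{state:>10}:  B_LC={rep.blc:6.1f}  D_seg={rep.dseg:.3f}  "
        f"SCD={rep.scd:7.2f}  kappa={rep.kappa:.3f}  net={rep.net_charge:+d}  "
        f"blocks(+/-)={rep.n_blocks_pos}/{rep.n_blocks_neg}"
    )
    blocks = segment_blocks(charge_profile(unit, window=35, state=state))
    for b in blocks:
        print(f"            block {b.sign} {b.start}-{b.end} ({b.size} aa, area {b.area:.1f})")

print(
    "\nB_LC rises on mitotic entry because the phosphosite cluster forms a "
    "designated negative block downstream of the basic tract."
)
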