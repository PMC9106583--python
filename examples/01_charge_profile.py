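"""Windowed charge profile of a diblock repeat unit in both cell-cycle states.

Builds the package's synthetic Ki-67 R12-like repeat unit and prints its
net charge and 25-residue windowed charge sums around one phosphosite in
the interphase (dephosphorylated) and mitotic (hyperphosphorylated)
states.  The mitotic values are more negative wherever a window covers a
phosphosite, because each phosphate contributes charge -2.
"""

from chargeblocks import charge_profile, net_charge
from chargeblocks.synthetic_constructs import ki67_r12_like_unit

unit = ki67_r12_like_unit()
print(f"unit: {unit.id}, {len(unit)} aa, {len(unit.phosphosites)} phosphosites")
print(f"net charge interphase: {net_charge(unit, 'interphase'):+d}")
print(f"net charge mitotic:    {net_charge(unit, 'mitotic'):+d}")

inter = charge_profile(unit, window=25, state="interphase")
mit = charge_profile(unit, window=25, state="mitotic")
site = sorted(unit.phosphosites)[4]
print(f"\nwindowed sums (W=25) near phosphosite {site}:")
print("pos  res  interphase  mitotic")
for pos in range(site - 2, site + 3):
    print(
        f"{pos:>3}  {unit.residue_at(pos)}    {inter.sums[pos-1]:>6}   {mit.sums[pos-1]:>6}"
    )
print(
    "\nThe drop of the mitotic values reflects the -2 charge of each "
    "phosphorylated S/T inside the window."
)
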