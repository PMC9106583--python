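"""In-silico mutant classes of the repeat unit.

Builds the phosphomimetic (all phosphosites -> E), the
non-phosphorylatable (S/T -> A) and the charge-block mimetic (CBm-7-like)
variants and prints their interphase net charge and B_LC.  The
phosphomimetic raises blockiness without any phosphate; the alanine
variant is state-independent; the CBm analogue reaches net charge +5 with
B_LC ~35 purely through substitutions at non-phosphosite residues.
"""

from chargeblocks import apply_nonphospho, apply_phosphomimetic, compute_blc, net_charge
from chargeblocks.synthetic_constructs import cbm7_like, ki67_r12_like_unit

unit = ki67_r12_like_unit()
variants = {
    "WT (interphase)": unit,
    "WT (mitotic)": unit,
    "Pm9 (phosphomimetic)": apply_phosphomimetic(unit).sequence,
    "A9 (non-phospho)": apply_nonphospho(unit).sequence,
    "CBm-7-like": cbm7_like().sequence,
}
for name, seq in variants.items():
    state = "mitotic" if "mitotic" in name else "interphase"
    print(
        f"{name:>22}:  net={net_charge(seq, state):+3d}   "
        f"B_LC={compute_blc(seq, state):6.1f}"
    )
print(
    "\nPm9 mimics the mitotic charge pattern with ordinary glutamates; "
    "CBm-7-like shows that blockiness, not a specific phosphosite, sets the pattern."
)
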