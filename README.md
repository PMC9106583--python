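# chargeblocks

Phospho-aware charge-block analysis of intrinsically disordered protein
regions (IDRs), with saturation-concentration (C_sat) estimation from
turbidity curves for liquid–liquid phase separation (LLPS) studies.

## The scientific problem

Mitotic kinases hyperphosphorylate the disordered regions of many
nucleolar and chromosomal proteins. Each phospho-Ser/Thr adds roughly two
negative charges, and when the sites cluster, phosphorylation does not
just shift the net charge — it reshapes the *arrangement* of charges
along the chain. A disordered repeat with a basic (K/R-rich) tract
followed by a phosphosite cluster becomes, upon hyperphosphorylation, a
diblock polyampholyte: a positive charge block followed by a negative
one. Block polyampholytes phase-separate far more readily than sequences
with the same charges dispersed, so cell cycle-specific phosphorylation
can switch LLPS on (blockiness-enhancing, Ki-67-like geometry) or off
(blockiness-reducing, NPM1-like geometry, when the sites sit *inside* a
basic block and cancel it).

`chargeblocks` is a library for people who want to quantify this: it
computes windowed charge profiles under the fixed-charge rule
(R/K = +1, D/E = −1, pSer/pThr = −2), segments alternating charge
blocks, scores charge patterning, designs mutant classes in silico,
fits C_sat from turbidity titrations, and tests whether blockiness or
net charge better explains measured C_sat values.

## Statistics computed

For a sequence with per-residue charges *q_i* and a windowed profile
*s_i* (sum of charges in a *W*-residue window centred on *i*, *W* = 35
for block designation, 25 for plotting):

- **Charge block** — a maximal same-sign run of the windowed profile
  whose area under the windowed-sum plot exceeds the designation
  threshold (default 20). Block *area* is reported in windowed-mean
  units, approximately the absolute net charge the block contains.
- **B_LC** (blockiness of like charges) — the summed area of all
  designated blocks. 0 when no block is designated; grows as like
  charges cluster into long tracts.
- **D_seg** (degree of segregation) — mean squared windowed-mean charge,
  normalised by the same quantity for the fully segregated arrangement
  of the identical composition; in [0, 1].
- **SCD** (sequence charge decoration) — (1/N) Σ_{i<j} q_i q_j √(j−i).
- **κ** — blob-level charge-asymmetry patterning parameter (blob = 5),
  normalised to [0, 1] by a deterministic segregated-arrangement
  maximum.
- **C_sat** — from OD600-vs-concentration titrations via the
  four-parameter log-logistic fit
  `od(c) = baseline + od_max / (1 + (c_sat/c)^h)`, so C_sat is exactly
  the concentration at half-maximal turbidity.

## Worked example

```python
from chargeblocks import compute_report
from chargeblocks.synthetic_constructs import ki67_r12_like_unit

unit = ki67_r12_like_unit()           # 110 aa, 9 phosphosites annotated
for state in ("interphase", "mitotic"):
    rep = compute_report(unit, state=state)
    print(state, round(rep.blc, 1), round(rep.dseg, 3), rep.net_charge)
```

prints

```
interphase 31.8 0.527 17
mitotic 49.7 0.493 -1
```

Interphase: the unit carries one designated positive block (the basic
tract) and net charge +17. Mitotic: nine phosphosites add −18, the
C-terminal cluster becomes a designated negative block, and B_LC rises
from 31.8 to 49.7 — the hyperphosphorylated unit is a strong diblock
ampholyte even though its net charge is now roughly zero. The
`examples/` directory contains one short script per capability (charge
profiles, blockiness metrics, variant design, C_sat fitting, the
blockiness-vs-C_sat panel, and the proteome ΔB_LC scan), each printing
the numbers it computes and what they mean.

A thin CLI mirrors the library:

```bash
chargeblocks simulate --seed 0 --outdir bundle
chargeblocks run --fasta bundle/sequences.fasta --sites bundle/phosphosites.tsv \
    --turbidity bundle/turbidity.tsv --idr-ranges bundle/idr_ranges.tsv --outdir out
```

## Reference constructs

The published repeat-unit and mutant sequences are not redistributed
with this package.
`chargeblocks.synthetic_constructs` therefore provides clearly labelled
*synthetic* stand-ins built with the package's own design rules to the
documented constraints — a 110-aa repeat unit with 9 phosphosites (6
with the CDK1 S/T-P consensus), a charge-block mimetic analogue with net
charge +5 and B_LC ≈ 35, and a 146-aa blockiness-reducing IDR analogue.
They validate the analysis pipeline, not the published residue-level
sequences.

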