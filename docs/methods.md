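# Methods

## Charge model

Residue charges are fixed integers: Arg/Lys +1, Asp/Glu −1,
phospho-Ser/Thr −2, everything else 0. Histidine is neutral by default
(`ChargeModel(histidine_charge=...)` overrides); terminal charges are
ignored; there is no pH dependence. The −2 for a phosphosite encodes the
approximate protonation state of a phosphate monoester at neutral pH.
Phosphomimetic substitutions introduced by the variant engine are plain
glutamates or aspartates and therefore carry −1, not −2: a mimic is an
ordinary acidic residue, and only an annotated phospho-*state* yields −2.

A sequence's phospho state is carried on the record itself: the set of
annotated phosphosites (where mitotic kinases act) and the subset that is
currently phosphorylated. `set_state(seq, "mitotic")` phosphorylates all
annotated sites; `"interphase"` none. Sites must be S or T; an explicit
override accepts other residues and assigns them charge 0 when flagged
phosphorylated.

## Windowed profiles

The charge profile at window *W* (odd) assigns to each position the sum
of charges over the *W*-residue window centred there, truncated at the
termini (no padding), so every residue has a value. The effective window
length is retained, and the windowed *mean* (sum / effective length) is
the derived view used by the block-area rule. Two windows are used
throughout: 25 residues for plotting/profiles, 35 for block designation;
both are configuration keys.

## Block designation and B_LC

Maximal same-sign runs of the windowed profile are candidate blocks
(positions with exactly zero windowed charge belong to neither sign and
break runs). A run is *designated* a charge block when the area under
the windowed-sum plot across the run — Σ|s_i|, in residue·charge
plot-area units — exceeds the threshold (default 20). The *area* of a
designated block is reported in windowed-mean units (Σ|s_i / w_i|),
which for an interior block approximates the absolute net charge it
contains, and **B_LC is the summed area of all designated blocks**.

The designation-unit choice deserves a note, because the two natural
readings differ sharply. Applying the threshold of 20 to the *mean*-unit
area would require every designated block to hold ≳20 net like charges.
For a ~110-residue sequence with a small positive net charge (e.g. +5),
positive and negative block areas are then nearly balanced
(P − N ≈ net), so B_LC could only fall below ~31 (one designated block,
limited by sequence length) or above ~41 (two designated blocks, each
>20) — a structurally forbidden band in between, which contradicts
observed intermediate B_LC values around 35 for exactly such constructs.
Applying the threshold to the area under the windowed-*sum* curve (the
quantity a charge plot actually displays) designates any run with a
modest contiguous charge excess, keeps block sizes at the expected
~30–40 residues, and makes the full B_LC range realisable. The package
therefore thresholds on the plot (windowed-sum) area and reports block
areas and B_LC in mean units. `BlockinessReport.blc_formula` records the
formulation (`block-area-fallback`) in every output.

B_LC is invariant under sequence reversal and under a global sign flip
of all charges, is 0 for a charge-free sequence, and is non-decreasing
along fixed-composition segregation gradients — properties the test
suite asserts.

## D_seg

D_seg is the mean squared windowed-mean charge over all *full* windows
(window 35 by default, configurable; full windows avoid terminal
coverage artefacts), divided by the same quantity for the fully
segregated rearrangement of the identical charge multiset. The
normaliser is the maximum over a deterministic arrangement family:
positive and negative charges as contiguous blocks (sorted by magnitude)
with the neutral residues split between the left end, the middle and the
right end, scanning all splits on a grid. On small compositions this
family provably attains the maximum over *all* permutations (verified
exhaustively in the tests at length 12), so D_seg ∈ [0, 1]: a perfectly
alternating arrangement scores the minimum of its composition class and
the diblock scores 1. A charge-free sequence scores 0 by convention.

## SCD and κ

SCD is computed exactly as (1/N) Σ_{i<j} q_i q_j √(j−i) with the −2
phospho charge entering q directly. κ uses a single blob size (default
5, configurable) rather than the literature's 5/6 average: per-blob
charge asymmetry σ = (f₊ − f₋)²/(f₊ + f₋) over all sliding blobs, δ the
mean squared deviation from the global asymmetry, and κ = δ/δ_max.
δ_max comes from the same deterministic segregated-arrangement family as
the D_seg normaliser (no stochastic search); empirically κ stays within
[0, 1] across broad random sweeps, reaching exactly 1 for a fully
segregated diblock. Sequences with no charged residues (or a degenerate
normaliser, e.g. all charges of one sign) return NaN as a flagged
missing value.

## Variant engine

Mutant classes mirror the experimental design vocabulary: phosphomimetic
(annotated S/T → E, or D by flag; the positions leave the phosphosite
annotation because a mimic cannot be phosphorylated), non-phosphorylatable
(S/T → A, clearing the sites so both cell-cycle states give identical
charges), charge-block mimetic region rules (neutral → E with a stated
count, selected left to right among eligible residues and always
skipping annotated phosphosites; K/R → Q neutralising a basic region),
seeded composition-preserving shuffles (whole-sequence, with phosphosite
annotations remapped through the permutation, or charged-only), and
tandem repeats joined by the GHTEESVEDD linker with phosphosites
replicated per copy. Left-to-right selection for neutral → E is a
documented convention of this package, not a published rule. Every
variant records provenance sufficient to regenerate it exactly.

## Turbidity model and C_sat

OD600 versus concentration is fitted with the four-parameter
log-logistic `od(c) = baseline + od_max/(1 + (c_sat/c)^h)`, which makes
the fitted c_sat exactly the half-maximal concentration. Fitting uses
bounded trust-region least squares from three deterministic starts (the
interpolated half-max crossing with steepness 2 and 6, and the geometric
mean concentration with steepness 3), keeping the lowest-residual
solution; the baseline is bounded at 0. A degenerate curve (flat, all
zero, <5 points) or a c_sat outside the measured range yields
`converged=False` with a diagnostic, never an exception. An optional
residual bootstrap gives a percentile confidence interval. Fits are
performed per replicate by default; pooling is the caller's choice.

Correlation analysis reports Spearman ρ on (metric, C_sat) and Pearson r
on (metric, log C_sat), with a least-squares log-linear trend;
`compare_metrics` ranks metrics by |ρ| (ties broken alphabetically) and
flags whether a blockiness metric outranks net charge.

## ΔB_LC scan

For each protein with a user-supplied IDR range (1-based inclusive; no
disorder predictor is bundled) and mitotically up-regulated sites, B_LC
of the IDR substring is computed in both states.
|ΔB_LC| ≤ neutral band (default 1) classifies as neutral, otherwise the
sign of ΔB_LC gives blockiness-enhancing or -reducing. The scan is a
pure function of its inputs; records sort by |ΔB_LC| descending.

## Synthetic data generator

The generators emulate the target system's geometry so every stage is
testable without downloads: ~110-residue repeat units with a ~35-residue
basic tract at ~0.68 charge density, nine S/T phosphosites of which two
thirds carry the S/T-P CDK1 consensus, and a modest acidic background
(7 residues) in the phospho region so the mitotic acidic block clears
the designation threshold. Phosphosite placement selects the geometry:
`c_terminal_cluster` (blockiness-enhancing), `within_basic_block`
(blockiness-reducing; the preset analogue uses a 146-aa unit with 11
sites, a 70-residue basic tract at 0.5 density and a dense C-terminal
acidic block), or `uniform`. The neutral spacer alphabet is G/A/P/N/Q —
uncharged, non-phospho-acceptor, and free of C/W/Y so optical-labelling
concerns never arise. All generators are pure functions of
(config, seed).

Turbidity curves are simulated from the same log-logistic model
(defaults: C_sat 10 µM, steepness 4, OD_max 1.0, baseline 0.02, 12
log-spaced concentrations spanning 0.5–200 µM) with additive Gaussian
noise (default sd 0.05 OD) clamped at 0 — emulating a plate-reader
titration around a known threshold.

The planted-correlation study generates 18 constructs whose diblock core
size spans 15–35 charges per sign (so B_LC spans from sub-threshold to a
strong diblock), jitters net charge independently over [−4, +5] via
dispersed single-charge substitutions, draws
log10 C_sat = 2.0 − 0.03·B_LC + N(0, 0.15), and simulates a noisy curve
per construct. These sizes keep the full suite and the acceptance script
at a few seconds of compute while leaving comfortable statistical margin
on every assertion.

What the generator does *not* emulate: real amino-acid composition
beyond charge and phospho-acceptor placement, solution variables (salt,
crowding agent, temperature), replicate-level systematic error, droplet
morphology, or any imaging-derived quantity. Passing tests therefore
demonstrate the correctness and sensitivity of the analysis chain under
the stated charge-geometry assumptions, not biological conclusions about
any particular protein.

## Reference stand-ins

The published repeat-unit and mutant sequences are not redistributed
with this package, nor is a canonical reference form of the blockiness
equations; `synthetic_constructs` therefore ships
clearly labelled synthetic analogues generated by the package's own
rules (fixed seed, frozen as literals), and the blockiness statistics
use the block-area formulation described above, flagged in every report.
The CBm-7-style analogue is constructed at run time from the repeat-unit
stand-in via K/R → Q over residues 30–35 plus nine neutral → E
substitutions over residues 51–61, yielding net charge +5 with one
positive (area ≈ 20) and one negative (area ≈ 15) designated block,
B_LC ≈ 35 — the documented summary statistics of that mutant class.

## Numerical choices and edge cases

- Windows must be odd; profile values exist for every residue (truncated
  windows), while D_seg uses full windows only.
- Zero windowed charge breaks sign runs; it belongs to neither block.
- The D_seg/κ normaliser grids step at ~1/40 of the neutral count to
  bound cost on long sequences.
- Fit bounds: baseline ∈ [0, max OD], steepness ∈ [0.05, 50], c_sat
  within two decades of the measured range; c_sat outside the measured
  range is reported but flagged unconverged.
- Ambiguity codes map to X (charge 0) only in permissive FASTA mode;
  strict mode rejects them. X never counts as charged or phospho-capable.
- Reports serialise floats at 6 significant digits; all tables are TSV
  with headers; positions are 1-based inclusive everywhere.

## Known limitations

- The designation threshold's unit choice is an interpretation (argued
  above); `blc_formula` metadata makes downstream comparison explicit.
- κ's normaliser is a deterministic family, not a proof of the global
  maximum for every composition; extreme compositions could in principle
  exceed 1 (none observed across randomised sweeps).
- The turbidity model assumes a monotone sigmoid; re-entrant phase
  behaviour is out of scope.
- IDR boundaries are taken as given; no disorder prediction is bundled.
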