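"""Synthetic stand-in constructs for the published reference sequences.

The experimentally characterised repeat unit (Ki-67 R12), its mutant
panel (Pm9, A9, CBm series) and the NPM1 IDR are not redistributed with
this package.  This module provides SYNTHETIC analogues built to the
published design constraints —
they reproduce the documented charge geometry and summary statistics of
the real constructs, not their residue identities.  Every object here is
a synthetic stand-in and is named accordingly.

Design constraints encoded:

* ``ki67_r12_like_unit`` — 110-residue diblock-ampholyte repeat unit with
  an N-terminal basic (K/R-rich) tract and nine mitotic phosphosites
  clustered C-terminally, exactly six of which carry the minimal CDK1
  S/T-P consensus; mitotic hyperphosphorylation converts it into a strong
  diblock ampholyte (a positive block followed by a negative block).
* ``cbm7_like`` — charge-block mimetic analogue of the unit obtained with
  the package's own region rules (K/R -> Q trimming of the basic block
  plus neutral -> E substitutions at non-phosphosite positions), designed
  to the published summary of the CBm-7 mutant: interphase net charge +5
  and B_LC 35.
* ``npm1_like_idr`` — 146-residue IDR analogue whose eleven mitotic
  phosphosites sit inside the basic tract, so hyperphosphorylation
  *reduces* charge blockiness (the blockiness-reducing geometry).

The units were generated once with :func:`chargeblocks.simulate.gen_diblock_unit`
at a fixed seed and are frozen here as literals for stability.
"""

from __future__ import annotations

from .sequences import AnnotatedSequence, PhosphositeTable
from .variants import VariantRecord, apply_region_rule

#: 110-aa synthetic Ki-67 R12-like repeat unit
#: (gen_diblock_unit(GeneratorConfig(seed=0)), frozen)
_R12_LIKE_RESIDUES = (
    "QKRAKGKGGRNQKRRRKRPRRKRRRKRRRNKGGKRPGAPPPGGGGNPNANNAPQQQANQNQ"
    "NNAQGPNQPAAPPNTPDPSPPESPPPSPAETPANESPDETNEATQGGSA"
)
#: nine mitotic phosphosites; the first six are followed by Pro (S/T-P)
_R12_LIKE_SITES = (76, 80, 84, 88, 92, 97, 101, 105, 109)

#: 146-aa synthetic NPM1-IDR-like sequence with phosphosites inside the
#: basic tract (gen_diblock_unit at seed 0, within_basic_block geometry)
_NPM1_LIKE_RESIDUES = (
    "KRSPKGGKGRSPKTPRKRPKARKGKQKRNKSPTPGKSPKRKKTPKNKSANKARKSQKNQKRKRAKKKRST"
    "AAPPNQGQPANPAANPPANAAQAANNDEDQENAENQGGNEEEQEDENEEGEEQEQGDEEAQNQDNDGENE"
    "ENNQPE"
)
_NPM1_LIKE_SITES = (3, 11, 14, 31, 33, 37, 43, 48, 55, 69, 70)

KI67_LIKE_ID = "synthetic-R12-like"
NPM1_LIKE_ID = "synthetic-NPM1-IDR-like"


def ki67_r12_like_unit() -> AnnotatedSequence:
    """Synthetic 110-aa R12-like repeat unit with its 9 phosphosites annotated."""
    return AnnotatedSequence(
        id=KI67_LIKE_ID,
        residues=_R12_LIKE_RESIDUES,
        phosphosites=frozenset(_R12_LIKE_SITES),
        description="synthetic Ki-67 R12-like diblock repeat unit (stand-in)",
    )


def ki67_r12_like_sites() -> PhosphositeTable:
    """Phosphosite annotation table for the R12-like unit (all mitotic 'up')."""
    seq = _R12_LIKE_RESIDUES
    return PhosphositeTable.from_rows(
        [(KI67_LIKE_ID, p, seq[p - 1], "up") for p in _R12_LIKE_SITES]
    )


def cbm7_like() -> VariantRecord:
    """Synthetic charge-block mimetic analogue of the CBm-7 design.

    Built at run time from the R12-like unit with the package's region
    rules: K/R -> Q over residues 30-35 (trims the basic block) followed
    by 9 neutral -> E substitutions over residues 51-61 at non-phosphosite
    positions (builds a mid-sequence acidic block).  The resulting
    unphosphorylated form has net charge +5 and B_LC ~= 35, the published
    summary statistics of the CBm-7 mutant.
    """
    unit = ki67_r12_like_unit()
    step1 = apply_region_rule(unit, (30, 35), "KR_to_Q")
    step2 = apply_region_rule(
        step1.sequence, (51, 61), "neutral_to_E", count=9, name="synthetic-CBm-7-like"
    )
    return VariantRecord(
        parent_id=unit.id,
        name="CBm-7-like",
        sequence=step2.sequence,
        provenance={
            "rule": "cbm",
            "steps": [step1.provenance, step2.provenance],
        },
    )


def npm1_like_idr() -> AnnotatedSequence:
    """Synthetic NPM1-IDR-like sequence (blockiness-reducing geometry)."""
    return AnnotatedSequence(
        id=NPM1_LIKE_ID,
        residues=_NPM1_LIKE_RESIDUES,
        phosphosites=frozenset(_NPM1_LIKE_SITES),
        description="synthetic NPM1 IDR-like sequence (stand-in)",
    )


def npm1_like_sites() -> PhosphositeTable:
    seq = _NPM1_LIKE_RESIDUES
    return PhosphositeTable.from_rows(
        [(NPM1_LIKE_ID, p, seq[p - 1], "up") for p in _NPM1_LIKE_SITES]
    )
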