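"""In-silico construction of charge-pattern variants.

Implements the mutant classes used to dissect charge-blockiness effects on
phase separation:

* phosphomimetic variants (annotated S/T phosphosites replaced by E or D,
  mimicking the phosphorylated charge state with an ordinary -1 acidic
  residue),
* non-phosphorylatable variants (S/T -> A, abolishing phosphorylation),
* charge-block mimetic region rules (neutral -> E to build an acidic
  block, K/R -> Q to neutralise a basic block),
* composition-preserving charge shuffles (segregation-destroying
  controls), and
* tandem repeats joined by the GHTEESVEDD linker used for homogeneous
  repeat constructs.

Every variant carries provenance sufficient to regenerate it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .charge import ChargeModel, DEFAULT_MODEL
from .sequences import (
    AnnotatedSequence,
    MutationSpec,
    PointRule,
    RegionRule,
    SequenceError,
)

TANDEM_LINKER = "GHTEESVEDD"


@dataclass(frozen=True)
class VariantRecord:
    parent_id: str
    name: str
    sequence: AnnotatedSequence
    provenance: dict = field(default_factory=dict)


def _mutate(residues: str, changes: dict[int, str]) -> str:
    chars = list(residues)
    for pos, new in changes.items():
        chars[pos - 1] = new
    return "".join(chars)


def apply_phosphomimetic(
    seq: AnnotatedSequence,
    sites: frozenset[int] | None = None,
    target: Literal["E", "D"] = "E",
    name: str | None = None,
) -> VariantRecord:
    """Replace phospho-accepting S/T sites by an acidic residue.

    The mimic carries an ordinary -1 charge (it is a plain glutamate or
    aspartate, not a phosphate), and the mutated positions are removed
    from the phosphosite annotation — a mimic cannot be phosphorylated.
    Defaults to all annotated sites.
    """
    positions = frozenset(seq.phosphosites if sites is None else sites)
    for pos in positions:
        if seq.residue_at(pos) not in ("S", "T"):
            raise SequenceError(
                f"phosphomimetic site {pos} is {seq.residue_at(pos)}, not S/T"
            )
    mutated = _mutate(seq.residues, {p: target for p in positions})
    new_seq = AnnotatedSequence(
        id=f"{seq.id}|Pm{len(positions)}" if name is None else name,
        residues=mutated,
        phosphosites=seq.phosphosites - positions,
        phosphorylated=seq.phosphorylated - positions,
        description=seq.description,
        allow_non_st=seq.allow_non_st,
    )
    return VariantRecord(
        parent_id=seq.id,
        name=name or f"Pm{len(positions)}",
        sequence=new_seq,
        provenance={"rule": "phosphomimetic", "sites": sorted(positions), "target": target},
    )


def apply_nonphospho(
    seq: AnnotatedSequence,
    sites: frozenset[int] | None = None,
    name: str | None = None,
) -> VariantRecord:
    """Replace phospho-accepting S/T sites by alanine (non-phosphorylatable).

    The listed positions are cleared from the annotation, so the mitotic
    and interphase forms of the variant carry identical charges.
    """
    positions = frozenset(seq.phosphosites if sites is None else sites)
    for pos in positions:
        if seq.residue_at(pos) not in ("S", "T"):
            raise SequenceError(
                f"alanine-substitution site {pos} is {seq.residue_at(pos)}, not S/T"
            )
    mutated = _mutate(seq.residues, {p: "A" for p in positions})
    new_seq = AnnotatedSequence(
        id=f"{seq.id}|A{len(positions)}" if name is None else name,
        residues=mutated,
        phosphosites=seq.phosphosites - positions,
        phosphorylated=seq.phosphorylated - positions,
        description=seq.description,
        allow_non_st=seq.allow_non_st,
    )
    return VariantRecord(
        parent_id=seq.id,
        name=name or f"A{len(positions)}",
        sequence=new_seq,
        provenance={"rule": "nonphospho", "sites": sorted(positions)},
    )


#: residues eligible for neutral -> E substitution (charge 0, not phospho-capable
#: positions are additionally excluded at application time)
_NEUTRAL_FOR_E = frozenset("GSTANPQVLIMFWYCH")


def apply_region_rule(
    seq: AnnotatedSequence,
    region: tuple[int, int],
    rule_kind: str,
    count: int | None = None,
    name: str | None = None,
    model: ChargeModel = DEFAULT_MODEL,
) -> VariantRecord:
    """Apply a charge-block mimetic region rule.

    ``neutral_to_E`` replaces ``count`` neutral residues (left to right,
    skipping annotated phosphosites so the phospho-regulatory positions
    stay untouched) with glutamate; ``KR_to_Q`` neutralises every K/R in
    the region; ``ST_to_A`` / ``ST_to_E`` act on annotated phosphosites
    inside the region.
    """
    start, end = region
    rule = RegionRule(start, end, rule_kind, count)
    MutationSpec((rule,)).validate_against(seq)
    changes: dict[int, str] = {}
    sites_to_clear: set[int] = set()
    if rule_kind == "neutral_to_E":
        if count is None:
            raise SequenceError("neutral_to_E requires a substitution count")
        eligible = [
            p
            for p in range(start, end + 1)
            if seq.residues[p - 1] in _NEUTRAL_FOR_E and p not in seq.phosphosites
        ]
        if len(eligible) < count:
            raise SequenceError(
                f"region {start}-{end} has only {len(eligible)} eligible neutral "
                f"residues, {count} requested"
            )
        changes = {p: "E" for p in eligible[:count]}
    elif rule_kind == "KR_to_Q":
        changes = {
            p: "Q" for p in range(start, end + 1) if seq.residues[p - 1] in ("K", "R")
        }
    elif rule_kind in ("ST_to_A", "ST_to_E"):
        target = "A" if rule_kind == "ST_to_A" else "E"
        sites_in = [p for p in sorted(seq.phosphosites) if start <= p <= end]
        changes = {p: target for p in sites_in}
        sites_to_clear = set(sites_in)
    mutated = _mutate(seq.residues, changes)
    new_seq = AnnotatedSequence(
        id=f"{seq.id}|{rule_kind}:{start}-{end}" if name is None else name,
        residues=mutated,
        phosphosites=seq.phosphosites - sites_to_clear,
        phosphorylated=seq.phosphorylated - sites_to_clear,
        description=seq.description,
        allow_non_st=seq.allow_non_st,
    )
    return VariantRecord(
        parent_id=seq.id,
        name=name or f"{rule_kind}:{start}-{end}",
        sequence=new_seq,
        provenance={
            "rule": rule_kind,
            "region": [start, end],
            "count": count,
            "positions": sorted(changes),
        },
    )


def shuffle_charges(
    seq: AnnotatedSequence,
    seed: int,
    mode: Literal["all_residues", "charged_only"] = "all_residues",
    model: ChargeModel = DEFAULT_MODEL,
) -> VariantRecord:
    """Composition-preserving shuffle destroying charge segregation.

    ``all_residues`` permutes the entire sequence (phosphosite annotations
    are remapped through the permutation); ``charged_only`` permutes the
    charged residues among the charged positions, leaving neutral residues
    — including unphosphorylated S/T sites — in place.
    """
    rng = np.random.default_rng(seed)
    chars = list(seq.residues)
    if mode == "all_residues":
        perm = rng.permutation(len(chars))
        shuffled = "".join(chars[i] for i in perm)
        # new position (1-based) of the residue that was at old position i+1
        new_pos = {int(old) + 1: int(new) + 1 for new, old in enumerate(perm)}
        sites = frozenset(new_pos[p] for p in seq.phosphosites)
        phos = frozenset(new_pos[p] for p in seq.phosphorylated)
    elif mode == "charged_only":
        q = model.charge_array(seq.replace(phosphorylated=frozenset()))
        charged_idx = np.flatnonzero(q != 0)
        perm = rng.permutation(len(charged_idx))
        residues_at = [chars[i] for i in charged_idx]
        for slot, take in zip(charged_idx, perm):
            chars[slot] = residues_at[take]
        shuffled = "".join(chars)
        sites = seq.phosphosites
        phos = seq.phosphorylated
    else:
        raise SequenceError(f"unknown shuffle mode {mode!r}")
    new_seq = AnnotatedSequence(
        id=f"{seq.id}|shuffle-{mode}-seed{seed}",
        residues=shuffled,
        phosphosites=sites,
        phosphorylated=phos,
        description=seq.description,
        allow_non_st=seq.allow_non_st,
    )
    return VariantRecord(
        parent_id=seq.id,
        name=f"shuffle-seed-{seed}",
        sequence=new_seq,
        provenance={"rule": "shuffle", "mode": mode, "seed": seed},
    )


def build_tandem(
    unit: AnnotatedSequence,
    n: int,
    linker: str = TANDEM_LINKER,
    name: str | None = None,
) -> VariantRecord:
    """Join ``n`` copies of a repeat unit with a linker between copies.

    Unit phosphosite annotations are replicated into every copy with the
    appropriate offsets; the linker itself carries no sites.  ``n = 1``
    returns the unit unchanged (no linker).
    """
    if not 1 <= n <= 16:
        raise SequenceError(f"tandem copy number must be in [1, 16], got {n}")
    unit_len = len(unit)
    period = unit_len + len(linker)
    residues = linker.join([unit.residues] * n)
    sites = frozenset(
        p + k * period for k in range(n) for p in unit.phosphosites
    )
    phos = frozenset(
        p + k * period for k in range(n) for p in unit.phosphorylated
    )
    new_seq = AnnotatedSequence(
        id=f"({unit.id})_{n}" if name is None else name,
        residues=residues,
        phosphosites=sites,
        phosphorylated=phos,
        description=unit.description,
        allow_non_st=unit.allow_non_st,
    )
    return VariantRecord(
        parent_id=unit.id,
        name=name or f"({unit.id})_{n}",
        sequence=new_seq,
        provenance={"rule": "tandem", "n": n, "linker": linker},
    )
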