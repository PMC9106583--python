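"""Variant construction: phosphomimetic, non-phosphorylatable, region
rules, shuffles and tandem repeats."""

from collections import Counter

import numpy as np
import pytest

from chargeblocks import (
    AnnotatedSequence,
    apply_nonphospho,
    apply_phosphomimetic,
    apply_region_rule,
    build_tandem,
    compute_blc,
    net_charge,
    shuffle_charges,
)
from chargeblocks.sequences import SequenceError
from chargeblocks.variants import TANDEM_LINKER


class TestPhosphomimetic:
    def test_net_charge_drops_by_site_count(self, r12_like):
        pm = apply_phosphomimetic(r12_like)
        assert net_charge(pm.sequence, "interphase") == net_charge(
            r12_like, "interphase"
        ) - 9

    def test_mimic_positions_no_longer_sites(self, r12_like):
        pm = apply_phosphomimetic(r12_like)
        assert pm.sequence.phosphosites == frozenset()
        for pos in r12_like.phosphosites:
            assert pm.sequence.residue_at(pos) == "E"

    def test_empty_site_list_is_noop(self, r12_like):
        pm = apply_phosphomimetic(r12_like, sites=frozenset())
        assert pm.sequence.residues == r12_like.residues

    def test_reapplication_is_noop(self, r12_like):
        once = apply_phosphomimetic(r12_like)
        twice = apply_phosphomimetic(once.sequence)
        assert twice.sequence.residues == once.sequence.residues

    def test_aspartate_target(self, r12_like):
        pm = apply_phosphomimetic(r12_like, target="D")
        pos = next(iter(r12_like.phosphosites))
        assert pm.sequence.residue_at(pos) == "D"

    def test_non_st_site_rejected(self):
        seq = AnnotatedSequence(id="x", residues="GGGG")
        with pytest.raises(SequenceError, match="not S/T"):
            apply_phosphomimetic(seq, sites=frozenset({1}))


class TestNonPhospho:
    def test_states_become_equivalent(self, r12_like):
        a9 = apply_nonphospho(r12_like).sequence
        assert compute_blc(a9, "mitotic") == pytest.approx(
            compute_blc(a9, "interphase")
        )

    def test_net_charge_unchanged_vs_interphase_wt(self, r12_like):
        a9 = apply_nonphospho(r12_like).sequence
        assert net_charge(a9, "interphase") == net_charge(r12_like, "interphase")

    def test_empty_list_is_noop(self, r12_like):
        rec = apply_nonphospho(r12_like, sites=frozenset())
        assert rec.sequence.residues == r12_like.residues


class TestRegionRules:
    def test_kr_to_q_drops_net_charge_by_kr_count(self):
        seq = AnnotatedSequence(id="x", residues="GKRKGRGG" + "G" * 20)
        rec = apply_region_rule(seq, (1, 8), "KR_to_Q")
        assert net_charge(rec.sequence) == net_charge(seq) - 4
        assert "K" not in rec.sequence.residues[:8]

    def test_neutral_to_e_count_zero_is_noop(self, r12_like):
        rec = apply_region_rule(r12_like, (40, 60), "neutral_to_E", count=0)
        assert rec.sequence.residues == r12_like.residues

    def test_neutral_to_e_skips_phosphosites(self, r12_like):
        rec = apply_region_rule(r12_like, (70, 110), "neutral_to_E", count=5)
        for pos in r12_like.phosphosites:
            assert rec.sequence.residue_at(pos) == r12_like.residue_at(pos)
        assert net_charge(rec.sequence) == net_charge(r12_like, "interphase") - 5

    def test_neutral_to_e_mid_region_raises_blc(self, r12_like):
        # mimics a phosphorylated charge block built from neutral residues
        rec = apply_region_rule(r12_like, (45, 75), "neutral_to_E", count=14)
        assert compute_blc(rec.sequence, "interphase") > compute_blc(
            r12_like, "interphase"
        )

    def test_insufficient_eligible_residues(self):
        seq = AnnotatedSequence(id="x", residues="KR" * 20)
        with pytest.raises(SequenceError, match="eligible"):
            apply_region_rule(seq, (1, 10), "neutral_to_E", count=5)

    def test_st_to_a_clears_sites_in_region(self, r12_like):
        rec = apply_region_rule(r12_like, (70, 95), "ST_to_A")
        kept = {p for p in r12_like.phosphosites if not 70 <= p <= 95}
        assert rec.sequence.phosphosites == frozenset(kept)


class TestShuffle:
    def test_same_seed_identical(self, diblock_unit):
        a = shuffle_charges(diblock_unit, seed=42).sequence
        b = shuffle_charges(diblock_unit, seed=42).sequence
        assert a.residues == b.residues and a.phosphosites == b.phosphosites

    def test_composition_preserved(self, diblock_unit):
        shuffled = shuffle_charges(diblock_unit, seed=1).sequence
        assert Counter(shuffled.residues) == Counter(diblock_unit.residues)

    def test_charged_only_keeps_neutral_positions(self, diblock_unit):
        shuffled = shuffle_charges(diblock_unit, seed=1, mode="charged_only").sequence
        for i, (a, b) in enumerate(zip(diblock_unit.residues, shuffled.residues)):
            if a not in "KRDE":
                assert a == b
        assert shuffled.phosphosites == diblock_unit.phosphosites

    def test_sites_remapped_to_same_residues(self, r12_like):
        shuffled = shuffle_charges(r12_like, seed=3).sequence
        assert len(shuffled.phosphosites) == 9
        for pos in shuffled.phosphosites:
            assert shuffled.residue_at(pos) in "ST"

    def test_shuffling_destroys_segregation(self):
        base = AnnotatedSequence(
            id="d", residues="E" * 30 + "G" * 20 + "K" * 30 + "A" * 30
        )
        b0 = compute_blc(base)
        shuffled = [
            compute_blc(shuffle_charges(base, seed=s).sequence) for s in range(50)
        ]
        assert float(np.mean(shuffled)) < b0


class TestTandem:
    def test_single_copy_unchanged(self, r12_like):
        rec = build_tandem(r12_like, 1)
        assert rec.sequence.residues == r12_like.residues

    def test_two_copies_length(self, r12_like):
        rec = build_tandem(r12_like, 2)
        assert len(rec.sequence) == 2 * 110 + 10
        assert TANDEM_LINKER in rec.sequence.residues

    def test_twelve_copies_replicate_sites(self, r12_like):
        rec = build_tandem(r12_like, 12)
        assert len(rec.sequence.phosphosites) == 9 * 12
        for pos in rec.sequence.phosphosites:
            assert rec.sequence.residue_at(pos) in "ST"

    def test_copy_number_bounds(self, r12_like):
        with pytest.raises(SequenceError, match="copy number"):
            build_tandem(r12_like, 0)


class TestReversalCommutation:
    def test_phosphomimetic_commutes_with_reversal(self, r12_like):
        n = len(r12_like)
        reflected_sites = frozenset(n + 1 - p for p in r12_like.phosphosites)
        rev = AnnotatedSequence(
            id="rev", residues=r12_like.residues[::-1], phosphosites=reflected_sites
        )
        pm_then_rev = apply_phosphomimetic(r12_like).sequence.residues[::-1]
        rev_then_pm = apply_phosphomimetic(rev).sequence.residues
        assert pm_then_rev == rev_then_pm
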