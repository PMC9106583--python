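"""Charge-block segmentation and the patterning statistics B_LC, D_seg,
SCD and kappa."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from chargeblocks import (
    AnnotatedSequence,
    block_census,
    charge_profile,
    compute_blc,
    compute_dseg,
    compute_kappa,
    compute_report,
    compute_scd,
    segment_blocks,
    shuffle_charges,
)
from chargeblocks.blockiness import BLC_FORMULA, _mean_square_windowed
from chargeblocks.charge import ChargeError, DEFAULT_MODEL


def scd_oracle(charges):
    """O(N^2) double loop straight from the definition."""
    n = len(charges)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += charges[i] * charges[j] * math.sqrt(j - i)
    return total / n


def flip_charges(residues):
    table = str.maketrans("KRDE", "EDRK")
    return residues.translate(table)


class TestSegmentBlocks:
    def test_all_neutral_empty(self):
        seq = AnnotatedSequence(id="n", residues="GANQP" * 20)
        prof = charge_profile(seq, window=35)
        assert segment_blocks(prof) == []

    def test_diblock_areas_match_direct_computation(self):
        seq = AnnotatedSequence(id="d", residues="E" * 60 + "K" * 60)
        prof = charge_profile(seq, window=35)
        blocks = segment_blocks(prof)
        assert [b.sign for b in blocks] == ["-", "+"]
        means = prof.means
        for b in blocks:
            assert b.area == pytest.approx(
                float(np.abs(means[b.start - 1 : b.end]).sum())
            )
        # each block holds most of its 60 like charges
        assert all(b.area > 45 for b in blocks)

    def test_threshold_must_be_positive(self):
        seq = AnnotatedSequence(id="d", residues="E" * 40 + "K" * 40)
        prof = charge_profile(seq, window=35)
        with pytest.raises(ValueError, match="threshold"):
            segment_blocks(prof, threshold=0)

    def test_r12_like_mitotic_is_positive_then_negative_diblock(self, r12_like):
        prof = charge_profile(r12_like, window=35, state="mitotic")
        blocks = segment_blocks(prof)
        assert [b.sign for b in blocks] == ["+", "-"]

    def test_census(self):
        seq = AnnotatedSequence(
            id="t", residues="K" * 40 + "GANQP" * 8 + "E" * 40
        )
        blocks = segment_blocks(charge_profile(seq, window=35))
        n_pos, n_neg, mean_size = block_census(blocks)
        assert (n_pos, n_neg) == (1, 1)
        assert mean_size > 0

    def test_census_empty(self):
        n_pos, n_neg, mean_size = block_census([])
        assert (n_pos, n_neg) == (0, 0)
        assert math.isnan(mean_size)


class TestBlc:
    def test_charge_free_is_zero(self):
        seq = AnnotatedSequence(id="n", residues="G" * 120)
        assert compute_blc(seq) == 0.0

    def test_too_short_is_error(self):
        seq = AnnotatedSequence(id="s", residues="KE" * 10)
        with pytest.raises(ChargeError, match="shorter"):
            compute_blc(seq)

    def test_sign_flip_invariance(self, random_sequences):
        for seq in random_sequences(10, min_len=60, max_len=120, seed=3):
            flipped = AnnotatedSequence(id="f", residues=flip_charges(seq.residues))
            assert compute_blc(seq) == pytest.approx(compute_blc(flipped))

    def test_reversal_invariance(self, random_sequences):
        for seq in random_sequences(10, min_len=60, max_len=120, seed=4):
            rev = AnnotatedSequence(id="r", residues=seq.residues[::-1])
            assert compute_blc(seq) == pytest.approx(compute_blc(rev))

    def test_progressive_segregation_non_decreasing(self):
        # same composition (24 E, 24 K, 52 neutral), increasingly segregated
        values = []
        for core in (0, 4, 8, 12, 16, 20, 24):
            rest = 24 - core
            middle = "E" * core + "EK" * rest + "K" * core
            seq = AnnotatedSequence(id=f"c{core}", residues="G" * 26 + middle + "A" * 26)
            values.append(compute_blc(seq))
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] > values[0]

    def test_report_flags_formula(self, r12_like):
        rep = compute_report(r12_like, state="mitotic")
        assert rep.blc_formula == BLC_FORMULA
        assert rep.blc == pytest.approx(compute_blc(r12_like, state="mitotic"))


class TestDseg:
    @pytest.mark.parametrize("n_pairs", [3, 4, 5])
    def test_exhaustive_extremes_over_permutations(self, n_pairs):
        """Alternating is the minimum and the diblock the maximum of the
        composition class, checked against every distinct arrangement."""
        window = 5
        items = [1] * n_pairs + [-1] * n_pairs
        seen = set()
        values = {}
        for perm in itertools.permutations(items):
            if perm in seen:
                continue
            seen.add(perm)
            values[perm] = _mean_square_windowed(np.array(perm), window)
        alternating = tuple([1, -1] * n_pairs)
        diblock = tuple([1] * n_pairs + [-1] * n_pairs)
        assert values[alternating] == pytest.approx(min(values.values()))
        assert values[diblock] == pytest.approx(max(values.values()))

    def test_fully_segregated_scores_one(self):
        seq = AnnotatedSequence(id="d", residues="E" * 55 + "K" * 55)
        assert compute_dseg(seq) == pytest.approx(1.0)

    def test_alternating_scores_near_zero(self):
        seq = AnnotatedSequence(id="a", residues="EK" * 55)
        assert compute_dseg(seq) < 0.05

    def test_charge_free_is_zero(self):
        seq = AnnotatedSequence(id="n", residues="G" * 60)
        assert compute_dseg(seq) == 0.0

    def test_bounded_by_unit_interval(self, random_sequences):
        for seq in random_sequences(40, min_len=40, max_len=120, seed=6):
            d = compute_dseg(seq)
            assert 0.0 <= d <= 1.0 + 1e-12

    def test_small_window_override(self):
        seq = AnnotatedSequence(id="s", residues="EEEKKK")
        assert compute_dseg(seq, window=3) == pytest.approx(1.0)


class TestScd:
    def test_all_neutral_zero(self):
        seq = AnnotatedSequence(id="n", residues="GGGG")
        assert compute_scd(seq) == 0.0

    def test_ek_hand_value(self):
        seq = AnnotatedSequence(id="x", residues="EK")
        assert compute_scd(seq) == pytest.approx(-0.5)

    def test_matches_double_loop_oracle(self, random_sequences):
        model = DEFAULT_MODEL
        for seq in random_sequences(25, min_len=10, max_len=60, seed=8):
            q = model.charge_array(seq).tolist()
            assert compute_scd(seq) == pytest.approx(scd_oracle(q), abs=1e-9)

    def test_sign_flip_invariance(self, random_sequences):
        for seq in random_sequences(10, seed=9):
            flipped = AnnotatedSequence(id="f", residues=flip_charges(seq.residues))
            assert compute_scd(seq) == pytest.approx(compute_scd(flipped))


class TestKappa:
    def test_fully_segregated_is_one(self):
        seq = AnnotatedSequence(id="d", residues="E" * 25 + "K" * 25)
        assert compute_kappa(seq) == pytest.approx(1.0)

    def test_alternating_below_segregated(self):
        alt = AnnotatedSequence(id="a", residues="EK" * 25)
        seg = AnnotatedSequence(id="s", residues="E" * 25 + "K" * 25)
        assert compute_kappa(alt) < compute_kappa(seg)
        assert compute_kappa(alt) < 0.05

    def test_unit_interval_sweep(self, random_sequences):
        for seq in random_sequences(60, min_len=20, max_len=50, seed=10):
            k = compute_kappa(seq)
            if not math.isnan(k):
                assert 0.0 <= k <= 1.0 + 1e-12

    def test_no_charges_flagged_missing(self):
        seq = AnnotatedSequence(id="n", residues="GGGGGGGG")
        assert math.isnan(compute_kappa(seq))

    def test_reversal_invariance(self, random_sequences):
        for seq in random_sequences(10, min_len=20, max_len=50, seed=12):
            rev = AnnotatedSequence(id="r", residues=seq.residues[::-1])
            a, b = compute_kappa(seq), compute_kappa(rev)
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(b)


class TestMetricRelationships:
    def test_blc_and_dseg_rank_correlate_over_shuffles(self):
        base = AnnotatedSequence(
            id="d", residues="E" * 30 + "G" * 15 + "K" * 30 + "A" * 15
        )
        blcs, dsegs = [], []
        for seed in range(40):
            seq = shuffle_charges(base, seed=seed).sequence
            blcs.append(compute_blc(seq))
            dsegs.append(compute_dseg(seq))
        rho, _ = stats.spearmanr(blcs, dsegs)
        assert rho > 0.5

    def test_phospho_geometry_sets_direction_of_blc_change(
        self, r12_like, npm1_like
    ):
        assert compute_blc(r12_like, "mitotic") > compute_blc(r12_like, "interphase")
        assert compute_blc(npm1_like, "mitotic") < compute_blc(npm1_like, "interphase")
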