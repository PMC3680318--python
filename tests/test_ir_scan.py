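import numpy as np
import pytest

from mitescout.errors import ParameterError
from mitescout.ir_scan import (
    ScanParams,
    brute_force_ir,
    find_inverted_repeats,
    is_simple_arm,
    mask_low_complexity,
)
from mitescout.sequence_model import reverse_complement

from conftest import random_seq


def coord_set(pairs):
    return {p.coords() for p in pairs}


class TestIsSimpleArm:
    @pytest.mark.parametrize(
        "arm,expected",
        [
            ("ATATATATAT", True),  # dinucleotide run
            ("GCCGGCGCCG", True),  # G/C-only
            ("GATTACAGAT", False),
            ("AAAAAAAA", True),  # homopolymer
            ("ACACACACA", True),  # period 2 with trailing partial
            ("AGAGAGAG", True),
            ("ACGTACGT", False),  # period 4 is not simple
            ("GANTC", True),  # N makes it unusable
        ],
    )
    def test_examples(self, arm, expected):
        assert is_simple_arm(arm) is expected

    def test_empty_raises(self):
        with pytest.raises(ParameterError):
            is_simple_arm("")


class TestMaskLowComplexity:
    def test_homopolymer_fully_masked(self):
        assert mask_low_complexity("A" * 200) == "N" * 200

    def test_dinucleotide_masked(self):
        assert mask_low_complexity("AT" * 100) == "N" * 200

    def test_max_entropy_unchanged(self):
        s = "ACGT" * 50
        assert mask_low_complexity(s) == s

    def test_random_mostly_unmasked(self, rng):
        s = random_seq(rng, 200)
        masked = mask_low_complexity(s)
        assert masked.count("N") - s.count("N") < 0.05 * len(s)

    def test_length_preserved(self, rng):
        s = random_seq(rng, 137) + "A" * 90 + random_seq(rng, 41)
        assert len(mask_low_complexity(s)) == len(s)


class TestScanParams:
    def test_validation(self):
        with pytest.raises(ParameterError):
            ScanParams(min_element_len=0)
        with pytest.raises(ParameterError):
            ScanParams(min_element_len=800, max_element_len=50)
        with pytest.raises(ParameterError):
            ScanParams(min_arm_len=40, min_element_len=50)

    def test_sensitivity_levels(self):
        assert ScanParams.from_sensitivity("high").seed_len < ScanParams().seed_len


class TestFindInvertedRepeats:
    def test_planted_construct(self, rng):
        arm = "GATTACAGATCA"  # 12 nt, not simple
        interior = random_seq(rng, 80)
        seq = random_seq(rng, 60) + arm + interior + reverse_complement(arm) + random_seq(rng, 60)
        pairs = find_inverted_repeats(seq)
        covering = [
            p
            for p in pairs
            if p.left_start <= 60 + len(arm) and p.right_end >= 60 + len(arm) + 80
        ]
        assert covering, "planted inverted repeat not found"
        assert all(p.arm_len >= 10 for p in covering)
        assert coord_set(pairs) == coord_set(brute_force_ir(seq))

    def test_random_matches_oracle(self, rng):
        for _ in range(5):
            s = random_seq(rng, 500)
            assert coord_set(find_inverted_repeats(s)) == coord_set(brute_force_ir(s))

    def test_short_slice_empty(self):
        assert find_inverted_repeats("ACGT" * 10) == []

    def test_homopolymer_rejected(self):
        assert find_inverted_repeats("A" * 600) == []
        assert brute_force_ir("A" * 600) == []

    def test_perfect_palindrome(self, rng):
        half = random_seq(rng, 30)
        seq = half + reverse_complement(half)
        pairs = brute_force_ir(seq)
        assert any(p.element_length == 60 and p.arm_len == 30 for p in pairs)

    def test_element_length_bounds(self, rng):
        params = ScanParams()
        for _ in range(3):
            s = random_seq(rng, 1500)
            for p in find_inverted_repeats(s, params):
                assert params.min_element_len <= p.element_length <= params.max_element_len
                assert p.left_end <= p.right_start
                assert p.arm_len >= params.min_arm_len
                assert p.arm_identity >= params.min_arm_identity - 1e-9

    def test_no_simple_arms_in_output(self, rng):
        s = "AT" * 100 + random_seq(rng, 300) + "GC" * 80
        for p in find_inverted_repeats(s):
            assert not is_simple_arm(s[p.left_start : p.left_end])
            assert not is_simple_arm(s[p.right_start : p.right_end])

    def test_deterministic(self, rng):
        s = random_seq(rng, 1000)
        assert find_inverted_repeats(s) == find_inverted_repeats(s)

    def test_reverse_complement_reflection(self, rng):
        """Scanning the reverse complement yields the same pairs with
        coordinates reflected (the arm pair maps onto itself, arms swapped)."""
        for _ in range(5):
            arm = random_seq(rng, 14)
            s = (
                random_seq(rng, 40)
                + arm
                + random_seq(rng, 70)
                + reverse_complement(arm)
                + random_seq(rng, 40)
            )
            n = len(s)
            fwd = coord_set(find_inverted_repeats(s))
            rc = coord_set(find_inverted_repeats(reverse_complement(s)))
            reflected = {
                (n - re, n - rs, n - le, n - ls) for (ls, le, rs, re) in fwd
            }
            assert rc == reflected

    def test_n_in_arms_excluded(self, rng):
        arm = "GATTACAGATCA"
        seq = (
            random_seq(rng, 30)
            + arm[:6] + "N" + arm[7:]
            + random_seq(rng, 80)
            + reverse_complement(arm)
            + random_seq(rng, 30)
        )
        for p in find_inverted_repeats(seq):
            assert "N" not in seq[p.left_start : p.left_end]
            assert "N" not in seq[p.right_start : p.right_end]


class TestBruteForce:
    def test_size_cap(self):
        with pytest.raises(ParameterError):
            brute_force_ir("A" * 2001)

    def test_agreement_mixed_adversarial(self, rng):
        for _ in range(5):
            arm = random_seq(rng, 16)
            inner = random_seq(rng, 10)
            nested = (
                arm
                + random_seq(rng, 20)
                + inner
                + random_seq(rng, 40)
                + reverse_complement(inner)
                + random_seq(rng, 20)
                + reverse_complement(arm)
            )
            s = random_seq(rng, 50) + nested + random_seq(rng, 50)
            assert coord_set(find_inverted_repeats(s)) == coord_set(brute_force_ir(s))
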