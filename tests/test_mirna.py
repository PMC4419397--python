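"""miRNA normalization, duplex construction, rule engine and energies."""

import itertools
import math

import numpy as np
import pytest

from anser.mirna import (DUPLEX_INIT, STACK_TABLE, DuplexAlignment, PairState,
                         check_rules, fold_change, mismatch_score,
                         normalize_expression, pair_duplex,
                         reverse_complement, scan_targets, stack_energy,
                         states_of)

WC, GU, MM = PairState.WATSON_CRICK, PairState.GU, PairState.MISMATCH


def build_sequences(states: list[PairState]) -> tuple[str, str]:
    """Realize an arbitrary pair-state vector as concrete sequences."""
    mirna, site_rev = [], []
    for st in states:
        if st is WC:
            mirna.append("A"); site_rev.append("U")
        elif st is GU:
            mirna.append("U"); site_rev.append("G")
        else:
            mirna.append("A"); site_rev.append("A")
    return "".join(mirna), "".join(reversed(site_rev))


def literal_verdicts(states, mfe, mfe_perfect, gu_strict=False):
    """Independent, literal transcription of the six rules."""
    score = {WC: 0.0, GU: 0.5, MM: 1.0}
    s = [score[x] for x in states]
    mm = [x is MM or (gu_strict and x is GU) for x in states]
    L = len(states)
    r1 = sum(s) <= 4
    r2 = not any(all(mm[i:i + 3]) and i + 3 <= L for i in range(L))
    r3 = True
    for p in range(2, 12):  # 1-based adjacent pairs (p, p+1) inside 2..12
        if p + 1 <= 12 and p + 1 <= L and mm[p - 1] and mm[p]:
            r3 = False
    r4 = not (L >= 10 and mm[9]) and not (L >= 11 and mm[10])
    r5 = sum(s[:12]) <= 2.5
    r6 = abs(mfe) >= 0.75 * abs(mfe_perfect)
    return (r1, r2, r3, r4, r5, r6)


class TestNormalization:
    @pytest.mark.parametrize("count,total,expected", [
        (50, 10**6, 50.0), (0, 123, 0.0), (500, 500, 10**6),
    ])
    def test_transcripts_per_million(self, count, total, expected):
        assert normalize_expression(count, total) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_expression(5, 0)

    def test_fold_change_is_log2(self):
        assert fold_change(8.0, 2.0) == pytest.approx(2.0)


class TestDuplexConstruction:
    def test_perfect_complement(self):
        m = "UGAGGUA"
        d = pair_duplex(m, reverse_complement(m))
        assert all(st is WC for st in d.states)
        assert d.mismatch_score == 0.0
        assert d.mfe == d.mfe_perfect

    def test_single_gu_scores_half(self):
        # A:U pairs everywhere except one U:G wobble
        states = [WC, WC, WC, GU, WC, WC, WC]
        m, s = build_sequences(states)
        d = pair_duplex(m, s)
        assert d.states == states
        assert d.mismatch_score == 0.5

    def test_all_mismatch_scores_length(self):
        states = [MM] * 9
        m, s = build_sequences(states)
        assert pair_duplex(m, s).mismatch_score == 9.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            states_of("UGAGGUA", "ACGU")

    def test_dna_alphabet_accepted(self):
        d = pair_duplex("TGAGGTA", reverse_complement("UGAGGUA"))
        assert all(st is WC for st in d.states)


class TestRuleEngine:
    @pytest.mark.parametrize("gu_strict", [False, True])
    def test_matches_literal_recheck_all_length7(self, gu_strict):
        for combo in itertools.product([WC, GU, MM], repeat=7):
            states = list(combo)
            m, s = build_sequences(states)
            d = pair_duplex(m, s)
            got = check_rules(d, gu_strict=gu_strict)
            want = literal_verdicts(states, d.mfe, d.mfe_perfect, gu_strict)
            assert got.as_tuple() == want, states
            assert got.accepted == all(want)

    def test_matches_literal_recheck_random_length21(self):
        rng = np.random.default_rng(99)
        alphabet = [WC, GU, MM]
        for _ in range(10_000):
            states = [alphabet[i] for i in rng.integers(0, 3, size=21)]
            m, s = build_sequences(states)
            d = pair_duplex(m, s)
            got = check_rules(d)
            assert got.as_tuple() == literal_verdicts(states, d.mfe, d.mfe_perfect)

    def test_mismatch_at_position_10_rejects(self):
        states = [WC] * 21
        states[9] = MM
        m, s = build_sequences(states)
        v = check_rules(pair_duplex(m, s))
        assert not v.paired_10_11
        assert not v.accepted

    def test_score_four_and_a_half_fails_rule_one(self):
        states = [WC] * 21
        for i in (0, 2, 4, 6):
            states[i] = MM
        states[14] = GU  # 4 mismatches + one wobble -> 4.5
        m, s = build_sequences(states)
        d = pair_duplex(m, s)
        assert d.mismatch_score == 4.5
        assert not check_rules(d).max_total_score

    def test_gu_allowed_at_10_11_unless_strict(self):
        states = [WC] * 21
        states[9] = GU
        m, s = build_sequences(states)
        d = pair_duplex(m, s)
        assert check_rules(d, gu_strict=False).paired_10_11
        assert not check_rules(d, gu_strict=True).paired_10_11

    def test_missing_energy_never_accepts(self):
        states = [WC] * 7
        m, s = build_sequences(states)
        d = DuplexAlignment(m, s, states, 0.0, None, None)
        v = check_rules(d)
        assert not v.mfe_ratio and not v.accepted


class TestStackEnergy:
    def test_two_pair_helix_hand_sum(self):
        # 5'-GC-3' / 3'-CG-5': initiation plus one GC/GC stack
        dg = stack_energy("GC", "GC")
        assert dg == pytest.approx(DUPLEX_INIT + STACK_TABLE[("GC", "GC")])

    def test_reverse_orientation_identical(self):
        rng = np.random.default_rng(5)
        bases = "ACGU"
        for _ in range(200):
            m = "".join(bases[i] for i in rng.integers(0, 4, size=12))
            s = "".join(bases[i] for i in rng.integers(0, 4, size=12))
            assert stack_energy(m, s) == pytest.approx(stack_energy(s, m))

    def test_stack_table_symmetric_and_nonpositive(self):
        for (p1, p2), dg in STACK_TABLE.items():
            assert STACK_TABLE[(p2, p1)] == dg
            assert dg <= 0.0

    def test_extending_helix_never_raises_energy(self):
        m = "GCGCGCA"
        full = stack_energy(m, reverse_complement(m))
        shorter = stack_energy(m[:-1], reverse_complement(m[:-1]))
        assert full <= shorter

    def test_wc_to_mismatch_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            states = [PairState.WATSON_CRICK if rng.random() < 0.8
                      else PairState.GU for _ in range(15)]
            m, s = build_sequences(states)
            before = pair_duplex(m, s)
            i = int(rng.integers(0, 15))
            mutated = list(states)
            mutated[i] = PairState.MISMATCH
            m2, s2 = build_sequences(mutated)
            after = pair_duplex(m2, s2)
            assert abs(after.mfe) <= abs(before.mfe) + 1e-9
            assert after.mismatch_score >= before.mismatch_score

    def test_no_paired_positions_zero_energy(self):
        m, s = build_sequences([MM] * 8)
        assert stack_energy(m, s) == 0.0


class TestScanTargets:
    def test_planted_site_recovered(self):
        m = "UGAGGUAGUAGGUUGUAUAGUU"
        site = reverse_complement(m)
        rng = np.random.default_rng(1)
        bases = "ACGU"
        flank = lambda n: "".join(bases[i] for i in rng.integers(0, 4, size=n))
        utr = flank(60) + site + flank(60)
        calls = scan_targets("let7", m, [("utr1", utr)])
        accepted = [c for c in calls if c.accepted]
        assert [(c.start, c.end) for c in accepted] == [(60, 60 + len(m))]

    def test_null_acceptance_rate_is_tiny(self):
        m = "UGAGGUAGUAGGUUGUAUAGUU"
        rng = np.random.default_rng(42)
        bases = "ACGU"
        utr = "".join(bases[i] for i in rng.integers(0, 4, size=20_000))
        calls = scan_targets("let7", m, [("utr", utr)])
        n_windows = 20_000 - len(m) + 1
        assert len(calls) / n_windows < 0.01

    def test_empty_transcripts(self):
        assert scan_targets("m", "UGAGGUA", []) == []

    def test_short_transcript_skipped(self):
        assert scan_targets("m", "UGAGGUAGUA", [("t", "ACG")]) == []

    def test_coordinates_are_half_open_sense_strand(self):
        m = "UGAGGUA"
        utr = "CCC" + reverse_complement(m) + "CCC"
        calls = scan_targets("m", m, [("t", utr)])
        (c,) = [c for c in calls if c.accepted]
        assert utr[c.start:c.end] == reverse_complement(m)
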