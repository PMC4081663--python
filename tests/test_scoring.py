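"""SNMM and PWM scoring, strand handling, and sequence scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snmmkit as sk
from snmmkit.seqs import AlphabetError

dna10 = st.text(alphabet="ACGT", min_size=10, max_size=10)


class TestSnmmScore:
    def test_reproduces_full_published_score_column(self, table2, snmm_scorer):
        """Every one of the 52 published SNMM scores at 3 decimals."""
        scores = snmm_scorer.predict(table2["sequence"])
        np.testing.assert_allclose(
            np.round(scores, 3), table2["SNMM"].to_numpy(), atol=5e-4
        )

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGGGATTCCC", 0.987),
            ("GGGGAATCCC", 0.903),
            ("GGAGAACCCC", 0.747),
            ("GGAGACCTCC", 0.699),
            ("GGAGGCCTCC", 0.694),
        ],
    )
    def test_spot_values(self, table1, seq, expected):
        assert round(sk.snmm_score(seq, table1), 3) == expected

    def test_argmax_sequence_scores_exactly_one(self, table1):
        assert table1.argmax_sequence() == "GGGATTTCCC"
        assert sk.snmm_score("GGGATTTCCC", table1) == 1.0

    def test_argmin_sequence_scores_exactly_zero(self, table1):
        assert table1.argmin_sequence() == "CCCCCCAGGT"
        assert sk.snmm_score("CCCCCCAGGT", table1) == 0.0

    def test_reference_score_is_normalized_zero_point(self, table1):
        # (0 - S_min) / (S_max - S_min) = 301.50 / 315.37
        assert round(sk.snmm_score(table1.reference, table1), 3) == 0.956

    def test_per_position_monotonicity(self, table1):
        """A strictly larger delta at any one position strictly raises the score."""
        start = "GGAACTTTCC"
        base_score = sk.snmm_score(start, table1)
        for pos in range(10):
            for b in "ACGT":
                if b == start[pos]:
                    continue
                variant = start[:pos] + b + start[pos + 1:]
                d_new = table1.cell(b, pos + 1)
                d_old = table1.cell(start[pos], pos + 1)
                s = sk.snmm_score(variant, table1)
                if d_new > d_old:
                    assert s > base_score
                elif d_new < d_old:
                    assert s < base_score

    def test_reduced_matrix_against_exhaustive_enumeration(self):
        """On a 3-active-column matrix the score equals the brute-force
        normalized rank formula over all 64 varying sequences."""
        rng = np.random.default_rng(42)
        delta = np.zeros((4, 10))
        active = [2, 5, 8]
        ref = "GGGACTTTCC"
        for pos in active:
            col = np.round(rng.uniform(-50, 10, size=4), 2)
            col["ACGT".index(ref[pos])] = 0.0
            delta[:, pos] = col
        m = sk.MutationMatrix(ref, delta)
        smin = sum(delta[:, p].min() for p in active)
        smax = sum(delta[:, p].max() for p in active)
        for combo in itertools.product("ACGT", repeat=3):
            seq = list(ref)
            for pos, b in zip(active, combo):
                seq[pos] = b
            seq = "".join(seq)
            brute = (
                sum(delta["ACGT".index(b), p] for p, b in zip(active, combo)) - smin
            ) / (smax - smin)
            assert sk.snmm_score(seq, m) == pytest.approx(brute, abs=1e-12)

    @given(dna10)
    @settings(max_examples=200, deadline=None)
    def test_scores_bounded(self, seq):
        m = sk.table1_matrix()
        assert 0.0 <= sk.snmm_score(seq, m) <= 1.0

    def test_wrong_length_and_alphabet_errors(self, table1):
        with pytest.raises(ValueError, match="10-mer"):
            sk.snmm_score("ACGT", table1)
        with pytest.raises(AlphabetError):
            sk.snmm_score("GGGACTTTCN", table1)

    def test_case_and_u_canonicalization(self, table1):
        assert sk.snmm_score("gggacuuucc", table1) == sk.snmm_score(
            "GGGACTTTCC", table1
        )


class TestPwmScorers:
    @pytest.mark.parametrize("method", ["pwmsa", "match"])
    def test_argmax_one_argmin_zero(self, nfkb_pwm, method):
        scorer = sk.PWMScorer.from_pwm(nfkb_pwm, method=method)
        assert scorer.score_sequence(nfkb_pwm.argmax_sequence()) == pytest.approx(1.0)
        assert scorer.score_sequence(nfkb_pwm.argmin_sequence()) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("method", ["pwmsa", "match"])
    @given(seq=dna10)
    @settings(max_examples=100, deadline=None)
    def test_bounded(self, method, seq):
        scorer = sk.PWMScorer.from_pwm(sk.nfkb_pwm(), method=method)
        assert -1e-12 <= scorer.score_sequence(seq) <= 1 + 1e-12

    def test_pwmsa_is_normalized_log_odds(self, nfkb_pwm):
        seq = "GGGGATTCCC"
        lods = np.log(nfkb_pwm.frequencies / nfkb_pwm.background[:, None])
        raw = sum(lods["ACGT".index(b), i] for i, b in enumerate(seq))
        lo, hi = lods.min(axis=0).sum(), lods.max(axis=0).sum()
        assert sk.pwmsa_score(seq, nfkb_pwm) == pytest.approx((raw - lo) / (hi - lo))

    def test_match_is_information_weighted(self, nfkb_pwm):
        seq = "GGGGATTCCC"
        w = nfkb_pwm.information[None, :] * nfkb_pwm.frequencies
        raw = sum(w["ACGT".index(b), i] for i, b in enumerate(seq))
        lo, hi = w.min(axis=0).sum(), w.max(axis=0).sum()
        assert sk.match_mss(seq, nfkb_pwm) == pytest.approx((raw - lo) / (hi - lo))

    def test_zero_frequency_pwmsa_demands_pseudocount(self):
        pwm = sk.build_pwm(["ACGT", "ACGT"], pseudocount=0)
        with pytest.raises(sk.MatrixError, match="pseudocount"):
            sk.PWMScorer.from_pwm(pwm, method="pwmsa")

    def test_width_mismatch(self, nfkb_pwm):
        with pytest.raises(ValueError):
            sk.match_mss("ACGTACGT", nfkb_pwm)

    def test_sklearn_params_round_trip(self):
        scorer = sk.PWMScorer(method="pwmsa", pseudocount=2.0)
        clone = sk.PWMScorer(**scorer.get_params())
        assert clone.get_params() == scorer.get_params()


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,rc", [("GGGACTTTCC", "GGAAAGTCCC"), ("A", "T"), ("ACGT", "ACGT")]
    )
    def test_examples(self, seq, rc):
        assert sk.reverse_complement(seq) == rc

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_involution(self, seq):
        assert sk.reverse_complement(sk.reverse_complement(seq)) == seq

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            sk.reverse_complement("ACGN")


class TestScan:
    # the consensus site is quasi-palindromic: its reverse complement
    # GGGAATCCCC scores 0.907 itself, so a 0.95 threshold isolates the
    # spliced site on exactly one strand
    def test_spliced_site_found_on_plus_strand(self, snmm_scorer):
        seq = "A" * 5 + "GGGGATTCCC" + "A" * 35
        hits = sk.scan_sequence(seq, snmm_scorer, threshold=0.95)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.strand, h.site) == (5, "+", "GGGGATTCCC")
        assert round(h.score, 3) == 0.987

    def test_spliced_reverse_complement_found_on_minus_strand(self, snmm_scorer):
        rc_site = sk.reverse_complement("GGGGATTCCC")  # GGGAATCCCC
        seq = "A" * 5 + rc_site + "A" * 35
        hits = sk.scan_sequence(seq, snmm_scorer, threshold=0.95)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (5, "-")
        assert hits[0].site == "GGGGATTCCC"
        assert round(hits[0].score, 3) == 0.987

    def test_lower_threshold_also_reports_the_palindromic_partner(self, snmm_scorer):
        seq = "A" * 5 + "GGGGATTCCC" + "A" * 35
        hits = sk.scan_sequence(seq, snmm_scorer, threshold=0.9)
        assert [(h.strand, h.site) for h in hits] == [
            ("+", "GGGGATTCCC"), ("-", "GGGAATCCCC")
        ]

    def test_threshold_one_keeps_only_the_perfect_site(self, table1, snmm_scorer):
        hits = sk.scan_sequence("GGGATTTCCC", snmm_scorer, threshold=1.0, strands="+")
        assert len(hits) == 1 and hits[0].score == 1.0

    def test_short_sequence_warns_and_returns_empty(self, snmm_scorer):
        with pytest.warns(UserWarning, match="shorter"):
            assert sk.scan_sequence("ACGTACG", snmm_scorer, threshold=0.0) == []

    def test_window_scoring_matches_extraction(self, snmm_scorer, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        hits = sk.scan_sequence(seq, snmm_scorer, threshold=0.0, strands="+")
        assert len(hits) == 51
        for h in hits:
            assert h.score == snmm_scorer.score_sequence(seq[h.start:h.start + 10])

    def test_both_equals_plus_union_flipped_rc_scan(self, snmm_scorer, rng):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        both = sk.scan_sequence(seq, snmm_scorer, threshold=0.6)
        plus = sk.scan_sequence(seq, snmm_scorer, threshold=0.6, strands="+")
        rc_plus = sk.scan_sequence(
            sk.reverse_complement(seq), snmm_scorer, threshold=0.6, strands="+"
        )
        flipped = {
            (len(seq) - h.start - 10, "-", h.site, h.score) for h in rc_plus
        }
        got = {(h.start, h.strand, h.site, h.score) for h in both}
        want = {(h.start, h.strand, h.site, h.score) for h in plus} | flipped
        assert got == want

    def test_hits_sorted_and_coordinates_valid(self, snmm_scorer, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50))
        hits = sk.scan_sequence(seq, snmm_scorer, threshold=0.0)
        assert hits == sorted(hits, key=lambda h: (h.start, h.strand))
        assert all(0 <= h.start <= len(seq) - 10 for h in hits)
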