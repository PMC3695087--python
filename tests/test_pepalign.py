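import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antigenscreen.pepalign import (
    ROBINSON_FREQUENCIES,
    ProteinRecord,
    ScoringScheme,
    best_local_hit,
    compute_ungapped_lambda,
    evalue_two_seq,
    screen_database,
)
from tests.conftest import AA20, brute_force_best_gapless, random_seq

peptide_st = st.text(alphabet=AA20, min_size=7, max_size=7)


class TestBestLocalHit:
    def test_exact_substring_scores_diagonal_sum(self, scheme, blosum62, toy_protein):
        hit = best_local_hit("NFTLPSW", toy_protein, scheme)
        expected = sum(int(blosum62[c, c]) for c in "NFTLPSW")
        assert hit.raw_score == expected
        assert (hit.prot_start, hit.prot_end) == (5, 11)
        assert (hit.pep_start, hit.pep_end) == (1, 7)

    def test_no_positive_pair_returns_none(self, scheme):
        assert best_local_hit("AAAAAAA", ProteinRecord("W", "", "WWWWWWWW"), scheme) is None

    def test_identity_spans_both_sequences(self, scheme, blosum62):
        pep = "NFTLPSW"
        hit = best_local_hit(pep, ProteinRecord("P", "", pep), scheme)
        assert (hit.pep_start, hit.pep_end) == (1, 7)
        assert (hit.prot_start, hit.prot_end) == (1, 7)
        assert hit.raw_score == sum(int(blosum62[c, c]) for c in pep)

    def test_unknown_residue_named_in_error(self, scheme):
        with pytest.raises(ValueError, match="'1'"):
            best_local_hit("NFTLPS1", ProteinRecord("P", "", "NFTLPSW"), scheme)

    def test_tie_break_prefers_smallest_protein_start(self, scheme):
        # identical motif planted twice: the earlier occurrence must win
        prot = ProteinRecord("P", "", "GGNFTLPSWGGGGNFTLPSWGG")
        hit = best_local_hit("NFTLPSW", prot, scheme)
        assert hit.prot_start == 3

    def test_oracle_equivalence_on_random_pairs(self, scheme, blosum62):
        # exhaustive all-offset scoring is the independent oracle
        rng = random.Random(12345)
        mismatches = 0
        for _ in range(1000):
            pep = random_seq(rng, 7)
            prot = ProteinRecord("P", "", random_seq(rng, rng.randint(20, 120)))
            expected = brute_force_best_gapless(pep, prot.sequence, blosum62)
            hit = best_local_hit(pep, prot, scheme)
            got = 0 if hit is None else hit.raw_score
            mismatches += got != expected
        assert mismatches == 0

    @given(peptide_st, st.text(alphabet=AA20, min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_score_symmetry(self, pep, other):
        scheme = ScoringScheme()
        a = best_local_hit(pep, ProteinRecord("A", "", other), scheme)
        b = best_local_hit(other, ProteinRecord("B", "", pep), scheme)
        sa = 0 if a is None else a.raw_score
        sb = 0 if b is None else b.raw_score
        assert sa == sb

    @given(peptide_st, st.text(alphabet=AA20, min_size=5, max_size=40),
           st.text(alphabet=AA20, min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_appending_residues_never_decreases_score(self, pep, prot, extra):
        scheme = ScoringScheme()
        short = best_local_hit(pep, ProteinRecord("S", "", prot), scheme)
        longer = best_local_hit(pep, ProteinRecord("L", "", prot + extra), scheme)
        s = 0 if short is None else short.raw_score
        l = 0 if longer is None else longer.raw_score
        assert l >= s

    def test_bit_score_order_matches_raw_score_order(self, scheme):
        rng = random.Random(99)
        hits = []
        for _ in range(50):
            h = best_local_hit(random_seq(rng, 7),
                               ProteinRecord("P", "", random_seq(rng, 80)), scheme)
            if h is not None:
                hits.append(h)
        by_raw = sorted(hits, key=lambda h: h.raw_score)
        by_bits = sorted(hits, key=lambda h: h.bit_score)
        assert [h.raw_score for h in by_raw] == [h.raw_score for h in by_bits]


class TestStatistics:
    def test_tabulated_lambda_and_entropy_rederive(self):
        # dual route: solve sum p_i p_j exp(lambda s_ij) = 1 numerically
        for name, lam_expected, h_expected in (
            ("BLOSUM62", 0.3176, 0.4012),
            ("PAM30", 0.3400, 1.7536),
        ):
            lam, h = compute_ungapped_lambda(name)
            assert lam == pytest.approx(lam_expected, rel=1e-3)
            assert h == pytest.approx(h_expected, rel=1e-3)

    def test_evalue_matches_formula_rederivation(self, scheme):
        for raw, m, n in [(20, 7, 100), (34, 7, 400), (45, 7, 5000)]:
            k, lam, h = scheme.k_param, scheme.lambda_, scheme.h_param
            ell = math.log(k * m * n) / h
            expected = k * max(m - ell, 1) * max(n - ell, 1) * math.exp(-lam * raw)
            assert evalue_two_seq(raw, m, n, scheme) == pytest.approx(expected)

    def test_evalue_vanishes_at_high_score(self, scheme):
        assert evalue_two_seq(10_000, 7, 400, scheme) == pytest.approx(0.0, abs=1e-300)

    def test_evalue_roughly_linear_in_protein_length(self, scheme):
        # doubling n doubles E up to the edge correction
        e1 = evalue_two_seq(30, 7, 10_000, scheme)
        e2 = evalue_two_seq(30, 7, 20_000, scheme)
        assert e2 / e1 == pytest.approx(2.0, rel=0.01)

    def test_bit_score_definition(self, scheme):
        raw = 34
        bits = (scheme.lambda_ * raw - math.log(scheme.k_param)) / math.log(2)
        assert scheme.bit_score(raw) == pytest.approx(bits)


class TestScreenDatabase:
    def test_planted_peptide_found_uniquely_among_decoys(self, scheme):
        rng = random.Random(42)
        pep = "NFTLPSW"
        decoys = []
        while len(decoys) < 100:
            seq = random_seq(rng, 60)
            if pep not in seq:
                decoys.append(ProteinRecord(f"D{len(decoys)}", "", seq))
        target = ProteinRecord("T", "", "MM" + pep + "MM")
        self_bits = best_local_hit(pep, target, scheme).bit_score
        hits = screen_database([pep], decoys + [target], scheme, self_bits)
        assert [h.protein_accession for h in hits] == ["T"]

    def test_infinite_threshold_empty(self, scheme):
        prots = [ProteinRecord("P", "", "NFTLPSWNFTLPSW")]
        assert screen_database(["NFTLPSW"], prots, scheme, math.inf) == []

    def test_exhaustive_pairing_at_minus_inf(self, scheme):
        rng = random.Random(1)
        peps = [random_seq(rng, 7) for _ in range(3)]
        prots = [ProteinRecord(f"P{i}", "", random_seq(rng, 50)) for i in range(4)]
        hits = screen_database(peps, prots, scheme, -math.inf)
        assert len(hits) == 12

    def test_empty_database_warns(self, scheme):
        with pytest.warns(UserWarning):
            assert screen_database(["NFTLPSW"], [], scheme, 0.0) == []


class TestSchemes:
    def test_pam30_selectable(self):
        scheme = ScoringScheme(matrix_name="PAM30")
        hit = best_local_hit("NFTLPSW", ProteinRecord("P", "", "MNFTLPSWM"), scheme)
        assert hit is not None and hit.raw_score > 0

    def test_unknown_matrix_without_constants_rejected(self):
        with pytest.raises(ValueError, match="constants"):
            ScoringScheme(matrix_name="BLOSUM45")

    def test_gapped_mode_finds_exact_match(self):
        scheme = ScoringScheme(gapless=False)
        hit = best_local_hit("NFTLPSW", ProteinRecord("P", "", "MMNFTLPSWMM"), scheme)
        assert (hit.prot_start, hit.prot_end) == (3, 9)
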