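import random

import pytest

from antigenscreen.pepalign import ProteinRecord, ScoringScheme, best_local_hit
from antigenscreen.ranking import (
    CandidateAntigen,
    RankingParams,
    format_final_score,
    format_initial_score,
    step1_shortlist,
    step2_final_rank,
)
from antigenscreen.selection import PeptideList
from tests.conftest import random_seq


def plist(peptides, role="step1"):
    return PeptideList("s", [(p, 100 - i) for i, p in enumerate(peptides)], role=role)


class TestScoreArithmetic:
    """Score formulas and display conventions of the report tables."""

    @pytest.mark.parametrize(
        "matches,length,shown",
        [(7, 386, "0.0181"), (2, 230, "0.0086"), (5, 69, "0.0724"), (2, 418, "0.0047")],
    )
    def test_initial_score_display(self, matches, length, shown):
        c = CandidateAntigen("X", "", length, initial_matches=matches)
        assert c.initial_score == pytest.approx(matches / length)
        assert format_initial_score(c.initial_score) == shown

    @pytest.mark.parametrize(
        "total,length,shown",
        [
            (769.5, 386, "1.993523"),
            (917.3, 417, "2.19976"),
            (1260.4, 69, "18.26667"),
        ],
    )
    def test_final_score_display(self, total, length, shown):
        c = CandidateAntigen("X", "", length, sum_overall_scores=total)
        assert format_final_score(c.final_score) == shown

    def test_ratio_identities_exact(self):
        c = CandidateAntigen("X", "", 386, initial_matches=7,
                             sum_overall_scores=2245.2)
        assert c.final_score * c.length == pytest.approx(c.sum_overall_scores)
        assert c.initial_score * c.length == pytest.approx(c.initial_matches)


class TestStep1Shortlist:
    def test_two_protein_toy_ordering(self, scheme):
        # lengths 100 and 200, each hit by the same 2 peptides:
        # scores 0.02 vs 0.01, short protein first
        peps = ["NFTLPSW", "WYWYWYW"]
        core = "".join(peps)
        short = ProteinRecord("B_SHORT", "", core + "A" * (100 - len(core)))
        longp = ProteinRecord("A_LONG", "", core + "A" * (200 - len(core)))
        out = step1_shortlist(plist(peps), [short, longp],
                              RankingParams(), scheme)
        assert [c.accession for c in out] == ["B_SHORT", "A_LONG"]
        assert out[0].initial_score == pytest.approx(0.02)
        assert out[1].initial_score == pytest.approx(0.01)
        assert all(c.initial_matches == 2 for c in out)

    def test_single_match_excluded(self, scheme):
        prot = ProteinRecord("P", "", "MM" + "NFTLPSW" + "M" * 90)
        out = step1_shortlist(plist(["NFTLPSW", "DDDDDDD"]), [prot],
                              RankingParams(), scheme)
        assert out == []

    def test_truncation_to_top_candidates(self, scheme):
        peps = ["NFTLPSW", "WYWYWYW"]
        core = "".join(peps)
        prots = [ProteinRecord(f"P{i:02d}", "", core + "A" * (50 + i))
                 for i in range(10)]
        out = step1_shortlist(plist(peps), prots,
                              RankingParams(top_candidates=3), scheme)
        assert len(out) == 3
        scores = [c.initial_score for c in out]
        assert scores == sorted(scores, reverse=True)


class TestStep2FinalRank:
    def test_sum_matches_best_hit_bits(self, scheme):
        peps = ["NFTLPSW", "WYWYWYW"]
        prot = ProteinRecord("P", "", "".join(peps) + "A" * 30)
        shortlist = step1_shortlist(plist(peps), [prot], RankingParams(), scheme)
        final = step2_final_rank(plist(peps, role="step2"), shortlist, [prot],
                                 RankingParams(), scheme)
        assert len(final) == 1
        expected = sum(best_local_hit(p, prot, scheme).bit_score for p in peps)
        assert final[0].sum_overall_scores == pytest.approx(expected)
        assert final[0].final_score == pytest.approx(expected / prot.length)

    def test_zero_included_peptides_ranked_last(self, scheme):
        peps = ["NFTLPSW", "WYWYWYW"]
        good = ProteinRecord("GOOD", "", "".join(peps) + "A" * 30)
        shortlist = step1_shortlist(plist(peps), [good], RankingParams(), scheme)
        empty = CandidateAntigen("ZERO", "", 100, initial_matches=2)
        blank = ProteinRecord("ZERO", "", "G" * 100)
        final = step2_final_rank(
            plist(["WWWWWWW"], role="step2"), shortlist + [empty],
            [good, blank], RankingParams(step2_evalue_cutoff=1e-6), scheme,
        )
        assert final[-1].accession == "ZERO"
        assert final[-1].final_score == 0.0

    def test_shortlist_containment(self, scheme):
        rng = random.Random(77)
        peps = ["NFTLPSW", "WYWYWYW", "HKHKHKH"]
        prots = [ProteinRecord(f"P{i}", "", random_seq(rng, 150)) for i in range(20)]
        prots.append(ProteinRecord("T", "", "".join(peps) + "A" * 100))
        params = RankingParams()
        shortlist = step1_shortlist(plist(peps), prots, params, scheme)
        final = step2_final_rank(plist(peps, role="step2"), shortlist, prots,
                                 params, scheme)
        assert {c.accession for c in final} <= {c.accession for c in shortlist}

    def test_doubling_length_halves_scores(self, scheme):
        peps = ["NFTLPSW", "WYWYWYW"]
        seq = "".join(peps) + "A" * 86  # length 100
        single = ProteinRecord("S", "", seq)
        doubled = ProteinRecord("D", "", seq + "G" * 100)
        params = RankingParams()
        for prot in (single, doubled):
            shortlist = step1_shortlist(plist(peps), [prot], params, scheme)
            final = step2_final_rank(plist(peps, role="step2"), shortlist, [prot],
                                     params, scheme)
            if prot is single:
                s_init, s_final = final[0].initial_score, final[0].final_score
            else:
                assert final[0].initial_score == pytest.approx(s_init / 2)
                assert final[0].final_score == pytest.approx(s_final / 2)

    def test_major_epitope_score_bounded_by_sum(self, scheme):
        rng = random.Random(13)
        peps = [random_seq(rng, 7) for _ in range(30)] + ["NFTLPSW", "FTLPSWA"]
        prot = ProteinRecord("T", "", "M" * 50 + "NFTLPSWA" + "M" * 50)
        shortlist = step1_shortlist(plist(peps[-2:]), [prot], RankingParams(), scheme)
        final = step2_final_rank(plist(peps, role="step2"), shortlist, [prot],
                                 RankingParams(), scheme)
        for c in final:
            assert c.major_epitope_score <= c.sum_overall_scores + 1e-9
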