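"""Alignment kernels, E-value statistics, and sub-alignment scoring."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from seedsearch import alignkit
from seedsearch.alignkit import (
    DatabaseSummary,
    EVDParams,
    FitError,
    SubstitutionMatrix,
    bit_score,
    evalue,
    fit_evd,
    pssm_search,
    smith_waterman,
    subalignment_scores,
)
from seedsearch.msaforge import build_query_msa
from seedsearch.pssmkit import build_pssm
from seedsearch.seqio import AlphabetError, DomainAnnotation, ProteinSequence

from _oracles import affine_local_score, pair_local_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestSmithWaterman:
    def test_self_alignment_full_length(self, blosum62):
        seq = ProteinSequence("x", "WYACDEFGHI")
        aln = smith_waterman(seq, seq, blosum62)
        assert (aln.q_start, aln.q_end, aln.s_start, aln.s_end) == (1, 10, 1, 10)
        assert aln.percent_identity == 100.0
        assert aln.raw_score == sum(blosum62.score(c, c) for c in seq.residues)
        assert aln.btop == "10"

    def test_all_negative_scores_is_no_hit(self, blosum62):
        # A vs C scores 0 under BLOSUM62; W vs P is -4 — use a pair with no
        # positive cell at all
        a = ProteinSequence("a", "PPPP")
        b = ProteinSequence("b", "WWWW")
        assert smith_waterman(a, b, blosum62) is None

    def test_empty_sequence_rejected(self, blosum62):
        with pytest.raises(AlphabetError):
            ProteinSequence("a", "")

    def test_btop_validates_against_sequences(self, blosum62, rng):
        from seedsearch.btop import btop_decode

        for _ in range(20):
            q = ProteinSequence("q", "".join(rng.choice(list(AA), 30)))
            s = ProteinSequence("s", "".join(rng.choice(list(AA), 30)))
            aln = smith_waterman(q, s, blosum62)
            if aln is None:
                continue
            qrow, srow = btop_decode(
                aln.btop,
                q.residues[aln.q_start - 1 : aln.q_end],
                s.residues[aln.s_start - 1 : aln.s_end],
            )
            assert len(qrow) == len(srow)

    def test_score_matches_bruteforce_on_random_pairs(self, blosum62, rng):
        """200 random 12-mer pairs against the naive three-matrix DP."""
        for _ in range(200):
            q = "".join(rng.choice(list(AA), 12))
            s = "".join(rng.choice(list(AA), 12))
            aln = smith_waterman(
                ProteinSequence("q", q), ProteinSequence("s", s), blosum62
            )
            expected = pair_local_score(q, s, blosum62)
            assert (aln.raw_score if aln else 0) == expected

    def test_swap_symmetry(self, blosum62, rng):
        """Score is invariant under query/subject swap (symmetric matrix)."""
        for _ in range(50):
            q = ProteinSequence("q", "".join(rng.choice(list(AA), 25)))
            s = ProteinSequence("s", "".join(rng.choice(list(AA), 20)))
            a1 = smith_waterman(q, s, blosum62)
            a2 = smith_waterman(s, q, blosum62)
            s1 = a1.raw_score if a1 else 0
            s2 = a2.raw_score if a2 else 0
            assert s1 == s2


class TestPssmSearch:
    def test_query_only_pssm_self_search_is_maximal_diagonal(self, blosum62):
        query = ProteinSequence("q", "WYACDEFGHIKLMNPQRSTV")
        pssm = build_pssm(build_query_msa(query, []), blosum62)
        aln = pssm_search(pssm, query)
        assert (aln.q_start, aln.q_end) == (1, len(query.residues))
        assert aln.raw_score == int(
            sum(pssm.scores[i, AA.index(c)] for i, c in enumerate(query.residues))
        )

    def test_no_positive_cell_is_no_hit(self, blosum62):
        query = ProteinSequence("q", "WWWW")
        pssm = build_pssm(build_query_msa(query, []), blosum62)
        assert pssm_search(pssm, ProteinSequence("s", "PPPP")) is None

    def test_subject_outside_alphabet_rejected(self, blosum62):
        query = ProteinSequence("q", "ACDE")
        pssm = build_pssm(build_query_msa(query, []), blosum62)
        with pytest.raises(AlphabetError):
            pssm_search(pssm, ProteinSequence("s", "ACXD"))

    def test_score_matches_bruteforce_profile_dp(self, blosum62, rng):
        """200 random (PSSM, subject) pairs against the naive profile DP."""
        for _ in range(200):
            q = ProteinSequence("q", "".join(rng.choice(list(AA), 12)))
            pssm = build_pssm(build_query_msa(q, []), blosum62)
            s = "".join(rng.choice(list(AA), 12))
            aln = pssm_search(pssm, ProteinSequence("s", s))
            expected = affine_local_score(
                pssm.scores.tolist(), [AA.index(c) for c in s], 11, 1
            )
            assert (aln.raw_score if aln else 0) == expected


class TestEvalues:
    def test_monotone_decreasing_in_score(self):
        p = EVDParams(0.3, 0.05, 10**6, 1000)
        scores = np.arange(10, 200, 7)
        es = [float(evalue(p, s, 150)) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))
        bits = [bit_score(p, s) for s in scores]
        assert all(a < b for a, b in zip(bits, bits[1:]))

    def test_linear_in_database_size(self):
        p1 = EVDParams(0.3, 0.05, 10**6, 1000)
        p2 = EVDParams(0.3, 0.05, 2 * 10**6, 2000)
        assert float(evalue(p2, 100, 150)) == pytest.approx(
            2 * float(evalue(p1, 100, 150))
        )

    def test_gumbel_lambda_recovered_within_5_percent(self):
        lam_true = 0.267
        rng = np.random.default_rng(7)
        scores = stats.gumbel_r.rvs(loc=60.0, scale=1.0 / lam_true, size=10_000, random_state=rng)
        db = DatabaseSummary(residues=10_000 * 350, sequences=10_000, query_length=250)
        params = fit_evd(scores, db)
        assert abs(params.lam - lam_true) / lam_true < 0.05

    def test_censoring_recovers_null_under_contamination(self):
        # a homolog tail a few hundred strong must not flatten the fit
        lam_true = 0.28
        rng = np.random.default_rng(11)
        null = stats.gumbel_r.rvs(loc=40.0, scale=1.0 / lam_true, size=2_000, random_state=rng)
        homologs = rng.uniform(200, 500, size=300)
        db = DatabaseSummary(residues=2_300 * 300, sequences=2_300, query_length=200)
        params = fit_evd(np.concatenate([null, homologs]), db)
        assert abs(params.lam - lam_true) / lam_true < 0.10

    def test_degenerate_scores_raise(self):
        db = DatabaseSummary(10**5, 100, 100)
        with pytest.raises(FitError):
            fit_evd(np.full(100, 37.0), db)
        with pytest.raises(FitError):
            fit_evd(np.arange(10.0), db)  # too few


def _ungapped_alignment(query, subject, matrix):
    from seedsearch.btop import btop_encode

    raw = sum(matrix.score(a, b) for a, b in zip(query, subject))
    ident = 100.0 * sum(a == b for a, b in zip(query, subject)) / len(query)
    return alignkit.LocalAlignment(
        q_start=1,
        q_end=len(query),
        s_start=1,
        s_end=len(subject),
        raw_score=raw,
        percent_identity=ident,
        btop=btop_encode(query, subject),
    )


class TestSubalignmentScores:
    def test_single_region_conserves_raw_score(self, blosum62):
        q = ProteinSequence("q", "ACDEFGHIKL")
        s = ProteinSequence("s", "ACDEFGHIKL")
        aln = _ungapped_alignment(q.residues, s.residues, blosum62)
        parts = subalignment_scores(
            aln, q, s, [DomainAnnotation("s", "D1", "", 1, 10)], blosum62
        )
        assert parts[0].score == aln.raw_score
        assert sum(p.score for p in parts) == aln.raw_score

    def test_split_by_boundary_sums_to_raw_score(self, blosum62, rng):
        for _ in range(25):
            qres = "".join(rng.choice(list(AA), 40))
            sres = "".join(rng.choice(list(AA), 40))
            q, s = ProteinSequence("q", qres), ProteinSequence("s", sres)
            aln = smith_waterman(q, s, blosum62)
            if aln is None:
                continue
            cut = (aln.s_start + aln.s_end) // 2
            regions = [
                DomainAnnotation("s", "L", "", 1, cut),
                DomainAnnotation("s", "R", "", cut + 1, 40),
            ]
            parts = subalignment_scores(aln, q, s, regions, blosum62)
            assert sum(p.score for p in parts) == aln.raw_score

    def test_region_outside_alignment_reports_zero(self, blosum62):
        q = ProteinSequence("q", "ACDEFGHIKL")
        s = ProteinSequence("s", "ACDEFGHIKLMNPQRSTVWY")
        aln = _ungapped_alignment(q.residues, s.residues[:10], blosum62)
        parts = subalignment_scores(
            aln, q, s, [DomainAnnotation("s", "far", "", 15, 20)], blosum62
        )
        assert parts[0].score == 0 and parts[0].columns == 0

    def test_overextended_tail_has_lower_score_density(self, blosum62, rng):
        """A 40%-identity block followed by a random-vs-random tail: the
        tail's score per column is far below the block's."""
        n_block, n_tail = 60, 60
        qb = rng.choice(list(AA), n_block)
        sb = qb.copy()
        mutate = rng.choice(n_block, size=int(0.6 * n_block), replace=False)
        for i in mutate:
            sb[i] = rng.choice([c for c in AA if c != qb[i]])
        q = "".join(qb) + "".join(rng.choice(list(AA), n_tail))
        s = "".join(sb) + "".join(rng.choice(list(AA), n_tail))
        aln = _ungapped_alignment(q, s, blosum62)
        regions = [DomainAnnotation("s", "block", "", 1, n_block)]
        parts = subalignment_scores(
            aln, ProteinSequence("q", q), ProteinSequence("s", s), regions, blosum62
        )
        block, tail = parts[0], parts[1]
        assert tail.region is None
        assert block.density > tail.density

    def test_gap_charged_to_region_of_first_gap_column(self, blosum62):
        from seedsearch.btop import btop_decode

        q = ProteinSequence("q", "AAAACCCC")
        s = ProteinSequence("s", "AAAAGGCCCC")
        # alignment: 4 matches, 2-residue gap in query, 4 matches
        aln = alignkit.LocalAlignment(
            q_start=1, q_end=8, s_start=1, s_end=10,
            raw_score=sum(blosum62.score(c, c) for c in "AAAACCCC")
            - (11 + 1) - 1,
            percent_identity=80.0,
            btop="4-G-G4",
        )
        regions = [
            DomainAnnotation("s", "left", "", 1, 5),
            DomainAnnotation("s", "right", "", 6, 10),
        ]
        parts = subalignment_scores(aln, q, s, regions, blosum62)
        by_id = {p.region.domain_id: p for p in parts if p.region}
        # whole gap run starts at subject position 5 -> charged to "left"
        assert by_id["left"].score == 4 * blosum62.score("A", "A") - 13
        assert by_id["right"].score == 4 * blosum62.score("C", "C")
        assert sum(p.score for p in parts) == aln.raw_score
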