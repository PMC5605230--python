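"""Query-anchored MSA assembly, boundary policies, and gap seeding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seedsearch.alignkit import LocalAlignment, smith_waterman
from seedsearch.btop import btop_encode
from seedsearch.msaforge import (
    BoundaryRegistry,
    GapFillPolicy,
    MSARow,
    QueryAnchoredMSA,
    apply_boundary_policy,
    build_query_msa,
    fill_gaps,
    trim_to_query_interval,
)
from seedsearch.seqio import DomainAnnotation, ProteinSequence

AA = "ACDEFGHIKLMNPQRSTVWY"


def _aln(q_start, q_end, s_start, s_end, btop, raw=100, identity=90.0):
    return LocalAlignment(
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        raw_score=raw,
        percent_identity=identity,
        btop=btop,
        evalue=1e-6,
        bit_score=40.0,
    )


class TestBuildQueryMsa:
    def test_full_span_match(self):
        query = ProteinSequence("q", "ACDE")
        subject = ProteinSequence("s", "ACDE")
        msa = build_query_msa(query, [(subject, _aln(1, 4, 1, 4, "4"))])
        assert msa.rows[0].text == "ACDE"
        assert msa.rows[0].insertions == ()

    def test_subject_insertion_deleted_from_row(self):
        # query ACD vs subject AGCD: G is an insertion relative to the query
        query = ProteinSequence("q", "ACD")
        subject = ProteinSequence("s", "AGCD")
        msa = build_query_msa(query, [(subject, _aln(1, 3, 1, 4, "1-G2"))])
        row = msa.rows[0]
        assert row.text == "ACD"
        assert len(row.text) == len(query.residues)
        assert row.insertions == ((2, "G"),)

    def test_partial_span_has_end_gaps(self):
        query = ProteinSequence("q", "WYACDEFG")
        subject = ProteinSequence("s", "ACDE")
        msa = build_query_msa(query, [(subject, _aln(3, 6, 1, 4, "4"))])
        assert msa.rows[0].text == "--ACDE--"

    def test_internal_subject_gap_stays_gap(self):
        query = ProteinSequence("q", "ACDE")
        subject = ProteinSequence("s", "ADE")
        msa = build_query_msa(query, [(subject, _aln(1, 4, 1, 3, "1C-2"))])
        assert msa.rows[0].text == "A-DE"

    def test_duplicate_subject_rejected(self):
        query = ProteinSequence("q", "ACDE")
        subject = ProteinSequence("s", "ACDE")
        hit = (subject, _aln(1, 4, 1, 4, "4"))
        with pytest.raises(ValueError, match="two hits"):
            build_query_msa(query, [hit, hit])

    def test_row_length_invariant_enforced(self):
        with pytest.raises(ValueError, match="length"):
            QueryAnchoredMSA(
                query=ProteinSequence("q", "ACDE"),
                rows=[MSARow("s", "AC", 1, 2, 1, 2)],
            )


class TestBoundaryRegistry:
    def test_write_once(self):
        reg = BoundaryRegistry()
        assert reg.record("s1", 10, 50, 5, 45)
        assert not reg.record("s1", 1, 99, 1, 99)
        assert reg.get("s1") == (10, 50, 5, 45)
        assert "s1" in reg and len(reg) == 1


class TestBoundaryPolicy:
    def test_current_is_identity(self):
        q = ProteinSequence("q", "ACDEFG")
        s = ProteinSequence("s", "ACDEFG")
        aln = _aln(1, 6, 1, 6, "6")
        assert apply_boundary_policy(s, aln, "current") is aln

    def test_history_intersects_with_registry_span(self, blosum62):
        query = ProteinSequence("q", "".join(AA[i % 20] for i in range(60)))
        subject = ProteinSequence("s", query.residues)
        reg = BoundaryRegistry()
        reg.record("s", 10, 50, 10, 50)
        aln = _aln(5, 60, 5, 60, "56")
        out = apply_boundary_policy(
            subject, aln, "history", registry=reg, query=query, matrix=blosum62
        )
        assert (out.q_start, out.q_end, out.s_start, out.s_end) == (10, 50, 10, 50)

    def test_history_first_appearance_passes_through(self, blosum62):
        query = ProteinSequence("q", "ACDEFGHIKL")
        subject = ProteinSequence("s", "ACDEFGHIKL")
        aln = _aln(1, 10, 1, 10, "10")
        out = apply_boundary_policy(
            subject, aln, "history", registry=BoundaryRegistry(), query=query,
            matrix=blosum62,
        )
        assert out is aln

    def test_history_empty_intersection_excludes_hit(self, blosum62):
        query = ProteinSequence("q", "ACDEFGHIKL")
        subject = ProteinSequence("s", "ACDEFGHIKL")
        reg = BoundaryRegistry()
        reg.record("s", 1, 3, 1, 3)
        aln = _aln(6, 10, 6, 10, "5")
        out = apply_boundary_policy(
            subject, aln, "history", registry=reg, query=query, matrix=blosum62
        )
        assert out is None

    def test_domain_policy_trims_to_densest_region(self, blosum62, rng):
        # strong 40%-identity block over the annotated region, random tail:
        # the hit is clamped to the annotated block
        n_block, n_tail = 50, 40
        qb = rng.choice(list(AA), n_block)
        sb = qb.copy()
        for i in rng.choice(n_block, size=int(0.6 * n_block), replace=False):
            sb[i] = rng.choice([c for c in AA if c != qb[i]])
        q = "".join(qb) + "".join(rng.choice(list(AA), n_tail))
        s = "".join(sb) + "".join(rng.choice(list(AA), n_tail))
        query = ProteinSequence("q", q)
        subject = ProteinSequence("s", s)
        aln = _aln(1, 90, 1, 90, "90", raw=50, identity=30.0)
        domains = [
            DomainAnnotation("q", "BLOCK", "", 1, n_block),
            DomainAnnotation("q", "TAIL", "", n_block + 1, 90),
        ]
        out = apply_boundary_policy(
            subject, aln, "domain", domains=domains, query=query, matrix=blosum62
        )
        assert out.q_end <= n_block

    def test_domain_policy_without_overlap_excludes(self, blosum62):
        query = ProteinSequence("q", "ACDEFGHIKL")
        subject = ProteinSequence("s", "ACDEFGHIKL")
        aln = _aln(1, 5, 1, 5, "5")
        out = apply_boundary_policy(
            subject, aln, "domain",
            domains=[DomainAnnotation("q", "D", "", 8, 10)],
            query=query, matrix=blosum62,
        )
        assert out is None


class TestTrim:
    def test_trim_recomputes_subject_coordinates_through_gaps(self, blosum62):
        query = ProteinSequence("q", "ACDEFGHIKL")
        subject = ProteinSequence("s", "ACDFGHIKL")  # E deleted
        aln = _aln(1, 10, 1, 9, "3E-6")
        out = trim_to_query_interval(aln, query, subject, 5, 10, blosum62)
        assert (out.q_start, out.q_end, out.s_start, out.s_end) == (5, 10, 4, 9)
        assert out.btop == "6"


def _row(text, q_start, q_end):
    stripped = text.replace("-", "")
    return MSARow("s0", text, q_start, q_end, 1, max(len(stripped), 1))


class TestFillGaps:
    def test_query_seed_all_gaps(self):
        msa = QueryAnchoredMSA(
            query=ProteinSequence("q", "WYACDEFG"),
            rows=[_row("--AC-E--", 3, 6)],
        )
        filled, lib = fill_gaps(msa, GapFillPolicy("query_seed", "internal_and_end_gaps"))
        assert filled.rows[0].text == "WYACDEFG"
        assert lib[0].residues == "WYACDEFG"

    def test_query_seed_internal_only(self):
        msa = QueryAnchoredMSA(
            query=ProteinSequence("q", "WYACDEFG"),
            rows=[_row("--AC-E--", 3, 6)],
        )
        filled, lib = fill_gaps(msa, GapFillPolicy("query_seed", "internal_gaps_only"))
        assert filled.rows[0].text == "--ACDE--"
        assert lib[0].residues == "ACDE"

    def test_none_is_identity(self):
        msa = QueryAnchoredMSA(
            query=ProteinSequence("q", "WYACDEFG"),
            rows=[_row("--AC-E--", 3, 6)],
        )
        filled, lib = fill_gaps(msa, GapFillPolicy("none", "internal_and_end_gaps"))
        assert filled.rows[0].text == msa.rows[0].text
        assert lib[0].residues == "ACE"

    def test_x_fill(self):
        msa = QueryAnchoredMSA(
            query=ProteinSequence("q", "WYACDEFG"),
            rows=[_row("--AC-E--", 3, 6)],
        )
        filled, _ = fill_gaps(msa, GapFillPolicy("x_fill", "internal_gaps_only"))
        assert filled.rows[0].text == "--ACXE--"

    def test_random_fill_deterministic_under_seed(self):
        msa = QueryAnchoredMSA(
            query=ProteinSequence("q", "WYACDEFG"),
            rows=[_row("--AC-E--", 3, 6)],
        )
        pol = GapFillPolicy("random_fill", "internal_and_end_gaps", rng_seed=42)
        a, _ = fill_gaps(msa, pol)
        b, _ = fill_gaps(msa, pol)
        assert a.rows[0].text == b.rows[0].text
        c, _ = fill_gaps(msa, GapFillPolicy("random_fill", "internal_and_end_gaps", rng_seed=43))
        assert "-" not in a.rows[0].text and "-" not in c.rows[0].text

    @given(st.integers(min_value=0, max_value=10_000))
    def test_query_seed_leaves_no_gaps_and_fills_match_query(self, seed):
        rng = np.random.default_rng(seed)
        L = 20
        query = "".join(rng.choice(list(AA), L))
        chars = list(query)
        for i in rng.choice(L, size=8, replace=False):
            chars[i] = "-"
        lo = next(i for i, c in enumerate(chars) if c != "-") + 1
        hi = L - next(i for i, c in enumerate(reversed(chars)) if c != "-")
        msa = QueryAnchoredMSA(
            query=ProteinSequence("q", query), rows=[_row("".join(chars), lo, hi)]
        )
        filled, _ = fill_gaps(msa, GapFillPolicy("query_seed", "internal_and_end_gaps"))
        text = filled.rows[0].text
        assert "-" not in text
        for i, (orig, new) in enumerate(zip(chars, text)):
            if orig == "-":
                assert new == query[i]
            else:
                assert new == orig
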