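"""Query-anchored MSA assembly, alignment-boundary policies, and gap seeding.

This module holds the central idea of the package: PSSMs in an iterative
search are built from a query-anchored MSA implied by the pairwise
alignments, and gapped positions in the subject rows can be *seeded* with
the aligned query residue before PSSM construction.  Seeding anchors the
model to the original query, raises the information content at gappy
columns, and sharply reduces model contamination through homologous
over-extension.

Boundary policies control how far a subject row may extend: ``current``
keeps the alignment as found, ``history`` clamps it to the span recorded
the first time the subject scored significantly, and ``domain`` clamps it
to the annotated query domain with the highest sub-alignment score density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import btop as _btop
from .alignkit import (
    LocalAlignment,
    SubstitutionMatrix,
    subalignment_scores,
)
from .seqio import STANDARD_AA, DomainAnnotation, ProteinSequence

GAP = "-"

FILL_MODES = ("none", "query_seed", "x_fill", "random_fill")
FILL_SCOPES = ("internal_gaps_only", "internal_and_end_gaps")
BOUNDARY_POLICIES = ("current", "history", "domain")


@dataclass(frozen=True)
class GapFillPolicy:
    """How gaps in subject rows are replaced before PSSM construction.

    The default is the winning configuration: seed the aligned query residue
    into both internal and end gaps.
    """

    mode: str = "query_seed"
    scope: str = "internal_and_end_gaps"
    rng_seed: int = 0

    def __post_init__(self):
        if self.mode not in FILL_MODES:
            raise ValueError(f"unknown fill mode {self.mode!r}")
        if self.scope not in FILL_SCOPES:
            raise ValueError(f"unknown fill scope {self.scope!r}")


@dataclass
class MSARow:
    """One subject row: exactly query-length columns over residues + '-'."""

    subject_id: str
    text: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    iteration: int = 0
    #: subject residues aligned to query-side insertions, dropped from the
    #: row (1-based subject position, residue) — kept for diagnostics
    insertions: tuple = ()


@dataclass
class QueryAnchoredMSA:
    """Query row plus subject rows, one column per query residue."""

    query: ProteinSequence
    rows: list[MSARow]

    def __post_init__(self):
        L = len(self.query.residues)
        for row in self.rows:
            if len(row.text) != L:
                raise ValueError(
                    f"row {row.subject_id}: length {len(row.text)} != query length {L}"
                )


class BoundaryRegistry:
    """Per-subject first-significant-alignment spans (write-once)."""

    def __init__(self):
        self._spans: dict[str, tuple[int, int, int, int]] = {}

    def record(self, subject_id: str, q_start: int, q_end: int, s_start: int, s_end: int) -> bool:
        """Record a span; returns False (and keeps the original) if the
        subject was already registered."""
        if subject_id in self._spans:
            return False
        self._spans[subject_id] = (q_start, q_end, s_start, s_end)
        return True

    def get(self, subject_id: str) -> tuple[int, int, int, int] | None:
        return self._spans.get(subject_id)

    def __contains__(self, subject_id: str) -> bool:
        return subject_id in self._spans

    def __len__(self) -> int:
        return len(self._spans)


def build_query_msa(
    query: ProteinSequence,
    hits: Sequence[tuple[ProteinSequence, LocalAlignment]],
    iteration: int = 0,
) -> QueryAnchoredMSA:
    """Assemble the query-anchored MSA implied by pairwise alignments.

    Columns are query positions.  Subject residues aligned to a query-side
    gap (insertions relative to the query) are deleted from the row and
    recorded in the row metadata; positions outside the aligned span stay
    '-' (end gaps).
    """
    seen: set[str] = set()
    L = len(query.residues)
    rows: list[MSARow] = []
    for subject, aln in hits:
        if subject.id in seen:
            raise ValueError(f"two hits for subject {subject.id!r}; pre-select one")
        seen.add(subject.id)
        qseg = query.residues[aln.q_start - 1 : aln.q_end]
        sseg = subject.residues[aln.s_start - 1 : aln.s_end]
        qrow, srow = _btop.btop_decode(aln.btop, qseg, sseg)
        text = [GAP] * L
        inserts: list[tuple[int, str]] = []
        qpos, spos = aln.q_start - 1, aln.s_start - 1  # last consumed, 1-based
        for qc, sc in zip(qrow, srow):
            if qc == GAP:
                spos += 1
                inserts.append((spos, sc))
            elif sc == GAP:
                qpos += 1
            else:
                qpos += 1
                spos += 1
                text[qpos - 1] = sc
        rows.append(
            MSARow(
                subject_id=subject.id,
                text="".join(text),
                q_start=aln.q_start,
                q_end=aln.q_end,
                s_start=aln.s_start,
                s_end=aln.s_end,
                iteration=iteration,
                insertions=tuple(inserts),
            )
        )
    return QueryAnchoredMSA(query=query, rows=rows)


def trim_to_query_interval(
    aln: LocalAlignment,
    query: ProteinSequence,
    subject: ProteinSequence,
    lo: int,
    hi: int,
    matrix: SubstitutionMatrix | None = None,
) -> LocalAlignment | None:
    """Restrict an alignment to query positions ``lo..hi`` via the BTOP walk.

    Leading/trailing gap columns of the restriction are stripped; subject
    coordinates are recomputed.  Returns ``None`` when nothing remains.
    The raw score is recomputed under ``matrix`` when given (the E-value of
    the original, untrimmed alignment is retained either way).
    """
    lo = max(lo, aln.q_start)
    hi = min(hi, aln.q_end)
    if lo > hi:
        return None
    qseg = query.residues[aln.q_start - 1 : aln.q_end]
    sseg = subject.residues[aln.s_start - 1 : aln.s_end]
    qrow, srow = _btop.btop_decode(aln.btop, qseg, sseg)
    cols: list[tuple[str, str]] = []
    qpos = aln.q_start - 1
    spans: list[tuple[int | None, int | None]] = []
    spos = aln.s_start - 1
    for qc, sc in zip(qrow, srow):
        if qc != GAP:
            qpos += 1
        if sc != GAP:
            spos += 1
        if lo <= qpos <= hi:
            cols.append((qc, sc))
            spans.append((qpos if qc != GAP else None, spos if sc != GAP else None))
    # strip edge columns that do not align a residue pair
    while cols and (cols[0][0] == GAP or cols[0][1] == GAP):
        cols.pop(0)
        spans.pop(0)
    while cols and (cols[-1][0] == GAP or cols[-1][1] == GAP):
        cols.pop()
        spans.pop()
    if not cols:
        return None
    qtext = "".join(c[0] for c in cols)
    stext = "".join(c[1] for c in cols)
    q0 = next(q for q, _ in spans if q is not None)
    q1 = next(q for q, _ in reversed(spans) if q is not None)
    s0 = next(s for _, s in spans if s is not None)
    s1 = next(s for _, s in reversed(spans) if s is not None)
    identities = sum(1 for a, b in cols if a == b and a != GAP)
    if matrix is not None:
        score = 0
        gap_side = None
        for qc, sc in cols:
            if qc != GAP and sc != GAP:
                score += matrix.score(qc, sc)
                gap_side = None
            else:
                side = "q" if qc == GAP else "s"
                score += (
                    -(matrix.gap_open + matrix.gap_extend)
                    if gap_side != side
                    else -matrix.gap_extend
                )
                gap_side = side
    else:
        score = aln.raw_score
    return LocalAlignment(
        q_start=q0,
        q_end=q1,
        s_start=s0,
        s_end=s1,
        raw_score=int(score),
        percent_identity=100.0 * identities / len(cols),
        btop=_btop.btop_encode(qtext, stext),
        evalue=aln.evalue,
        bit_score=aln.bit_score,
    )


def apply_boundary_policy(
    subject: ProteinSequence,
    aln: LocalAlignment,
    policy: str,
    registry: BoundaryRegistry | None = None,
    domains: Sequence[DomainAnnotation] | None = None,
    query: ProteinSequence | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> LocalAlignment | None:
    """Trim one hit according to the selected boundary policy.

    Returns the (possibly trimmed) alignment, or ``None`` when the hit is
    excluded (empty intersection with the registry span, or — under the
    domain policy — no overlap with any annotated query region).
    """
    if policy not in BOUNDARY_POLICIES:
        raise ValueError(f"unknown boundary policy {policy!r}")
    if policy == "current":
        return aln
    if query is None:
        raise ValueError("history/domain policies need the query sequence")
    if policy == "history":
        if registry is None:
            raise ValueError("history policy needs a BoundaryRegistry")
        span = registry.get(subject.id)
        if span is None:
            return aln
        lo, hi = span[0], span[1]
        return trim_to_query_interval(aln, query, subject, lo, hi, matrix)
    # domain policy: keep the annotated query region with the highest
    # sub-alignment score density among regions overlapping the hit
    if not domains or matrix is None:
        raise ValueError("domain policy needs query annotations and a matrix")
    overlapping = [
        d for d in domains if d.start <= aln.q_end and d.end >= aln.q_start
    ]
    if not overlapping:
        return None
    parts = subalignment_scores(aln, query, subject, overlapping, matrix, on="query")
    scored = [p for p in parts if p.region is not None and p.columns > 0]
    if not scored:
        return None
    best = max(scored, key=lambda p: (p.density, -p.region.start))
    return trim_to_query_interval(
        aln, query, subject, best.region.start, best.region.end, matrix
    )


def fill_gaps(
    msa: QueryAnchoredMSA,
    policy: GapFillPolicy,
    background: np.ndarray | None = None,
) -> tuple[QueryAnchoredMSA, list[ProteinSequence]]:
    """Apply a gap-fill policy; returns the filled MSA and the subject library.

    ``query_seed`` replaces each in-scope gap with the query residue of that
    column, ``x_fill`` with 'X', ``random_fill`` with a residue drawn from
    ``background`` (uniform over the 20 residues when omitted) using the
    policy's ``rng_seed``.  The library holds each row's non-gap text (fills
    included) as an ungapped sequence — the custom subject database that,
    together with the MSA, feeds PSSM construction.
    """
    query_row = msa.query.residues
    rng = np.random.default_rng(policy.rng_seed)
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()

    filled_rows: list[MSARow] = []
    library: list[ProteinSequence] = []
    for row in msa.rows:
        chars = list(row.text)
        for i, c in enumerate(chars):
            if c != GAP:
                continue
            internal = row.q_start <= i + 1 <= row.q_end
            if policy.scope == "internal_gaps_only" and not internal:
                continue
            if policy.mode == "none":
                continue
            elif policy.mode == "query_seed":
                chars[i] = query_row[i]
            elif policy.mode == "x_fill":
                chars[i] = "X"
            else:  # random_fill
                chars[i] = STANDARD_AA[int(rng.choice(20, p=background))]
        text = "".join(chars)
        filled_rows.append(replace(row, text=text))
        fragment = text.replace(GAP, "")
        if fragment:
            library.append(ProteinSequence(row.subject_id, fragment))
    return QueryAnchoredMSA(query=msa.query, rows=filled_rows), library
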