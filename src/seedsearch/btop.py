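"""Encode and decode BTOP (BLAST trace-back operations) alignment strings.

BTOP is the compact alignment encoding emitted by BLAST tabular output and
by ssearch ``-m 8CB``: a run-length integer denotes that many aligned
identical residue pairs, and each 2-character token encodes one non-match
column as (query character, subject character), with ``-`` standing for a
gap on that side.  ``"3ED1"`` therefore reads: 3 matches, an E/D mismatch,
1 match.
"""

from __future__ import annotations

from typing import Iterator

GAP = "-"


class BtopError(ValueError):
    """Raised when a BTOP string is malformed or inconsistent with its segments."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at BTOP offset {offset})"
        super().__init__(message)
        self.offset = offset


def tokenize(btop: str) -> Iterator[tuple[int, object]]:
    """Yield ``(offset, token)`` pairs; token is an int match-run or a 2-char str.

    Zero-length match runs are tolerated on input (some emitters produce
    them between adjacent edit tokens) but never re-emitted by :func:`btop_encode`.
    """
    i, n = 0, len(btop)
    while i < n:
        c = btop[i]
        if c.isdigit():
            j = i
            while j < n and btop[j].isdigit():
                j += 1
            yield i, int(btop[i:j])
            i = j
        else:
            if i + 1 >= n:
                raise BtopError("dangling edit-token character", i)
            yield i, btop[i : i + 2]
            i += 2


def consumed_lengths(btop: str) -> tuple[int, int]:
    """Number of (query, subject) residues a BTOP string consumes."""
    q = s = 0
    for _, tok in tokenize(btop):
        if isinstance(tok, int):
            q += tok
            s += tok
        else:
            if tok[0] != GAP:
                q += 1
            if tok[1] != GAP:
                s += 1
            if tok[0] == GAP and tok[1] == GAP:
                raise BtopError("token with gap on both sides")
    return q, s


def btop_decode(btop: str, query_segment: str, subject_segment: str) -> tuple[str, str]:
    """Expand a BTOP string into two equal-length gapped alignment rows.

    ``query_segment`` / ``subject_segment`` are the exact (ungapped) residue
    stretches spanned by the alignment.  Residue letters embedded in edit
    tokens are checked against the segments; a disagreement means the BTOP
    does not belong to these sequences.
    """
    qrow: list[str] = []
    srow: list[str] = []
    qi = si = 0
    for off, tok in tokenize(btop):
        if isinstance(tok, int):
            if qi + tok > len(query_segment) or si + tok > len(subject_segment):
                raise BtopError("match run overruns segment", off)
            qrow.append(query_segment[qi : qi + tok])
            srow.append(subject_segment[si : si + tok])
            qi += tok
            si += tok
        else:
            qc, sc = tok
            if qc == GAP and sc == GAP:
                raise BtopError("token with gap on both sides", off)
            if qc != GAP:
                if qi >= len(query_segment):
                    raise BtopError("edit token overruns query segment", off)
                if query_segment[qi] != qc:
                    raise BtopError(
                        f"query letter {qc!r} disagrees with segment "
                        f"{query_segment[qi]!r} at residue {qi + 1}",
                        off,
                    )
                qi += 1
            if sc != GAP:
                if si >= len(subject_segment):
                    raise BtopError("edit token overruns subject segment", off)
                if subject_segment[si] != sc:
                    raise BtopError(
                        f"subject letter {sc!r} disagrees with segment "
                        f"{subject_segment[si]!r} at residue {si + 1}",
                        off,
                    )
                si += 1
            qrow.append(qc)
            srow.append(sc)
    if qi != len(query_segment) or si != len(subject_segment):
        raise BtopError(
            f"BTOP consumes ({qi}, {si}) residues but segments have "
            f"({len(query_segment)}, {len(subject_segment)})"
        )
    return "".join(qrow), "".join(srow)


def btop_encode(query_row: str, subject_row: str) -> str:
    """Inverse of :func:`btop_decode`: gapped rows to canonical BTOP text.

    Canonical form merges adjacent match columns into a single maximal run
    and never emits zero-length runs.
    """
    if len(query_row) != len(subject_row):
        raise BtopError("rows differ in length")
    out: list[str] = []
    run = 0
    for col, (qc, sc) in enumerate(zip(query_row, subject_row)):
        if qc == GAP and sc == GAP:
            raise BtopError(f"column {col + 1} has gaps in both rows")
        if qc == sc and qc != GAP:
            run += 1
        else:
            if run:
                out.append(str(run))
                run = 0
            out.append(qc + sc)
    if run:
        out.append(str(run))
    return "".join(out)


def walk_positions(
    btop: str, q_start: int, s_start: int
) -> Iterator[tuple[int | None, int | None]]:
    """Yield per-column 1-based ``(query_pos, subject_pos)``; ``None`` marks a gap.

    Needs only the BTOP text, not the sequences — handy for coordinate
    bookkeeping (trimming, benchmark overlap tests).
    """
    q, s = q_start, s_start
    for _, tok in tokenize(btop):
        if isinstance(tok, int):
            for _ in range(tok):
                yield q, s
                q += 1
                s += 1
        else:
            qc, sc = tok
            if qc != GAP and sc != GAP:
                yield q, s
                q += 1
                s += 1
            elif sc == GAP:
                yield q, None
                q += 1
            else:
                yield None, s
                s += 1
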