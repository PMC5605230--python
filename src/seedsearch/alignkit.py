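"""Local alignment kernels, extreme-value statistics, and sub-alignment scoring.

Implements Smith-Waterman with affine gaps in two modes — sequence against
sequence under a substitution matrix, and profile (PSSM) against sequence —
plus the Karlin-Altschul / Gumbel machinery that turns raw scores into
E-values, and the sub-alignment score partition used to expose low
score-density over-extended alignment segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import _swkernel, btop as _btop
from .seqio import (
    STANDARD_AA,
    AlphabetError,
    DomainAnnotation,
    FormatError,
    ProteinSequence,
)

#: published gapped Karlin-Altschul parameters for BLOSUM62 with
#: gap open 11 / extend 1 (the BLAST protein defaults)
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


class FitError(RuntimeError):
    """The score distribution could not be fitted (degenerate input)."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution matrix with affine gap penalties."""

    alphabet: str
    matrix: np.ndarray  # (A, A) int
    gap_open: int = 11
    gap_extend: int = 1
    name: str = ""

    def __post_init__(self):
        a = len(self.alphabet)
        if self.matrix.shape != (a, a):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.alphabet)}
        )

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[self._index[a], self._index[b]])

    def encode(self, residues: str) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in residues], dtype=np.int64)
        except KeyError as exc:
            raise AlphabetError(f"residue {exc.args[0]!r} not in matrix alphabet")

    @classmethod
    def blosum62(cls, gap_open: int = 11, gap_extend: int = 1) -> "SubstitutionMatrix":
        """BLOSUM62 over the 20 standard residues + 'X', from Biopython's copy
        of the NCBI matrix."""
        from Bio.Align import substitution_matrices

        src = substitution_matrices.load("BLOSUM62")
        alphabet = STANDARD_AA + "X"
        mat = np.array(
            [[int(src[a, b]) for b in alphabet] for a in alphabet], dtype=np.int64
        )
        return cls(alphabet, mat, gap_open, gap_extend, name="BLOSUM62")

    @classmethod
    def from_ncbi_file(cls, path, gap_open: int = 11, gap_extend: int = 1):
        """Parse a matrix in NCBI text format ('#' comments, header row of
        letters, one labelled score row per letter)."""
        header: list[str] = []
        rows: dict[str, list[int]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if not header:
                    header = fields
                    continue
                rows[fields[0]] = [int(v) for v in fields[1 : len(header) + 1]]
        if not header or not rows:
            raise FormatError(f"{path}: not an NCBI matrix file")
        keep = [c for c in header if c in set(STANDARD_AA + "X") and c in rows]
        alphabet = "".join(keep)
        idx = {c: header.index(c) for c in keep}
        mat = np.array(
            [[rows[a][idx[b]] for b in keep] for a in keep], dtype=np.int64
        )
        return cls(alphabet, mat, gap_open, gap_extend, name=str(path))


@dataclass
class LocalAlignment:
    """One pairwise local alignment (coordinates 1-based inclusive)."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    raw_score: int
    percent_identity: float
    btop: str
    evalue: float | None = None
    bit_score: float | None = None

    @property
    def alignment_length(self) -> int:
        q, s = _btop.consumed_lengths(self.btop)
        ncols = 0
        for _, tok in _btop.tokenize(self.btop):
            ncols += tok if isinstance(tok, int) else 1
        return ncols


@dataclass(frozen=True)
class EVDParams:
    """Gumbel (extreme-value) parameters: ``E = K * m * n * exp(-lambda * S)``."""

    lam: float
    K: float
    db_residues: int
    db_sequences: int

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class DatabaseSummary:
    """Problem-size bookkeeping needed to calibrate E-values."""

    residues: int
    sequences: int
    query_length: int


def gapped_blosum62_params(db_residues: int, db_sequences: int) -> EVDParams:
    return EVDParams(
        BLOSUM62_GAPPED_LAMBDA, BLOSUM62_GAPPED_K, db_residues, db_sequences
    )


def evalue(params: EVDParams, raw_score, query_len: int):
    """Database expectation for a raw score (vectorized over ``raw_score``)."""
    return params.K * query_len * params.db_residues * np.exp(
        -params.lam * np.asarray(raw_score, dtype=float)
    )


def bit_score(params: EVDParams, raw_score) -> float:
    return (params.lam * float(raw_score) - math.log(params.K)) / math.log(2.0)


def fit_evd(scores: Sequence[float], db: DatabaseSummary, max_rounds: int = 5) -> EVDParams:
    """Maximum-likelihood Gumbel fit to a database score distribution.

    The high tail (scores whose fitted E-value is below 1 — the candidate
    homologs) is iteratively censored and the null refitted, at most
    ``max_rounds`` times.  K is anchored so that a score at the fitted
    location has expectation ~1 per average-length subject.
    """
    values = np.asarray(list(scores), dtype=float)
    if values.size < 50:
        raise FitError(f"need >= 50 scores to fit, got {values.size}")
    if np.ptp(values) == 0:
        raise FitError("degenerate (constant) score distribution")
    n_bar = db.residues / db.sequences

    def to_params(loc: float, scale: float) -> EVDParams:
        if not np.isfinite(scale) or scale <= 0:
            raise FitError("Gumbel fit collapsed")
        lam = 1.0 / scale
        K = math.exp(lam * loc) / (db.query_length * n_bar)
        return EVDParams(lam, K, db.residues, db.sequences)

    # initialize from the bulk of the distribution so that a heavy homolog
    # tail cannot flatten the first fit beyond the reach of censoring
    bulk = np.sort(values)[: max(50, int(0.8 * values.size))]
    if np.ptp(bulk) == 0:
        raise FitError("degenerate (constant) score distribution")
    params = to_params(*stats.gumbel_r.fit(bulk))
    kept = values
    for _ in range(max_rounds):
        mask = evalue(params, kept, db.query_length) >= 1.0
        if mask.sum() < 50:
            break
        kept = kept[mask]
        params = to_params(*stats.gumbel_r.fit(kept))
        if mask.all():
            break
    return params


# ---------------------------------------------------------------------------
# alignment kernels


def _finish_alignment(
    ops: np.ndarray,
    q0: int,
    s0: int,
    raw: int,
    query_residues: str,
    subject_residues: str,
) -> LocalAlignment:
    qrow: list[str] = []
    srow: list[str] = []
    qi, si = q0 - 1, s0 - 1
    for op in ops:
        if op == 0:
            qrow.append(query_residues[qi])
            srow.append(subject_residues[si])
            qi += 1
            si += 1
        elif op == 1:
            qrow.append(query_residues[qi])
            srow.append(_btop.GAP)
            qi += 1
        else:
            qrow.append(_btop.GAP)
            srow.append(subject_residues[si])
            si += 1
    qtext, stext = "".join(qrow), "".join(srow)
    identities = sum(1 for a, b in zip(qtext, stext) if a == b and a != _btop.GAP)
    ncols = len(qtext)
    return LocalAlignment(
        q_start=q0,
        q_end=qi,
        s_start=s0,
        s_end=si,
        raw_score=int(raw),
        percent_identity=100.0 * identities / ncols,
        btop=_btop.btop_encode(qtext, stext),
    )


def _profile_align(
    profile: np.ndarray,
    subject_idx: np.ndarray,
    query_residues: str,
    subject_residues: str,
    gap_open: int,
    gap_extend: int,
) -> LocalAlignment | None:
    best, bi, bj, H, E, F = _swkernel.sw_fill(
        profile, subject_idx, gap_open, gap_extend
    )
    if best <= 0:
        return None
    ops, q0, s0 = _swkernel.sw_traceback(
        H, E, F, profile, subject_idx, bi, bj, gap_open, gap_extend
    )
    return _finish_alignment(ops, q0, s0, best, query_residues, subject_residues)


def smith_waterman(
    query: ProteinSequence,
    subject: ProteinSequence,
    matrix: SubstitutionMatrix,
) -> LocalAlignment | None:
    """Optimal local alignment of two sequences under affine gap penalties.

    Returns ``None`` when no cell scores above zero (no-hit).
    """
    if not query.residues or not subject.residues:
        raise ValueError("sequences must be non-empty")
    profile = matrix.matrix[matrix.encode(query.residues)]
    subject_idx = matrix.encode(subject.residues)
    return _profile_align(
        profile,
        subject_idx,
        query.residues,
        subject.residues,
        matrix.gap_open,
        matrix.gap_extend,
    )


def pssm_search(
    pssm,
    subject: ProteinSequence,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> LocalAlignment | None:
    """Local alignment of a PSSM against a sequence.

    The match score at (position i, subject residue a) is ``pssm.scores[i, a]``;
    the query side of the BTOP comes from the PSSM's query sequence.
    """
    if pssm.positions < 1:
        raise ValueError("PSSM must have at least one position")
    index = {c: i for i, c in enumerate(STANDARD_AA)}
    try:
        subject_idx = np.array(
            [index[c] for c in subject.residues], dtype=np.int64
        )
    except KeyError as exc:
        raise AlphabetError(
            f"subject {subject.id!r} residue {exc.args[0]!r} outside PSSM alphabet"
        )
    profile = np.ascontiguousarray(pssm.scores, dtype=np.int64)
    return _profile_align(
        profile,
        subject_idx,
        pssm.query.residues,
        subject.residues,
        gap_open,
        gap_extend,
    )


# ---------------------------------------------------------------------------
# sub-alignment scoring


@dataclass(frozen=True)
class RegionScore:
    """Score (and column count) contributed by one annotated region;
    ``region=None`` is the unannotated remainder."""

    region: DomainAnnotation | None
    score: int
    columns: int

    @property
    def density(self) -> float:
        return self.score / self.columns if self.columns else 0.0


def subalignment_scores(
    alignment: LocalAlignment,
    query: ProteinSequence,
    subject: ProteinSequence,
    regions: Sequence[DomainAnnotation],
    matrix: SubstitutionMatrix,
    on: str = "subject",
) -> list[RegionScore]:
    """Partition an alignment's raw score across annotated regions.

    Each aligned column is charged to the region containing its residue on
    the ``on`` axis; a whole gap run is charged to the region active at the
    run's first column.  The partition is exact: the per-region scores plus
    the unannotated remainder sum to ``alignment.raw_score``.
    """
    if on not in ("subject", "query"):
        raise ValueError("on must be 'subject' or 'query'")
    spans = sorted(regions, key=lambda r: r.start)
    for a, b in zip(spans, spans[1:]):
        if a.end >= b.start:
            raise ValueError("regions must be non-overlapping")

    def region_at(pos: int | None) -> DomainAnnotation | None:
        if pos is None:
            return None
        for r in spans:
            if r.start <= pos <= r.end:
                return r
        return None

    qseg = query.residues[alignment.q_start - 1 : alignment.q_end]
    sseg = subject.residues[alignment.s_start - 1 : alignment.s_end]
    qrow, srow = _btop.btop_decode(alignment.btop, qseg, sseg)

    go, ge = matrix.gap_open, matrix.gap_extend
    scores: dict[DomainAnnotation | None, int] = {}
    columns: dict[DomainAnnotation | None, int] = {}
    qpos, spos = alignment.q_start - 1, alignment.s_start - 1  # last consumed
    gap_side: str | None = None  # a side switch opens a new gap in the affine DP
    gap_region: DomainAnnotation | None = None
    for qc, sc in zip(qrow, srow):
        if qc != _btop.GAP and sc != _btop.GAP:
            qpos += 1
            spos += 1
            gap_side = None
            reg = region_at(spos if on == "subject" else qpos)
            col_score = matrix.score(qc, sc)
        else:
            side = "q" if qc == _btop.GAP else "s"
            if side == "q":
                spos += 1
            else:
                qpos += 1
            if gap_side != side:
                # anchor the run at its first column's position on the axis
                anchor = spos if on == "subject" else qpos
                gap_region = region_at(anchor)
                col_score = -(go + ge)
                gap_side = side
            else:
                col_score = -ge
            reg = gap_region
        scores[reg] = scores.get(reg, 0) + col_score
        columns[reg] = columns.get(reg, 0) + 1

    out = [RegionScore(r, scores.get(r, 0), columns.get(r, 0)) for r in spans]
    out.append(RegionScore(None, scores.get(None, 0), columns.get(None, 0)))
    return out
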