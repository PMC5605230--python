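"""Readers and writers for the on-disk formats used by the search pipeline.

Formats: FASTA (sequences and aligned-FASTA MSAs), BLAST-style commented
tabular hit files with a BTOP column, domain-annotation TSV, and PSSM
serialization (TSV score table plus a JSON metadata sidecar).

External files use 1-based inclusive coordinates (the BLAST convention);
any 0-based arithmetic is internal to the modules that need it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import btop as _btop

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AA = STANDARD_AA + "X"
_VALID_RESIDUES = frozenset(EXTENDED_AA)

#: column order of the tabular hit format (BLAST outfmt-7 shape + BTOP)
TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore btop"
).split()


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class AlphabetError(ValueError):
    """A sequence contains a letter outside the amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinSequence:
    """An uppercase protein sequence over the 20 standard residues plus 'X'."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise AlphabetError(f"sequence {self.id!r} is empty")
        if not set(self.residues) <= _VALID_RESIDUES:
            for pos, ch in enumerate(self.residues, start=1):
                if ch not in _VALID_RESIDUES:
                    raise AlphabetError(
                        f"illegal residue {ch!r} at position {pos} of record {self.id!r}"
                    )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated domain instance: ``seq_id[start..end]`` (1-based inclusive)."""

    seq_id: str
    domain_id: str
    clan_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"domain {self.domain_id} on {self.seq_id}: "
                f"invalid span {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TabularHitRecord:
    """One row of the tabular hit format (coordinates 1-based inclusive)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    btop: str

    def __post_init__(self):
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: reversed coordinates"
            )
        q_used, s_used = _btop.consumed_lengths(self.btop)
        if q_used != self.q_end - self.q_start + 1:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: BTOP consumes {q_used} "
                f"query residues but span is {self.q_end - self.q_start + 1}"
            )
        if s_used != self.s_end - self.s_start + 1:
            raise FormatError(
                f"hit {self.query_id}/{self.subject_id}: BTOP consumes {s_used} "
                f"subject residues but span is {self.s_end - self.s_start + 1}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[ProteinSequence]:
    """Read a protein FASTA file; wrapped lines are concatenated, whitespace
    stripped and lowercase folded to uppercase."""
    records: list[ProteinSequence] = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(maxsplit=1)
            seq_id = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            residues = "".join(seq.split()).upper()
            records.append(ProteinSequence(seq_id, residues, desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in sequences:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def write_afa(rows: Sequence[tuple[str, str]], path) -> None:
    """Write an aligned-FASTA MSA: ``rows`` are ``(id, gapped text)`` pairs,
    query first by convention."""
    with open(path, "w") as out:
        for name, text in rows:
            out.write(f">{name}\n{text}\n")


# ---------------------------------------------------------------------------
# tabular hits


def _btop_mismatches_gapopens(btop_text: str) -> tuple[int, int]:
    mismatch = 0
    gapopen = 0
    prev_gap = False
    for _, tok in _btop.tokenize(btop_text):
        if isinstance(tok, int):
            prev_gap = False
            continue
        if _btop.GAP in tok:
            if not prev_gap:
                gapopen += 1
            prev_gap = True
        else:
            mismatch += 1
            prev_gap = False
    return mismatch, gapopen


def write_tabular_hits(hits: Iterable[TabularHitRecord], path, comments: Sequence[str] = ()) -> None:
    """Write hits as commented tab-separated text (13 columns incl. BTOP).

    Floats are written with full round-trip precision so that
    ``read(write(x)) == x`` holds exactly.
    """
    with open(path, "w") as out:
        out.write("# Fields: " + ", ".join(TABULAR_COLUMNS) + "\n")
        for line in comments:
            out.write(f"# {line}\n")
        for h in hits:
            mismatch, gapopen = _btop_mismatches_gapopens(h.btop)
            fields = [
                h.query_id,
                h.subject_id,
                repr(float(h.percent_identity)),
                str(h.alignment_length),
                str(mismatch),
                str(gapopen),
                str(h.q_start),
                str(h.q_end),
                str(h.s_start),
                str(h.s_end),
                repr(float(h.evalue)),
                repr(float(h.bit_score)),
                h.btop,
            ]
            out.write("\t".join(fields) + "\n")


def read_tabular_hits(path) -> list[TabularHitRecord]:
    """Read a commented tabular hit file; '#' lines are skipped, extra trailing
    columns are ignored."""
    hits: list[TabularHitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(TABULAR_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(TABULAR_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            try:
                rec = TabularHitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                    btop=fields[12],
                )
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(rec)
    return hits


# ---------------------------------------------------------------------------
# domain annotations

_DOMAIN_COLUMNS = ["seq_id", "domain_id", "clan_id", "start", "end"]


def read_domains(path) -> list[DomainAnnotation]:
    """Read a 5-column domain TSV (header optional, '#' comments skipped).

    Columns: seq_id, domain_id, clan_id (may be empty), start, end.
    """
    out: list[DomainAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:5] == _DOMAIN_COLUMNS:
                continue  # header row
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(
                DomainAnnotation(fields[0], fields[1], fields[2], start, end)
            )
    return out


def write_domains(annotations: Iterable[DomainAnnotation], path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(_DOMAIN_COLUMNS) + "\n")
        for a in annotations:
            out.write(f"{a.seq_id}\t{a.domain_id}\t{a.clan_id}\t{a.start}\t{a.end}\n")


def annotations_by_sequence(
    annotations: Iterable[DomainAnnotation],
) -> dict[str, list[DomainAnnotation]]:
    by_seq: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        by_seq.setdefault(a.seq_id, []).append(a)
    return by_seq


# ---------------------------------------------------------------------------
# PSSM serialization (TSV score table + JSON metadata sidecar)


def write_pssm(pssm, path) -> None:
    """Serialize a PSSM as a human-readable integer score table plus a JSON
    sidecar (``<path>.meta.json``) holding the query, statistics, and the
    full-precision frequencies / unrounded scores."""
    path = Path(path)
    alphabet = STANDARD_AA
    with open(path, "w") as out:
        out.write("pos\tres\t" + "\t".join(alphabet) + "\n")
        for i in range(pssm.positions):
            row = "\t".join(str(int(v)) for v in pssm.scores[i])
            out.write(f"{i + 1}\t{pssm.query.residues[i]}\t{row}\n")
    meta = {
        "query_id": pssm.query.id,
        "query_description": pssm.query.description,
        "query_residues": pssm.query.residues,
        "alphabet": alphabet,
        "lambda": None if pssm.params is None else pssm.params.lam,
        "K": None if pssm.params is None else pssm.params.K,
        "db_residues": None if pssm.params is None else pssm.params.db_residues,
        "db_sequences": None if pssm.params is None else pssm.params.db_sequences,
        "raw_scores": [list(map(float, row)) for row in pssm.raw_scores],
        "freqs": [list(map(float, row)) for row in pssm.freqs],
        "n_eff": [float(v) for v in pssm.n_eff],
        "background": [float(v) for v in pssm.background],
    }
    with open(path.with_name(path.name + ".meta.json"), "w") as out:
        json.dump(meta, out)


def read_pssm(path):
    """Inverse of :func:`write_pssm`; returns a ``pssmkit.PSSM``."""
    import numpy as np

    from .alignkit import EVDParams
    from .pssmkit import PSSM

    path = Path(path)
    scores: list[list[int]] = []
    residues: list[str] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["pos", "res"] or "".join(header[2:]) != STANDARD_AA:
            raise FormatError(f"{path}: not a PSSM score table")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 + len(STANDARD_AA):
                raise FormatError(f"{path}:{lineno}: bad column count")
            residues.append(fields[1])
            scores.append([int(v) for v in fields[2:]])
    meta_path = path.with_name(path.name + ".meta.json")
    with open(meta_path) as handle:
        meta = json.load(handle)
    if meta["query_residues"] != "".join(residues):
        raise FormatError(f"{path}: score table and sidecar disagree on the query")
    params = None
    if meta["lambda"] is not None:
        params = EVDParams(
            lam=meta["lambda"],
            K=meta["K"],
            db_residues=meta["db_residues"],
            db_sequences=meta["db_sequences"],
        )
    return PSSM(
        query=ProteinSequence(
            meta["query_id"], meta["query_residues"], meta["query_description"]
        ),
        scores=np.asarray(scores, dtype=np.int32),
        raw_scores=np.asarray(meta["raw_scores"], dtype=float),
        freqs=np.asarray(meta["freqs"], dtype=float),
        n_eff=np.asarray(meta["n_eff"], dtype=float),
        background=np.asarray(meta["background"], dtype=float),
        params=params,
    )


def hit_sort_key(hit: TabularHitRecord) -> tuple:
    """Stable ordering for reported hits: ascending E-value, then subject id."""
    return (hit.evalue, -hit.bit_score, hit.subject_id)
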