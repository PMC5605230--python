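"""Benchmark machinery: embedded queries, TP/FP classification, and metrics.

The benchmark embeds a genuine domain in random flanking sequence (flanks of
``floor(domain_length / 2)`` on each side, so a 200-residue domain yields a
400-residue query).  Because everything outside the embedded domain is
random, any alignment there is non-homologous by construction: a hit is a
true positive only when the query-domain part of the alignment lands on a
subject domain of the same family (or clan); anything else reported below
the scoring threshold is a false positive.  Full-length queries are scored
only inside the annotated query domain — alignments elsewhere are ignored.

Sensitivity is family coverage TP/(TP+FN); FDR is FP/(TP+FP), defined as 0
when nothing is reported.  Multi-query summaries weight every query
equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import btop as _btop
from .seqio import (
    STANDARD_AA,
    DomainAnnotation,
    ProteinSequence,
    TabularHitRecord,
)

#: reported-alignment significance threshold used for scoring
REPORT_EVALUE = 1e-3


@dataclass(frozen=True)
class BenchQuery:
    """A query with a scored domain interval (full-length mode)."""

    sequence: ProteinSequence
    domain_id: str
    clan_id: str
    domain_start: int
    domain_end: int

    @property
    def embedded(self) -> bool:
        return False


@dataclass(frozen=True)
class EmbeddedQuery(BenchQuery):
    """A domain embedded in random flanks; alignments outside the domain are
    false positives rather than ignored."""

    flank_len_left: int = 0
    flank_len_right: int = 0

    def __post_init__(self):
        dlen = self.domain_end - self.domain_start + 1
        if self.flank_len_left != self.flank_len_right:
            raise ValueError("flanks must be equal length")
        if len(self.sequence.residues) != dlen + self.flank_len_left + self.flank_len_right:
            raise ValueError("sequence length inconsistent with domain + flanks")

    @property
    def embedded(self) -> bool:
        return True


def make_embedded_query(
    domain: ProteinSequence,
    domain_id: str,
    clan_id: str = "",
    rng_seed: int = 0,
    background: np.ndarray | None = None,
) -> EmbeddedQuery:
    """Embed a domain into random sequence: flanks of ``floor(L/2)`` residues
    drawn i.i.d. from ``background`` (uniform by default) on each side."""
    rng = np.random.default_rng(rng_seed)
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    L = len(domain.residues)
    flank = L // 2
    letters = np.array(list(STANDARD_AA))
    left = "".join(rng.choice(letters, size=flank, p=background))
    right = "".join(rng.choice(letters, size=flank, p=background))
    seq = ProteinSequence(
        id=f"{domain.id}_embedded",
        residues=left + domain.residues + right,
        description=f"{domain_id} embedded in {flank}-residue random flanks",
    )
    return EmbeddedQuery(
        sequence=seq,
        domain_id=domain_id,
        clan_id=clan_id,
        domain_start=flank + 1,
        domain_end=flank + L,
        flank_len_left=flank,
        flank_len_right=flank,
    )


def _same_family(query: BenchQuery, dom: DomainAnnotation, clan_map: Mapping[str, str]) -> bool:
    if dom.domain_id == query.domain_id:
        return True
    q_clan = query.clan_id or clan_map.get(query.domain_id, "")
    s_clan = dom.clan_id or clan_map.get(dom.domain_id, "")
    return bool(q_clan) and q_clan == s_clan


def classify_hit(
    hit: TabularHitRecord,
    query: BenchQuery,
    subject_domains: Sequence[DomainAnnotation] = (),
    clan_map: Mapping[str, str] | None = None,
    min_overlap: int = 1,
) -> str:
    """Classify one reported hit as ``"TP"``, ``"FP"``, or ``"ignored"``.

    TP requires (i) the hit's query span to overlap the query's domain
    interval by at least ``min_overlap`` residues and (ii) the subject
    positions aligned to that overlap (via the BTOP walk) to overlap a
    subject domain of the same family or clan.  A hit entirely outside the
    query domain is an FP for embedded queries and ignored for full-length
    queries.  Subjects without annotations have none to match — FP.
    """
    clan_map = clan_map or {}
    lo = max(hit.q_start, query.domain_start)
    hi = min(hit.q_end, query.domain_end)
    if hi - lo + 1 < min_overlap:
        return "FP" if query.embedded else "ignored"
    s_positions = [
        s
        for q, s in _btop.walk_positions(hit.btop, hit.q_start, hit.s_start)
        if q is not None and s is not None and lo <= q <= hi
    ]
    if not s_positions:
        return "FP"
    s_lo, s_hi = min(s_positions), max(s_positions)
    for dom in subject_domains:
        if not _same_family(query, dom, clan_map):
            continue
        if min(s_hi, dom.end) - max(s_lo, dom.start) + 1 >= min_overlap:
            return "TP"
    return "FP"


@dataclass
class QueryEvaluation:
    """Per-query, per-iteration counts and rates."""

    query_id: str
    iteration: int
    tp: int
    fp: int
    ignored: int
    fn: int

    @property
    def sensitivity(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else 0.0

    @property
    def fdr(self) -> float:
        total = self.tp + self.fp
        return self.fp / total if total else 0.0


@dataclass
class EvaluationResult:
    """Weighted (equal per-query) sensitivity and FDR per iteration, with the
    per-query breakdown and a coverage-vs-FDR table."""

    per_query: list[QueryEvaluation]
    weighted_sensitivity: dict[int, float]
    weighted_fdr: dict[int, float]
    table: pd.DataFrame


def evaluate_iteration(
    hits: Sequence[TabularHitRecord],
    query: BenchQuery,
    query_id: str,
    iteration: int,
    annotations: Mapping[str, Sequence[DomainAnnotation]],
    clan_map: Mapping[str, str],
    family_size: int,
    report_evalue: float = REPORT_EVALUE,
    min_overlap: int = 1,
) -> QueryEvaluation:
    """Count TP/FP/ignored among one query's reported hits for one iteration.

    A subject counts once toward TP (family coverage); ``TP + FP + ignored``
    equals the number of scored hits.
    """
    tp = fp = ignored = 0
    tp_subjects: set[str] = set()
    for hit in hits:
        if not hit.evalue < report_evalue:
            continue
        label = classify_hit(
            hit, query, annotations.get(hit.subject_id, ()), clan_map, min_overlap
        )
        if label == "TP":
            tp += 1
            tp_subjects.add(hit.subject_id)
        elif label == "FP":
            fp += 1
        else:
            ignored += 1
    fn = family_size - len(tp_subjects)
    return QueryEvaluation(
        query_id=query_id, iteration=iteration, tp=tp, fp=fp, ignored=ignored, fn=fn
    )


def evaluate_run(
    hits_by_query: Mapping[str, Mapping[int, Sequence[TabularHitRecord]]],
    queries: Mapping[str, BenchQuery],
    annotations: Mapping[str, Sequence[DomainAnnotation]],
    clan_map: Mapping[str, str],
    family_sizes: Mapping[str, int],
    report_evalue: float = REPORT_EVALUE,
    min_overlap: int = 1,
) -> EvaluationResult:
    """Evaluate a whole benchmark run: per-query rates averaged with equal
    weight per query, per iteration."""
    per_query: list[QueryEvaluation] = []
    usable: list[str] = []
    for qid in queries:
        if family_sizes.get(qid, 0) <= 0:
            warnings.warn(f"query {qid!r} has family size 0; excluded")
            continue
        usable.append(qid)
        for iteration, hits in sorted(hits_by_query.get(qid, {}).items()):
            per_query.append(
                evaluate_iteration(
                    hits,
                    queries[qid],
                    qid,
                    iteration,
                    annotations,
                    clan_map,
                    family_sizes[qid],
                    report_evalue,
                    min_overlap,
                )
            )
    iterations = sorted({e.iteration for e in per_query})
    weighted_sens: dict[int, float] = {}
    weighted_fdr: dict[int, float] = {}
    rows = []
    for it in iterations:
        evals = {e.query_id: e for e in per_query if e.iteration == it}
        sens = [evals[q].sensitivity if q in evals else 0.0 for q in usable]
        fdrs = [evals[q].fdr if q in evals else 0.0 for q in usable]
        weighted_sens[it] = float(np.mean(sens)) if sens else 0.0
        weighted_fdr[it] = float(np.mean(fdrs)) if fdrs else 0.0
        rows.append(
            {
                "iteration": it,
                "weighted_sensitivity": weighted_sens[it],
                "weighted_fdr": weighted_fdr[it],
                "tp": sum(e.tp for e in evals.values()),
                "fp": sum(e.fp for e in evals.values()),
                "ignored": sum(e.ignored for e in evals.values()),
            }
        )
    return EvaluationResult(
        per_query=per_query,
        weighted_sensitivity=weighted_sens,
        weighted_fdr=weighted_fdr,
        table=pd.DataFrame(rows),
    )


def overextension(hit: TabularHitRecord, query: BenchQuery) -> int:
    """Aligned query positions outside the domain interval."""
    left = max(0, query.domain_start - hit.q_start)
    right = max(0, hit.q_end - query.domain_end)
    return left + right


def overextension_stats(
    hits: Sequence[TabularHitRecord],
    query: BenchQuery,
    report_evalue: float = REPORT_EVALUE,
) -> float | None:
    """Median per-hit over-extension among significant hits; ``None`` when no
    hit qualifies."""
    values = [overextension(h, query) for h in hits if h.evalue < report_evalue]
    if not values:
        return None
    return float(np.median(values))


def identity_q1(
    hits: Sequence[TabularHitRecord], report_evalue: float = REPORT_EVALUE
) -> float | None:
    """Bottom quartile (linear-interpolation quantile) of percent identity
    among significant hits; ``None`` when no hit qualifies."""
    values = [h.percent_identity for h in hits if h.evalue < report_evalue]
    if not values:
        return None
    return float(np.percentile(values, 25))
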