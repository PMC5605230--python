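"""The iterative search loop: search, anchor, seed, build PSSM, re-search.

Iteration 1 is a plain Smith-Waterman search of the query against the
database; each subsequent iteration takes the subjects included at the
previous one (E-value at or below the inclusion threshold), applies the
boundary policy, assembles the query-anchored MSA, fills gaps per the
seeding policy, builds a PSSM, and searches the database with it.  PSSM
iterations calibrate their E-values empirically on that search's own score
distribution.  The loop stops early at a fixed point: the included subjects
and their alignment spans unchanged between consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import alignkit, msaforge, pssmkit
from .alignkit import (
    DatabaseSummary,
    EVDParams,
    FitError,
    LocalAlignment,
    SubstitutionMatrix,
)
from .msaforge import BoundaryRegistry, GapFillPolicy, QueryAnchoredMSA
from .pssmkit import PSSM
from .seqio import STANDARD_AA, DomainAnnotation, ProteinSequence, TabularHitRecord, hit_sort_key


@dataclass(frozen=True)
class IterationConfig:
    """Knobs of the iterative search.

    ``inclusion_evalue`` (default 0.002) gates what enters the next model;
    ``report_evalue`` (default 0.001) gates what is scored downstream.
    """

    n_iterations: int = 10
    inclusion_evalue: float = 0.002
    report_evalue: float = 0.001
    gapfill: GapFillPolicy = field(default_factory=GapFillPolicy)
    boundary: str = "current"
    gap_open: int = 11
    gap_extend: int = 1
    pseudocount_weight: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.inclusion_evalue <= 0 or self.report_evalue <= 0:
            raise ValueError("E-value thresholds must be positive")
        if self.boundary not in msaforge.BOUNDARY_POLICIES:
            raise ValueError(f"unknown boundary policy {self.boundary!r}")


@dataclass
class IterationResult:
    """State of one iteration of the loop."""

    iteration: int
    hits: list[TabularHitRecord]
    included: tuple[str, ...]
    pssm: PSSM | None
    msa: QueryAnchoredMSA | None
    evd: EVDParams
    converged: bool


def _db_composition(database: Sequence[ProteinSequence]) -> np.ndarray:
    counts = np.zeros(20)
    index = {c: i for i, c in enumerate(STANDARD_AA)}
    for seq in database:
        for c in seq.residues:
            if c in index:
                counts[index[c]] += 1
    total = counts.sum()
    return counts / total if total else np.full(20, 1.0 / 20.0)


def _to_record(
    query_id: str, subject_id: str, aln: LocalAlignment
) -> TabularHitRecord:
    return TabularHitRecord(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=aln.percent_identity,
        alignment_length=aln.alignment_length,
        q_start=aln.q_start,
        q_end=aln.q_end,
        s_start=aln.s_start,
        s_end=aln.s_end,
        evalue=aln.evalue,
        bit_score=aln.bit_score,
        btop=aln.btop,
    )


def run_iterative_search(
    query: ProteinSequence,
    database: Sequence[ProteinSequence],
    config: IterationConfig | None = None,
    matrix: SubstitutionMatrix | None = None,
    domains: Sequence[DomainAnnotation] | None = None,
) -> list[IterationResult]:
    """Run the full iterative search; returns one result per executed iteration.

    ``domains`` are query-side annotations, needed only by the ``domain``
    boundary policy.  Identical inputs and seeds give bit-identical output.
    """
    if not database:
        raise ValueError("database must be non-empty")
    config = config or IterationConfig()
    matrix = matrix or SubstitutionMatrix.blosum62(config.gap_open, config.gap_extend)
    by_id = {s.id: s for s in database}
    db_residues = sum(len(s) for s in database)
    db_summary = DatabaseSummary(db_residues, len(database), len(query.residues))
    composition = _db_composition(database)
    base_params = alignkit.gapped_blosum62_params(db_residues, len(database))
    registry = BoundaryRegistry()
    report_cut = max(config.inclusion_evalue, config.report_evalue)

    results: list[IterationResult] = []
    prev_included: tuple[str, ...] | None = None
    prev_spans: dict[str, tuple[int, int, int, int]] = {}
    prev_alns: dict[str, LocalAlignment] = {}
    params = base_params

    for iteration in range(1, config.n_iterations + 1):
        pssm: PSSM | None = None
        msa: QueryAnchoredMSA | None = None
        if iteration == 1:
            alns = {
                s.id: a
                for s in database
                if (a := alignkit.smith_waterman(query, s, matrix)) is not None
            }
            params = base_params
        else:
            pairs = []
            for sid in prev_included:
                subject = by_id[sid]
                trimmed = msaforge.apply_boundary_policy(
                    subject,
                    prev_alns[sid],
                    config.boundary,
                    registry=registry,
                    domains=domains,
                    query=query,
                    matrix=matrix,
                )
                if trimmed is not None:
                    pairs.append((subject, trimmed))
            msa = msaforge.build_query_msa(query, pairs, iteration=iteration - 1)
            gapfill = replace(
                config.gapfill, rng_seed=config.gapfill.rng_seed + config.rng_seed
            )
            filled, _library = msaforge.fill_gaps(msa, gapfill, background=composition)
            pssm = pssmkit.build_pssm(filled, matrix, config.pseudocount_weight)
            alns = {
                s.id: a
                for s in database
                if (
                    a := alignkit.pssm_search(
                        pssm, s, config.gap_open, config.gap_extend
                    )
                )
                is not None
            }
            try:
                params = alignkit.fit_evd(
                    [a.raw_score for a in alns.values()], db_summary
                )
            except FitError:
                pass  # keep the previous iteration's calibration
            pssm.params = params

        for a in alns.values():
            a.evalue = float(alignkit.evalue(params, a.raw_score, len(query.residues)))
            a.bit_score = alignkit.bit_score(params, a.raw_score)

        included = tuple(
            sorted(
                sid for sid, a in alns.items() if a.evalue <= config.inclusion_evalue
            )
        )
        for sid in included:
            a = alns[sid]
            registry.record(sid, a.q_start, a.q_end, a.s_start, a.s_end)

        hits = sorted(
            (
                _to_record(query.id, sid, a)
                for sid, a in alns.items()
                if a.evalue <= report_cut
            ),
            key=hit_sort_key,
        )
        # fixed point: same included subjects aligned over the same spans —
        # an id-only test would declare convergence while alignments are
        # still creeping (i.e. while the model is still moving)
        spans = {
            sid: (alns[sid].q_start, alns[sid].q_end, alns[sid].s_start, alns[sid].s_end)
            for sid in included
        }
        converged = prev_included is not None and spans == prev_spans
        if iteration == 1 and not included:
            converged = True
        results.append(
            IterationResult(
                iteration=iteration,
                hits=hits,
                included=included,
                pssm=pssm,
                msa=msa,
                evd=params,
                converged=converged,
            )
        )
        if converged:
            break
        prev_included = included
        prev_spans = spans
        prev_alns = {sid: alns[sid] for sid in included}

    return results
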