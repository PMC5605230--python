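"""Synthetic protein families and multi-domain architectures with known truth.

Every test and benchmark in this package runs on generated data: ancestral
domain sequences drawn i.i.d. from a background composition, family members
derived by point substitutions (sampled in proportion to BLOSUM62
exchangeabilities) down to a target percent identity, plus occasional short
indels, assembled into multi-domain proteins with random linkers.  A truth
manifest records every domain instance and family membership.

The contamination preset mimics the classic failure mode of iterative
searches on multi-domain proteins: a query carrying a truncated family-A
domain searched against a database where many family-A proteins also carry
an adjacent family-B domain.  Over-extension of A alignments into B can
teach the model family B, at which point B-only proteins — known
non-homologs of the query — start scoring significantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignkit import SubstitutionMatrix
from .bench import EmbeddedQuery, make_embedded_query
from .pssmkit import matrix_target_frequencies
from .seqio import STANDARD_AA, DomainAnnotation, ProteinSequence

_LETTERS = np.array(list(STANDARD_AA))


@dataclass(frozen=True)
class Architecture:
    """A protein layout: ordered domain instances and fixed-length random
    linkers, replicated ``count`` times.

    A domain item may carry an ancestor slice — ``("domain", id, (start,
    end))``, 1-based inclusive — for families whose instances have variable
    boundaries (partial-length domain instances are common in real
    annotations and matter for over-extension behaviour).
    """

    name: str
    count: int
    #: ("linker", length) | ("domain", id[, (start, end)[, identity]]) —
    #: the optional slice and identity override the family defaults for
    #: this architecture's instances
    layout: tuple


@dataclass(frozen=True)
class FamilySpec:
    """Declarative description of a synthetic database."""

    domains: Mapping[str, int]  # domain_id -> ancestor length
    #: domain_id -> target % identity to the ancestor: a single value, or a
    #: (low, high) range sampled uniformly per instance (heterogeneous
    #: families drive gradual discovery across iterations)
    identity: Mapping[str, float | tuple[float, float]]
    architectures: Sequence[Architecture]
    clans: Mapping[str, str] = field(default_factory=dict)
    rng_seed: int = 0
    indel_rate: float = 0.01  # events per ancestor position
    indel_mean: float = 2.0  # mean indel length (geometric)
    background: Sequence[float] | None = None  # uniform when omitted

    def __post_init__(self):
        for dom, t in self.identity.items():
            lo, hi = (t, t) if np.isscalar(t) else (t[0], t[1])
            if not (0 < lo <= hi <= 100):
                raise ValueError(f"identity target for {dom} outside (0, 100]")
            if lo < 5:
                raise ValueError(f"identity target {lo}% for {dom} is infeasible")
        for arch in self.architectures:
            for item in arch.layout:
                if item[0] == "domain" and item[1] not in self.domains:
                    raise ValueError(
                        f"architecture {arch.name} references unknown domain {item[1]}"
                    )


def _background(spec_background) -> np.ndarray:
    if spec_background is None:
        return np.full(20, 1.0 / 20.0)
    bg = np.asarray(spec_background, dtype=float)
    return bg / bg.sum()


def _random_residues(rng: np.random.Generator, n: int, bg: np.ndarray) -> str:
    return "".join(rng.choice(_LETTERS, size=n, p=bg))


def _exchange_probs(matrix: SubstitutionMatrix) -> np.ndarray:
    """P(b | a, b != a): BLOSUM-derived substitution target distribution with
    the diagonal removed and rows renormalized."""
    _, cond = matrix_target_frequencies(matrix)
    probs = cond.T.copy()  # probs[a, b] = P(b | a)
    np.fill_diagonal(probs, 0.0)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def mutate_domain(
    ancestor: str,
    target_identity: float,
    rng: np.random.Generator,
    exchange: np.ndarray,
    bg: np.ndarray,
    indel_rate: float = 0.01,
    indel_mean: float = 2.0,
) -> str:
    """Derive a family member from an ancestor at a target percent identity.

    Identity is measured the way the aligner reports it — identities over
    alignment columns, gap columns included — so the substitution budget is
    chosen after the indel plan: with ``ins`` inserted and ``del`` deleted
    residues, columns ≈ L + ins, aligned pairs = L - del, and the number of
    substitutions is set so matches / columns hits the target.
    """
    L = len(ancestor)
    aa_index = {c: i for i, c in enumerate(STANDARD_AA)}

    n_events = rng.poisson(indel_rate * L) if indel_rate > 0 else 0
    deletions: set[int] = set()
    insertions: dict[int, str] = {}  # after-position -> inserted text
    ins_total = 0
    for _ in range(n_events):
        length = int(rng.geometric(1.0 / max(indel_mean, 1.0)))
        if rng.random() < 0.5:
            start = int(rng.integers(0, max(1, L - length)))
            deletions.update(range(start, min(L, start + length)))
        else:
            pos = int(rng.integers(0, L + 1))
            insertions[pos] = insertions.get(pos, "") + _random_residues(rng, length, bg)
            ins_total += length
    surviving = [i for i in range(L) if i not in deletions]
    columns = L + ins_total
    matches_wanted = int(round(target_identity / 100.0 * columns))
    n_sub = max(0, min(len(surviving), len(surviving) - matches_wanted))

    residues = list(ancestor)
    sub_positions = rng.choice(len(surviving), size=n_sub, replace=False) if n_sub else []
    for k in np.sort(np.asarray(sub_positions, dtype=int)):
        i = surviving[int(k)]
        a = aa_index.get(residues[i])
        if a is None:
            continue
        residues[i] = STANDARD_AA[int(rng.choice(20, p=exchange[a]))]

    out: list[str] = []
    if 0 in insertions:
        out.append(insertions[0])
    for i in range(L):
        if i not in deletions:
            out.append(residues[i])
        if i + 1 in insertions:
            out.append(insertions[i + 1])
    return "".join(out)


def generate_database(
    spec: FamilySpec,
    matrix: SubstitutionMatrix | None = None,
) -> tuple[list[ProteinSequence], list[DomainAnnotation], dict]:
    """Realize a :class:`FamilySpec` into sequences, annotations, and truth.

    The truth manifest records the ancestors, every protein's architecture
    and domain instances, and per-domain family membership lists.  All
    output is deterministic under ``spec.rng_seed``.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    rng = np.random.default_rng(spec.rng_seed)
    bg = _background(spec.background)
    exchange = _exchange_probs(matrix)

    ancestors = {
        dom: _random_residues(rng, length, bg) for dom, length in spec.domains.items()
    }
    sequences: list[ProteinSequence] = []
    annotations: list[DomainAnnotation] = []
    families: dict[str, list[str]] = {dom: [] for dom in spec.domains}
    proteins: list[dict] = []

    for arch in spec.architectures:
        for k in range(arch.count):
            seq_id = f"{arch.name}{k:03d}"
            parts: list[str] = []
            doms: list[dict] = []
            pos = 0
            for item in arch.layout:
                kind, value = item[0], item[1]
                if kind == "linker":
                    parts.append(_random_residues(rng, int(value), bg))
                    pos += int(value)
                else:
                    ancestor = ancestors[value]
                    if len(item) > 2 and item[2] is not None:
                        lo, hi = item[2]
                        ancestor = ancestor[lo - 1 : hi]
                    t = item[3] if len(item) > 3 else spec.identity[value]
                    if np.isscalar(t):
                        # jitter keeps realized identities within the
                        # declared +/-2% band while spreading member scores
                        target = float(t)
                        if target < 100.0:
                            target = min(100.0, target + float(rng.uniform(-1.5, 1.5)))
                    else:
                        target = float(rng.uniform(t[0], t[1]))
                    instance = mutate_domain(
                        ancestor,
                        target,
                        rng,
                        exchange,
                        bg,
                        spec.indel_rate,
                        spec.indel_mean,
                    )
                    start = pos + 1
                    end = pos + len(instance)
                    parts.append(instance)
                    pos = end
                    clan = spec.clans.get(value, "")
                    annotations.append(
                        DomainAnnotation(seq_id, value, clan, start, end)
                    )
                    doms.append(
                        {
                            "domain_id": value,
                            "clan_id": clan,
                            "start": start,
                            "end": end,
                            "identity_target": target,
                        }
                    )
                    if seq_id not in families[value]:
                        families[value].append(seq_id)
            sequences.append(ProteinSequence(seq_id, "".join(parts), arch.name))
            proteins.append({"id": seq_id, "architecture": arch.name, "domains": doms})

    truth = {
        "rng_seed": spec.rng_seed,
        "ancestors": ancestors,
        "proteins": proteins,
        "families": families,
    }
    return sequences, annotations, truth


# ---------------------------------------------------------------------------
# contamination benchmark (two-domain architecture, truncated embedded query)

#: study conditions for the contamination benchmark — fixed, not a dial.
#: Family A is coherent but heterogeneous (members 55-85% identical to the
#: ancestor); the query is a distant (40%) member carrying only the first
#: 150 of the 160 ancestor positions, so subject A domains continue a
#: little past the query's domain.  The two-domain proteins carry the
#: full-length A instance followed by the B module: a weakly conserved
#: 20-residue edge segment and the tightly conserved B domain proper —
#: the architecture through which over-extension teaches the model family
#: B.  B-only proteins (edge + B domain, no A) are the contamination
#: sentinels: the query shares no domain with them, so their inclusion
#: means the model has drifted.
CONTAMINATION = {
    "domain_a_len": 160,
    "edge_len": 20,
    "domain_b_len": 120,
    "identity_a": (55.0, 85.0),
    "identity_edge": (35.0, 55.0),
    "identity_b": (88.0, 96.0),
    "query_identity": 40.0,
    "query_truncation": 150,  # query (and A-only instances) cover A positions 1..150
    "n_a_only": 35,
    "n_a_plus_b": 25,
    "n_b_only": 30,
    "n_decoys": 200,
    "decoy_len": 260,
}


def contamination_spec(seed: int = 0) -> FamilySpec:
    c = CONTAMINATION
    return FamilySpec(
        domains={
            "DOMA": c["domain_a_len"],
            "DOMBE": c["edge_len"],
            "DOMB": c["domain_b_len"],
        },
        identity={
            "DOMA": c["identity_a"],
            "DOMBE": c["identity_edge"],
            "DOMB": c["identity_b"],
        },
        architectures=(
            Architecture(
                "famA_",
                c["n_a_only"],
                (
                    ("linker", 20),
                    ("domain", "DOMA", (1, c["query_truncation"])),
                    ("linker", 20),
                ),
            ),
            Architecture(
                "famAB_",
                c["n_a_plus_b"],
                (
                    ("linker", 10),
                    ("domain", "DOMA"),
                    ("domain", "DOMBE"),
                    ("domain", "DOMB"),
                    ("linker", 10),
                ),
            ),
            Architecture(
                "famB_",
                c["n_b_only"],
                (
                    ("linker", 20),
                    ("domain", "DOMBE"),
                    ("domain", "DOMB"),
                    ("linker", 20),
                ),
            ),
            Architecture("decoy_", c["n_decoys"], (("linker", c["decoy_len"]),)),
        ),
        rng_seed=seed,
    )


@dataclass
class ContaminationBenchmark:
    """A multi-domain contamination scenario at toy scale."""

    query: EmbeddedQuery
    database: list[ProteinSequence]
    annotations: list[DomainAnnotation]
    truth: dict

    @property
    def true_positive_ids(self) -> set[str]:
        return set(self.truth["families"]["DOMA"])

    @property
    def decoy_domain_ids(self) -> set[str]:
        """B-only proteins: inclusion of any of these signals model
        contamination."""
        only_b = set(self.truth["families"]["DOMB"]) - set(
            self.truth["families"]["DOMA"]
        )
        return only_b


def contamination_benchmark(
    seed: int = 0, matrix: SubstitutionMatrix | None = None
) -> ContaminationBenchmark:
    """Generate the contamination database plus its truncated embedded query.

    The query carries a fresh family-A instance truncated at the C-terminus,
    so subject A domains continue past the query's domain into what is, for
    the query, random flank — the launching ramp for over-extension into the
    adjacent B domain of the two-domain proteins.
    """
    c = CONTAMINATION
    spec = contamination_spec(seed)
    matrix = matrix or SubstitutionMatrix.blosum62()
    sequences, annotations, truth = generate_database(spec, matrix)

    rng = np.random.default_rng(spec.rng_seed + 10_000)
    bg = _background(spec.background)
    exchange = _exchange_probs(matrix)
    ancestor = truth["ancestors"]["DOMA"][: c["query_truncation"]]
    truncated = mutate_domain(
        ancestor, c["query_identity"], rng, exchange, bg, indel_rate=0.0
    )
    domain_seq = ProteinSequence("queryA", truncated, "truncated family-A domain")
    query = make_embedded_query(
        domain_seq,
        domain_id="DOMA",
        clan_id="",
        rng_seed=seed + 20_000,
    )
    truth = dict(truth)
    truth["query"] = {
        "id": query.sequence.id,
        "domain_id": query.domain_id,
        "clan_id": query.clan_id,
        "domain_start": query.domain_start,
        "domain_end": query.domain_end,
        "true_positives": sorted(truth["families"]["DOMA"]),
    }
    return ContaminationBenchmark(
        query=query, database=sequences, annotations=annotations, truth=truth
    )
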