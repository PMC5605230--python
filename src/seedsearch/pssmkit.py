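"""Position-specific scoring matrix construction from a query-anchored MSA.

The construction follows the standard profile recipe: Henikoff
position-based sequence weights, weighted observed residue frequencies per
column, a data-dependent pseudocount blend with substitution-matrix derived
conditional frequencies, and half-bit log-odds scores

    Q_i(a) = (alpha_i * f_i(a) + beta * g_i(a)) / (alpha_i + beta)
    S_i(a) = round(2 * log2(Q_i(a) / p(a)))

where ``f`` are the weighted observed frequencies, ``g_i(a) = sum_b
P(a | b) f_i(b)`` are the matrix-derived pseudocount frequencies,
``alpha_i = n_eff(i) - 1`` counts the column's effective observations
(number of distinct residue types, Henikoff-style), and ``beta`` is the
pseudocount weight.

The conditional probabilities ``P(a | b)`` and the background ``p`` are
obtained by numerically inverting the half-bit substitution matrix
(``q_ab ∝ p_a p_b 2^{S_ab/2}``, iterated to self-consistency), so the whole
construction is determined by the scoring matrix itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignkit import EVDParams, SubstitutionMatrix
from .seqio import STANDARD_AA, ProteinSequence

_AA_INDEX = {c: i for i, c in enumerate(STANDARD_AA)}
_GAP = "-"


@dataclass
class PSSM:
    """Position x 20 score matrix with the frequencies behind it.

    scores are half-bit-scaled integers; ``raw_scores`` keeps the unrounded
    values, ``freqs`` the estimated target frequencies Q (rows sum to 1),
    ``n_eff`` the per-position effective observation count, ``background``
    the background distribution p, and ``params`` the E-value calibration
    (filled in after the search).
    """

    query: ProteinSequence
    scores: np.ndarray
    raw_scores: np.ndarray
    freqs: np.ndarray
    n_eff: np.ndarray
    background: np.ndarray
    params: EVDParams | None = None

    @property
    def positions(self) -> int:
        return self.scores.shape[0]


def matrix_target_frequencies(
    matrix: SubstitutionMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert a score matrix into ``(background p, conditional C)``.

    A valid log-odds matrix satisfies ``q_ab = p_a p_b exp(lambda S_ab)``
    for its implicit target frequencies.  Both unknowns follow from the
    scores alone: the ungapped lambda is the root of
    ``sum(exp(lambda S)^-1 @ 1) = 1`` and the solution vector of that linear
    system is the background, after which ``C[a, b] = q_ab / p_b = P(a | b)``.
    Computed over the 20 standard residues.
    """
    from scipy.optimize import brentq

    idx = [matrix.alphabet.index(c) for c in STANDARD_AA]
    S = matrix.matrix[np.ix_(idx, idx)].astype(float)

    def solve_p(lam: float) -> np.ndarray:
        return np.linalg.solve(np.exp(lam * S), np.ones(20))

    lam = brentq(lambda l: solve_p(l).sum() - 1.0, 0.01, 1.0, xtol=1e-12)
    p = solve_p(lam)
    if (p <= 0).any():
        raise ValueError("matrix does not define a positive background")
    q = np.outer(p, p) * np.exp(lam * S)
    q /= q.sum()
    cond = q / q.sum(axis=0, keepdims=True)  # cond[a, b] = P(a | b)
    return p, cond


def _msa_texts(msa) -> list[str]:
    """All MSA rows, query first."""
    return [msa.query.residues] + [row.text for row in msa.rows]


def position_weights(msa) -> np.ndarray:
    """Henikoff position-based sequence weights over all rows (query first).

    Per column with r distinct symbols, a row showing a symbol seen s times
    contributes 1/(r*s); row weights are the sums, normalized to 1.  Gap
    characters are treated as a symbol type of their own.
    """
    texts = _msa_texts(msa)
    if not texts:
        raise ValueError("empty MSA")
    n = len(texts)
    weights = np.zeros(n)
    for col in zip(*texts):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for k, c in enumerate(col):
            weights[k] += 1.0 / (r * counts[c])
    total = weights.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return weights / total


def build_pssm(
    filled_msa,
    matrix: SubstitutionMatrix,
    pseudocount_weight: float = 10.0,
) -> PSSM:
    """Construct a PSSM from a (possibly gap-filled) query-anchored MSA.

    A column with zero residue observations (possible only when gaps were
    left in place) falls back to the substitution-matrix row of the query
    residue at that position.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    query = filled_msa.query
    texts = _msa_texts(filled_msa)
    weights = position_weights(filled_msa)
    p, cond = matrix_target_frequencies(matrix)
    L = len(query.residues)
    scores = np.zeros((L, 20), dtype=np.int32)
    raw = np.zeros((L, 20), dtype=float)
    freqs = np.zeros((L, 20), dtype=float)
    n_eff = np.zeros(L, dtype=float)

    qi_idx = [matrix.alphabet.index(c) for c in STANDARD_AA]
    sub20 = matrix.matrix[np.ix_(qi_idx, qi_idx)].astype(float)

    for i in range(L):
        f = np.zeros(20)
        types: set[str] = set()
        for text, w in zip(texts, weights):
            c = text[i]
            if c == _GAP or c == "X":
                continue
            f[_AA_INDEX[c]] += w
            types.add(c)
        total = f.sum()
        if total == 0 or not types:
            # degenerate column: background log-odds of the query residue's row
            qa = _AA_INDEX[query.residues[i]]
            raw[i] = sub20[qa]
            scores[i] = np.rint(sub20[qa]).astype(np.int32)
            freqs[i] = cond[:, qa]
            n_eff[i] = 0.0
            continue
        f /= total
        n_eff[i] = len(types)
        alpha = max(n_eff[i] - 1.0, 0.0)
        g = cond @ f
        Q = (alpha * f + pseudocount_weight * g) / (alpha + pseudocount_weight)
        Q /= Q.sum()
        freqs[i] = Q
        raw[i] = 2.0 * np.log2(Q / p)
        scores[i] = np.rint(raw[i]).astype(np.int32)

    return PSSM(
        query=query,
        scores=scores,
        raw_scores=raw,
        freqs=freqs,
        n_eff=n_eff,
        background=p,
    )


def relative_entropy(pssm: PSSM) -> tuple[np.ndarray, float]:
    """Per-position Kullback-Leibler divergence of Q from the background, in
    bits, and its mean over positions."""
    Q = pssm.freqs
    p = pssm.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Q > 0, Q * np.log2(Q / p), 0.0)
    per_pos = terms.sum(axis=1)
    return per_pos, float(per_pos.mean())
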