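"""Independent brute-force oracles, deliberately naive.

These stay free of the package's DP kernels: plain-Python three-matrix
affine-gap recurrences and a token-level BTOP walker, used to cross-check
the optimized implementations on small instances.
"""

NEG = float("-inf")


def affine_local_score(profile, subject_idx, gap_open, gap_extend):
    """Best local alignment score: naive three-matrix recurrence.

    profile[i][a] is the score of profile position i against residue index
    a; a gap of length L costs gap_open + L * gap_extend.
    """
    m, n = len(profile), len(subject_idx)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + profile[i - 1][subject_idx[j - 1]],
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


def pair_local_score(query, subject, matrix):
    """Sequence-sequence wrapper over :func:`affine_local_score`."""
    idx = {c: i for i, c in enumerate(matrix.alphabet)}
    profile = [[int(matrix.matrix[idx[q], a]) for a in range(len(matrix.alphabet))] for q in query]
    return affine_local_score(
        profile, [idx[c] for c in subject], matrix.gap_open, matrix.gap_extend
    )


def btop_walk(btop, q_start, s_start):
    """Token-level BTOP walk yielding (q_pos, s_pos) pairs, None on gaps."""
    out = []
    q, s = q_start, s_start
    i = 0
    while i < len(btop):
        if btop[i].isdigit():
            j = i
            while j < len(btop) and btop[j].isdigit():
                j += 1
            for _ in range(int(btop[i:j])):
                out.append((q, s))
                q += 1
                s += 1
            i = j
        else:
            qc, sc = btop[i], btop[i + 1]
            if qc == "-":
                out.append((None, s))
                s += 1
            elif sc == "-":
                out.append((q, None))
                q += 1
            else:
                out.append((q, s))
                q += 1
                s += 1
            i += 2
    return out
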