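"""Independent brute-force oracles used by the tests.

These deliberately share no code with the dynamic-programming
implementations they check: alignment scores come from explicit enumeration
of every monotone alignment path, and profile-HMM scores from explicit
enumeration of every state path in plain probability space.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Alignment: enumerate all monotone paths with affine gap bookkeeping
# ---------------------------------------------------------------------------


def global_score_bruteforce(a: str, b: str, matrix) -> float:
    """Max score over every global alignment path (gap cost open + g*ext)."""
    go, ge = matrix.gap_open, matrix.gap_extend
    best = [-np.inf]

    def walk(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + matrix.score(a[i], b[j]), "M")
        if i < len(a):  # consume a, gap in b
            cost = ge if last == "A" else go + ge
            walk(i + 1, j, score - cost, "A")
        if j < len(b):  # consume b, gap in a
            cost = ge if last == "B" else go + ge
            walk(i, j + 1, score - cost, "B")

    walk(0, 0, 0.0, "M")
    return best[0]


def local_score_bruteforce(a: str, b: str, matrix) -> float:
    """Max over 0 and all substring pairs aligned globally."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, global_score_bruteforce(a[i1:i2], b[j1:j2], matrix))
    return best


# ---------------------------------------------------------------------------
# Profile HMM: enumerate all state paths (probability space)
# ---------------------------------------------------------------------------


def _paths(hmm, codes, combine_init, combine):
    """Shared traversal; combine accumulates path probabilities (sum or max)."""
    L, eta, bg, n = hmm.L, hmm.eta, hmm.background, len(codes)
    acc = [combine_init]

    def finish(i, p):
        for j in range(i, n):
            p *= eta * bg[codes[j]]
        acc[0] = combine(acc[0], p * (1 - eta))

    def core_from(state, k, i, p):
        if p == 0.0:
            return
        if state == "M":
            if k == L - 1:
                finish(i, p * hmm.t_me[k])
                return
            core_emit("M", k + 1, i, p * hmm.t_mm[k])
            core_emit("I", k, i, p * hmm.t_mi[k])
            core_from("D", k + 1, i, p * hmm.t_md[k])
            finish(i, p * hmm.t_me[k])
        elif state == "I":
            core_emit("M", k + 1, i, p * hmm.t_im[k])
            core_emit("I", k, i, p * hmm.t_ii[k])
        else:  # D
            if k == L - 1:
                finish(i, p)  # D_L -> E with probability 1
                return
            core_emit("M", k + 1, i, p * hmm.t_dm[k])
            core_from("D", k + 1, i, p * hmm.t_dd[k])

    def core_emit(state, k, i, p):
        if i >= n or p == 0.0:
            return
        c = codes[i]
        em = hmm.match_em[k][c] if state == "M" else hmm.insert_em[k][c]
        core_from(state, k, i + 1, p * em)

    for f in range(n + 1):  # flank prefix length
        p = 1.0
        for j in range(f):
            p *= eta * bg[codes[j]]
        p *= 1 - eta  # -> B
        for k in range(L):
            core_emit("M", k, f, p / L)
    return acc[0]


def null_prob(hmm, codes) -> float:
    return float((1 - hmm.eta) * np.prod([hmm.eta * hmm.background[c] for c in codes]))


def forward_bits_bruteforce(hmm, codes) -> float:
    total = _paths(hmm, codes, 0.0, lambda a, b: a + b)
    return float(np.log2(total / null_prob(hmm, codes)))


def viterbi_bits_bruteforce(hmm, codes) -> float:
    best = _paths(hmm, codes, 0.0, max)
    return float(np.log2(best / null_prob(hmm, codes)))
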