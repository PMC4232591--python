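"""Profile hidden Markov models for remote protein homology search.

A profile is built from a multiple alignment: columns whose gap fraction is
below 0.5 become match states; emissions are pseudocount-smoothed column
counts.  Search mode is local (Smith–Waterman-style): uniform entry from a
begin state into any match state, a fixed exit probability from every match
state, and geometric background-emitting flanks on both sides.  Scores are
log2-odds (bits) of the sequence under the profile versus an i.i.d.
background null with the same geometric length law, computed with the Forward
algorithm in log space; Viterbi provides the best state path for
domain-region reporting.

E-values come from a Gumbel (mu, lambda) fit to Forward scores of i.i.d.
background decoys, multiplied by the number of targets searched.

The generative model (emit-on-entry convention, all rows normalized):

    S -> N (eta) | B (1-eta);      N -> N (eta) | B (1-eta)
    B -> M_k (1/L each)
    M_k -> M_{k+1} | I_k | D_{k+1} | E        (counts-based, exit mixed in)
    I_k -> M_{k+1} | I_k;   D_k -> M_{k+1} | D_{k+1};   D_L -> E
    E -> C (eta) | T (1-eta);      C -> C (eta) | T (1-eta)

N, C and inserts emit background residues.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .align import AA_ALPHABET, MSA

N_AA = len(AA_ALPHABET)
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
_LN2 = float(np.log(2.0))
_NEG = -1e30


def encode_protein(seq: str, what: str = "sequence") -> np.ndarray:
    if not seq:
        raise ValueError(f"empty {what}")
    out = np.empty(len(seq), dtype=np.int64)
    for pos, c in enumerate(seq):
        i = _AA_INDEX.get(c)
        if i is None:
            raise ValueError(
                f"residue {c!r} at position {pos} of {what} is not a canonical amino acid"
            )
        out[pos] = i
    return out


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class ProfileHMM:
    name: str
    match_em: np.ndarray  # (L, 20)
    insert_em: np.ndarray  # (L, 20); insert state I_k follows match k (last row unused)
    t_mm: np.ndarray  # (L,) M_k -> M_{k+1}
    t_mi: np.ndarray  # (L,) M_k -> I_k
    t_md: np.ndarray  # (L,) M_k -> D_{k+1}
    t_me: np.ndarray  # (L,) M_k -> E
    t_im: np.ndarray  # (L,) I_k -> M_{k+1}
    t_ii: np.ndarray  # (L,) I_k -> I_k
    t_dm: np.ndarray  # (L,) D_k -> M_{k+1}
    t_dd: np.ndarray  # (L,) D_k -> D_{k+1}; D_L -> E has probability 1
    background: np.ndarray  # (20,)
    eta: float = 0.95  # flank/null geometric self-loop probability
    mu: float | None = None  # Gumbel location of decoy Forward scores
    lambda_: float | None = None  # Gumbel inverse scale
    calib_scores: np.ndarray | None = None  # sorted decoy Forward scores
    calib_length: int = 200  # decoy length the calibration was run at
    provenance: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.match_em.shape[0]

    @property
    def calibrated(self) -> bool:
        return (
            self.mu is not None
            and self.lambda_ is not None
            and self.calib_scores is not None
        )

    def validate(self, tol: float = 1e-9) -> None:
        L = self.L
        if L < 1:
            raise ValueError("model must have at least one match state")
        if not np.allclose(self.match_em.sum(axis=1), 1.0, atol=tol):
            raise ValueError("match emission rows must sum to 1")
        if not np.allclose(self.insert_em.sum(axis=1), 1.0, atol=tol):
            raise ValueError("insert emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=tol):
            raise ValueError("background must sum to 1")
        out_m = self.t_mm + self.t_mi + self.t_md + self.t_me
        if not np.allclose(out_m, 1.0, atol=tol):
            raise ValueError("match-state outgoing transitions must sum to 1")
        if L > 1:
            if not np.allclose((self.t_im + self.t_ii)[:-1], 1.0, atol=tol):
                raise ValueError("insert-state outgoing transitions must sum to 1")
            if not np.allclose((self.t_dm + self.t_dd)[1:-1], 1.0, atol=tol):
                raise ValueError("delete-state outgoing transitions must sum to 1")
        if not (0 < self.eta < 1):
            raise ValueError("eta must lie in (0, 1)")


@dataclass
class HmmHit:
    model: str
    target: str
    score: float  # Forward log2-odds (bits)
    evalue: float
    included: bool
    species: str = ""


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------


def build_profile(
    msa: MSA,
    match_gap_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    eta: float = 0.95,
    exit_prob: float = 0.1,
    background: np.ndarray | None = None,
    name: str | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Columns with gap fraction < ``match_gap_threshold`` become match states.
    Emissions and core transitions are relative frequencies smoothed by a
    fixed-weight Laplace mixture with the background (total added weight
    ``pseudocount_weight`` per distribution).  Residues in insert columns
    before the first or after the last match column belong to the flanks and
    are not counted.  Deterministic: no randomness is involved.
    """
    if len(msa) == 0:
        raise ValueError("cannot build a profile from an empty MSA")
    bg = (
        np.full(N_AA, 1.0 / N_AA)
        if background is None
        else np.asarray(background, dtype=float)
    )
    rows = [s for _, s in msa.records]
    ncols = msa.ncols
    nrows = len(rows)
    gapfrac = np.array(
        [sum(1 for r in rows if r[c] == "-") / nrows for c in range(ncols)]
    )
    match_cols = [c for c in range(ncols) if gapfrac[c] < match_gap_threshold]
    L = len(match_cols)
    if L == 0:
        raise ValueError(
            "no column qualifies as a match state "
            f"(gap fraction threshold {match_gap_threshold})"
        )
    col_state = {}  # column -> match index, or -1 for insert columns
    mi = 0
    for c in range(ncols):
        if mi < L and c == match_cols[mi]:
            col_state[c] = mi
            mi += 1
        else:
            col_state[c] = -1

    em_counts = np.zeros((L, N_AA))
    ins_counts = np.zeros((L, N_AA))
    # transition counts: mm, mi, md, im, ii, dm, dd
    c_mm = np.zeros(L)
    c_mi = np.zeros(L)
    c_md = np.zeros(L)
    c_im = np.zeros(L)
    c_ii = np.zeros(L)
    c_dm = np.zeros(L)
    c_dd = np.zeros(L)

    first_mc, last_mc = match_cols[0], match_cols[-1]
    for r in rows:
        prev = None  # ('M'|'D'|'I', match index)
        for c in range(first_mc, last_mc + 1):
            ch = r[c]
            k = col_state[c]
            if k >= 0:
                if ch != "-":
                    em_counts[k, _AA_INDEX[ch]] += 1.0
                    state = ("M", k)
                else:
                    state = ("D", k)
            else:
                if ch == "-":
                    continue
                # insert residue assigned to the preceding match index
                kins = max(0, col_state_before(col_state, c))
                ins_counts[kins, _AA_INDEX[ch]] += 1.0
                state = ("I", kins)
            if prev is not None:
                ps, pk = prev
                ss, sk = state
                if ps == "M" and ss == "M":
                    c_mm[pk] += 1.0
                elif ps == "M" and ss == "I":
                    c_mi[pk] += 1.0
                elif ps == "M" and ss == "D":
                    c_md[pk] += 1.0
                elif ps == "I" and ss == "M":
                    c_im[pk] += 1.0
                elif ps == "I" and ss == "I":
                    c_ii[pk] += 1.0
                elif ps == "D" and ss == "M":
                    c_dm[pk] += 1.0
                elif ps == "D" and ss == "D":
                    c_dd[pk] += 1.0
                # D->I and I->D are not modeled; such adjacencies are rare and skipped
            if not (prev is not None and prev[0] == "I" and state[0] == "D") and not (
                prev is not None and prev[0] == "D" and state[0] == "I"
            ):
                prev = state

    pw = float(pseudocount_weight)
    match_em = (em_counts + pw * bg) / (em_counts.sum(axis=1, keepdims=True) + pw)
    ins_tot = ins_counts.sum(axis=1, keepdims=True)
    insert_em = (ins_counts + pw * bg) / (ins_tot + pw)

    def norm2(a, b):
        tot = a + b + pw
        return (a + pw / 2) / tot, (b + pw / 2) / tot

    def norm3(a, b, c):
        tot = a + b + c + pw
        return (a + pw / 3) / tot, (b + pw / 3) / tot, (c + pw / 3) / tot

    t_mm = np.zeros(L)
    t_mi = np.zeros(L)
    t_md = np.zeros(L)
    t_me = np.zeros(L)
    t_im = np.zeros(L)
    t_ii = np.zeros(L)
    t_dm = np.zeros(L)
    t_dd = np.zeros(L)
    for k in range(L):
        if k == L - 1:
            t_me[k] = 1.0
            t_im[k] = 1.0  # unused
            t_dm[k] = 1.0  # D_L -> E carries all mass (kept in dm slot, unused)
            continue
        mm, mi_, md = norm3(c_mm[k], c_mi[k], c_md[k])
        t_mm[k], t_mi[k], t_md[k] = (
            mm * (1 - exit_prob),
            mi_ * (1 - exit_prob),
            md * (1 - exit_prob),
        )
        t_me[k] = exit_prob
        t_im[k], t_ii[k] = norm2(c_im[k], c_ii[k])
        t_dm[k], t_dd[k] = norm2(c_dm[k], c_dd[k])

    hmm = ProfileHMM(
        name=name or "profile",
        match_em=match_em,
        insert_em=insert_em,
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_me=t_me,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        background=bg,
        eta=eta,
        provenance={
            "source": name or "",
            "rows": nrows,
            "columns": ncols,
            "match_gap_threshold": match_gap_threshold,
            "pseudocount_weight": pseudocount_weight,
            "exit_prob": exit_prob,
        },
    )
    hmm.validate()
    return hmm


def col_state_before(col_state: dict, c: int) -> int:
    """Match index of the nearest match column left of c (-1 if none)."""
    for cc in range(c - 1, -1, -1):
        if col_state.get(cc, -1) >= 0:
            return col_state[cc]
    return -1


# ---------------------------------------------------------------------------
# Log-space parameter packing and DP kernels
# ---------------------------------------------------------------------------


def _log(x):
    with np.errstate(divide="ignore"):
        return np.where(np.asarray(x) > 0, np.log(np.maximum(x, 1e-300)), _NEG)


def _pack(hmm: ProfileHMM):
    return (
        _log(hmm.match_em),
        _log(hmm.insert_em),
        np.log(hmm.background),
        _log(hmm.t_mm),
        _log(hmm.t_mi),
        _log(hmm.t_md),
        _log(hmm.t_me),
        _log(hmm.t_im),
        _log(hmm.t_ii),
        _log(hmm.t_dm),
        _log(hmm.t_dd),
        float(np.log(hmm.eta)),
        float(np.log(1.0 - hmm.eta)),
    )


@njit(cache=True, inline="always", fastmath=True)
def _lse(a, b):
    if a < b:
        a, b = b, a
    if b <= _NEG:
        return a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True, fastmath=True)
def _forward_ln(
    x, lem, lins, lbg, lmm, lmi, lmd, lme, lim, lii, ldm, ldd, leta, lneta
):
    """ln P(x | model).  See module docstring for the state machine."""
    n = len(x)
    L = lem.shape[0]
    lentry = -np.log(L)
    M = np.full(L, _NEG)
    I = np.full(L, _NEG)
    D = np.full(L, _NEG)
    Mp = np.full(L, _NEG)
    Ip = np.full(L, _NEG)
    Dp = np.full(L, _NEG)
    lnN = _NEG  # in N after i emissions (i tracked by loop)
    B = lneta  # in B after 0 emissions: S->B
    E = _NEG
    C = _NEG
    for i in range(n):
        c = x[i]
        bgc = lbg[c]
        # flank N / begin B after emitting residue i
        lnN = bgc + leta + (lnN if i > 0 else 0.0)
        Bi = lnN + lneta
        # core (fused 4-term log-sum-exp per match state)
        entry = B + lentry
        Ei = _NEG
        for k in range(L):
            a = entry
            if k > 0:
                b = Mp[k - 1] + lmm[k - 1]
                cc = Ip[k - 1] + lim[k - 1]
                d = Dp[k - 1] + ldm[k - 1]
                hi = max(max(a, b), max(cc, d))
                m = hi + np.log(
                    np.exp(a - hi) + np.exp(b - hi) + np.exp(cc - hi) + np.exp(d - hi)
                )
            else:
                m = a
            mk = m + lem[k, c]
            M[k] = mk
            I[k] = lins[k, c] + _lse(Mp[k] + lmi[k], Ip[k] + lii[k])
            if k > 0:
                D[k] = _lse(M[k - 1] + lmd[k - 1], D[k - 1] + ldd[k - 1])
            else:
                D[k] = _NEG
            Ei = _lse(Ei, mk + lme[k])
        Ei = _lse(Ei, D[L - 1])  # D_L -> E, probability 1
        # tail flank C emits residue i via E->C or C->C
        C = bgc + leta + _lse(E, C)
        E = Ei
        B = Bi
        Mp, M = M, Mp
        Ip, I = I, Ip
        Dp, D = D, Dp
    return _lse(E, C) + lneta  # -> T


@njit(cache=True, fastmath=True)
def _forward_ln_concat(codes, starts, ends, lem, lins, lbg, lmm, lmi, lmd, lme, lim, lii, ldm, ldd, leta, lneta):
    nt = len(starts)
    out = np.empty(nt)
    for t in range(nt):
        out[t] = _forward_ln(
            codes[starts[t] : ends[t]],
            lem, lins, lbg, lmm, lmi, lmd, lme, lim, lii, ldm, ldd, leta, lneta,
        )
    return out


@njit(cache=True, fastmath=True)
def _viterbi_ln(
    x, lem, lins, lbg, lmm, lmi, lmd, lme, lim, lii, ldm, ldd, leta, lneta
):
    """Max-path ln-probability plus backpointers.

    Tie-break among predecessors prefers M over D over I (strict-> ordering).
    Returns (lnP, bpM, bpI, bpD, exit_k, exit_from_delete, exit_i).
    bpM codes: 0 = from B, 1 = from M, 2 = from I, 3 = from D.
    bpI codes: 0 = from M, 1 = from I.  bpD codes: 0 = from M, 1 = from D.
    """
    n = len(x)
    L = lem.shape[0]
    lentry = -np.log(L)
    M = np.full((n + 1, L), _NEG)
    I = np.full((n + 1, L), _NEG)
    D = np.full((n + 1, L), _NEG)
    bpM = np.zeros((n + 1, L), dtype=np.int8)
    bpI = np.zeros((n + 1, L), dtype=np.int8)
    bpD = np.zeros((n + 1, L), dtype=np.int8)
    lnN = _NEG
    Bprev = lneta  # B after 0 emissions
    Bvals = np.full(n + 1, _NEG)
    Bvals[0] = Bprev
    for i in range(1, n + 1):
        c = x[i - 1]
        bgc = lbg[c]
        lnN = bgc + leta + (lnN if i > 1 else 0.0)
        Bvals[i] = lnN + lneta
        for k in range(L):
            # into M: prefer B, then M > D > I on ties
            best = Bvals[i - 1] + lentry
            code = 0
            if k > 0:
                v = M[i - 1, k - 1] + lmm[k - 1]
                if v > best:
                    best = v
                    code = 1
                v = D[i - 1, k - 1] + ldm[k - 1]
                if v > best:
                    best = v
                    code = 3
                v = I[i - 1, k - 1] + lim[k - 1]
                if v > best:
                    best = v
                    code = 2
            M[i, k] = best + lem[k, c]
            bpM[i, k] = code
            vm = M[i - 1, k] + lmi[k]
            vi = I[i - 1, k] + lii[k]
            if vm >= vi:
                I[i, k] = lins[k, c] + vm
                bpI[i, k] = 0
            else:
                I[i, k] = lins[k, c] + vi
                bpI[i, k] = 1
            if k > 0:
                vm = M[i, k - 1] + lmd[k - 1]
                vd = D[i, k - 1] + ldd[k - 1]
                if vm >= vd:
                    D[i, k] = vm
                    bpD[i, k] = 0
                else:
                    D[i, k] = vd
                    bpD[i, k] = 1
    # best exit: E at position i, then tail flank of n - i residues
    best_total = _NEG
    exit_i = 0
    exit_k = 0
    exit_del = 0
    # tail[g] = ln prob of g tail-flank emissions then termination
    for i in range(1, n + 1):
        g = n - i
        tail = lneta
        for j in range(i, n):
            tail += leta + lbg[x[j]]
        Ei = _NEG
        ki = 0
        kdel = 0
        for k in range(L):
            v = M[i, k] + lme[k]
            if v > Ei:
                Ei = v
                ki = k
                kdel = 0
        v = D[i, L - 1]
        if v > Ei:
            Ei = v
            ki = L - 1
            kdel = 1
        total = Ei + tail
        if total > best_total:
            best_total = total
            exit_i = i
            exit_k = ki
            exit_del = kdel
    return best_total, bpM, bpI, bpD, M, I, D, exit_i, exit_k, exit_del


def _null_ln(hmm: ProfileHMM, codes: np.ndarray) -> float:
    lbg = np.log(hmm.background)
    return float(
        len(codes) * np.log(hmm.eta)
        + lbg[codes].sum()
        + np.log(1.0 - hmm.eta)
    )


# ---------------------------------------------------------------------------
# Scoring API
# ---------------------------------------------------------------------------


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """Forward log2-odds score in bits: log2 P(seq|hmm) - log2 P(seq|null)."""
    codes = encode_protein(seq)
    params = _pack(hmm)
    ln_model = _forward_ln(codes, *params)
    return (ln_model - _null_ln(hmm, codes)) / _LN2


def forward_scores(hmm: ProfileHMM, seqs) -> np.ndarray:
    """Forward bit scores for many sequences (batched kernel)."""
    encoded = [encode_protein(s, what=f"sequence {k}") for k, s in enumerate(seqs)]
    if not encoded:
        return np.zeros(0)
    starts = np.zeros(len(encoded), dtype=np.int64)
    ends = np.zeros(len(encoded), dtype=np.int64)
    pos = 0
    for k, e in enumerate(encoded):
        starts[k] = pos
        pos += len(e)
        ends[k] = pos
    concat = np.concatenate(encoded)
    params = _pack(hmm)
    ln_model = _forward_ln_concat(concat, starts, ends, *params)
    nulls = np.array([_null_ln(hmm, e) for e in encoded])
    return (ln_model - nulls) / _LN2


def viterbi_trace(hmm: ProfileHMM, seq: str):
    """Best state path and its bit score.

    Returns ``(score_bits, path)`` where path is a list of
    ``(state, model_index, seq_index)`` tuples for core states (state in
    "MID"; seq_index is None for deletes), in sequence order.
    """
    codes = encode_protein(seq)
    params = _pack(hmm)
    lnv, bpM, bpI, bpD, M, I, D, exit_i, exit_k, exit_del = _viterbi_ln(codes, *params)
    score = (lnv - _null_ln(hmm, codes)) / _LN2
    path = []
    i, k = int(exit_i), int(exit_k)
    state = "D" if exit_del else "M"
    while True:
        if state == "M":
            path.append(("M", k, i - 1))
            code = bpM[i, k]
            if code == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(code)]
            i -= 1
            k -= 1
        elif state == "I":
            path.append(("I", k, i - 1))
            state = "M" if bpI[i, k] == 0 else "I"
            i -= 1
        else:  # D
            path.append(("D", k, None))
            state = "M" if bpD[i, k] == 0 else "D"
            k -= 1
    path.reverse()
    return score, path


def viterbi_score(hmm: ProfileHMM, seq: str) -> float:
    return viterbi_trace(hmm, seq)[0]


def match_region(path) -> tuple[int, int]:
    """0-based half-open sequence interval covered by the core alignment."""
    pos = [p for s, _, p in path if p is not None]
    return (pos[0], pos[-1] + 1) if pos else (0, 0)


# ---------------------------------------------------------------------------
# Calibration and search
# ---------------------------------------------------------------------------


def calibrate(
    hmm: ProfileHMM, n_decoys: int = 2000, decoy_length: int = 200, seed: int = 0
) -> ProfileHMM:
    """Calibrate significance against Forward scores of background decoys.

    A maximum-likelihood Gumbel fit ``(mu, lambda)`` summarizes the decoy
    score distribution; the sorted decoy scores themselves are retained and
    drive the P-value curve (see :func:`score_pvalue`).  Deterministic for a
    fixed seed.
    """
    if n_decoys < 200:
        raise ValueError("calibration requires at least 200 decoys")
    from scipy.stats import gumbel_r

    rng = np.random.default_rng(seed)
    decoys = []
    for _ in range(n_decoys):
        codes = rng.choice(N_AA, size=int(decoy_length), p=hmm.background)
        decoys.append("".join(AA_ALPHABET[c] for c in codes))
    scores = forward_scores(hmm, decoys)
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate decoy score distribution (zero variance)")
    mu, beta = gumbel_r.fit(scores)
    hmm.mu = float(mu)
    hmm.lambda_ = float(1.0 / beta)
    hmm.calib_scores = np.sort(scores)
    hmm.calib_length = int(decoy_length)
    hmm.provenance.update(
        {"calib_n_decoys": n_decoys, "calib_decoy_length": decoy_length, "calib_seed": seed}
    )
    return hmm


def score_pvalues(hmm: ProfileHMM, scores, target_lengths=None) -> np.ndarray:
    """P(S >= score) for background decoys under the calibration.

    Scores are first length-normalized by ``log2(target_len / calib_len)``
    (Forward scores of null sequences grow logarithmically with target length
    because every additional residue adds alignment start points).  Within
    the range of the calibration decoy scores the survival function is
    empirical (log-scale interpolation between midpoint ranks); beyond the
    largest decoy score it continues exponentially at the universal
    likelihood-ratio rate — the score is a log2 odds ratio, so
    ``P(S >= s) <= 2**-s`` for any null sequence (Markov bound), so the
    continuation is that bound capped at the last empirical survival value.
    Monotone non-increasing in the score (strictly decreasing except on the
    short cap between the empirical range and the bound).
    """
    if not hmm.calibrated:
        raise ValueError("model is not calibrated; run calibrate() first")
    xs = hmm.calib_scores
    n = len(xs)
    scores = np.asarray(scores, dtype=float)
    if target_lengths is not None:
        scores = scores - np.log2(np.asarray(target_lengths, dtype=float) / hmm.calib_length)
    surv = (n - np.arange(1, n + 1) + 0.5) / n
    out = np.exp(np.interp(scores, xs, np.log(surv)))
    out[scores <= xs[0]] = 1.0
    hi = scores > xs[-1]
    # beyond the sample: the Markov bound itself, capped at the last
    # empirical survival (monotone, guaranteed >= the true tail probability)
    out[hi] = np.minimum(0.5 / n, np.exp(-_LN2 * scores[hi]))
    return out


def score_pvalue(hmm: ProfileHMM, score: float, target_length: int | None = None) -> float:
    """Scalar :func:`score_pvalues`."""
    tl = None if target_length is None else [target_length]
    return float(score_pvalues(hmm, [score], tl)[0])


def score_evalue(
    hmm: ProfileHMM, score: float, n_targets: int, target_length: int | None = None
) -> float:
    return score_pvalue(hmm, score, target_length) * n_targets


def hmmsearch(hmm: ProfileHMM, db, inclusion: float = 0.01, species: str = "") -> list[HmmHit]:
    """Search a proteome with a calibrated profile.

    ``db`` is an :class:`~nemaclock.orthology.ProteomeDB` (or any object with
    ``records`` of ``(id, sequence)``).  Every target is scored and reported;
    hits are sorted by ascending E-value, then descending score, then target
    id, with ``included`` set by ``E <= inclusion``.
    """
    if not hmm.calibrated:
        raise ValueError("model is not calibrated; run calibrate() first")
    records = list(db.records)
    if not records:
        return []
    n = len(records)
    scores = forward_scores(hmm, [s for _, s in records])
    pvals = score_pvalues(hmm, scores, [len(s) for _, s in records])
    hits = []
    for (tid, _), sc, pv in zip(records, scores, pvals):
        e = float(pv) * n
        hits.append(
            HmmHit(hmm.name, tid, float(sc), e, e <= inclusion, species or getattr(db, "species", ""))
        )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.target))
    return hits


# ---------------------------------------------------------------------------
# Serialization (documented plain-text format, HMMER3-like but not compatible)
# ---------------------------------------------------------------------------


def save_hmm(hmm: ProfileHMM, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_hmm(hmm))


def dumps_hmm(hmm: ProfileHMM) -> str:
    out = io.StringIO()
    f = lambda v: format(float(v), ".17g")
    out.write("NEMACLOCK-HMM 1\n")
    out.write(f"NAME {hmm.name}\n")
    out.write(f"LENG {hmm.L}\n")
    out.write(f"ALPH {AA_ALPHABET}\n")
    out.write(f"ETA {f(hmm.eta)}\n")
    out.write("BG " + " ".join(f(v) for v in hmm.background) + "\n")
    if hmm.mu is not None and hmm.lambda_ is not None:
        out.write(f"CALIB {f(hmm.mu)} {f(hmm.lambda_)}\n")
    if hmm.calib_scores is not None:
        out.write(f"CALLEN {hmm.calib_length}\n")
        out.write("CALSCORES " + " ".join(f(v) for v in hmm.calib_scores) + "\n")
    for key, val in sorted(hmm.provenance.items()):
        out.write(f"PROV {key} {val}\n")
    for k in range(hmm.L):
        out.write(f"MATCH {k} " + " ".join(f(v) for v in hmm.match_em[k]) + "\n")
        out.write(f"INS {k} " + " ".join(f(v) for v in hmm.insert_em[k]) + "\n")
        out.write(
            f"TRANS {k} "
            + " ".join(
                f(v)
                for v in (
                    hmm.t_mm[k], hmm.t_mi[k], hmm.t_md[k], hmm.t_me[k],
                    hmm.t_im[k], hmm.t_ii[k], hmm.t_dm[k], hmm.t_dd[k],
                )
            )
            + "\n"
        )
    out.write("//\n")
    return out.getvalue()


def load_hmm(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("NEMACLOCK-HMM"):
        raise ValueError(f"{path}: not a nemaclock HMM file")
    name = "profile"
    L = 0
    eta = 0.95
    bg = None
    mu = lam = None
    calib_scores = None
    calib_length = 200
    prov = {}
    rows = {}
    for ln in lines[1:]:
        if ln == "//" or not ln.strip():
            continue
        tag, rest = ln.split(" ", 1)
        if tag == "NAME":
            name = rest
        elif tag == "LENG":
            L = int(rest)
        elif tag == "ETA":
            eta = float(rest)
        elif tag == "BG":
            bg = np.array([float(v) for v in rest.split()])
        elif tag == "CALIB":
            mu, lam = (float(v) for v in rest.split())
        elif tag == "CALLEN":
            calib_length = int(rest)
        elif tag == "CALSCORES":
            calib_scores = np.array([float(v) for v in rest.split()])
        elif tag == "PROV":
            k, v = rest.split(" ", 1)
            prov[k] = v
        elif tag in ("MATCH", "INS", "TRANS"):
            k, vals = rest.split(" ", 1)
            rows[(tag, int(k))] = np.array([float(v) for v in vals.split()])
    match_em = np.stack([rows[("MATCH", k)] for k in range(L)])
    insert_em = np.stack([rows[("INS", k)] for k in range(L)])
    trans = np.stack([rows[("TRANS", k)] for k in range(L)])
    hmm = ProfileHMM(
        name=name,
        match_em=match_em,
        insert_em=insert_em,
        t_mm=trans[:, 0], t_mi=trans[:, 1], t_md=trans[:, 2], t_me=trans[:, 3],
        t_im=trans[:, 4], t_ii=trans[:, 5], t_dm=trans[:, 6], t_dd=trans[:, 7],
        background=bg,
        eta=eta,
        mu=mu,
        lambda_=lam,
        calib_scores=calib_scores,
        calib_length=calib_length,
        provenance=prov,
    )
    hmm.validate()
    return hmm
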