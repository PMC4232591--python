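"""Pairwise and progressive protein alignment with BLAST-style statistics.

Global alignment uses the Gotoh three-state affine-gap recurrence, local
alignment the affine-gap Smith–Waterman variant.  A gap of length ``g`` costs
``gap_open + g * gap_extend`` (the BLAST convention; the bundled defaults are
BLOSUM62 with open 11, extend 1).  E-values follow Karlin–Altschul,
``E = K * m * n * exp(-lambda * S)``, with ``(lambda, K)`` estimated by a
maximum-likelihood Gumbel fit to local scores of shuffled/random decoy pairs.

Progressive multiple alignment builds a neighbor-joining guide tree from
pairwise global-alignment distances and merges profiles at internal nodes
under "once a gap, always a gap".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_NEG = -1e30


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Residue substitution scores plus affine gap penalties.

    ``scores[i, j]`` is the (symmetric, integer-valued) score for the ordered
    residue pair ``(alphabet[i], alphabet[j])``.
    """

    alphabet: str
    scores: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.alphabet)})
        s = np.asarray(self.scores, dtype=np.float64)
        if s.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        object.__setattr__(self, "scores", s)

    def encode(self, seq: str, *, what: str = "sequence") -> np.ndarray:
        """Map residues to matrix indices, naming any offending symbol."""
        out = np.empty(len(seq), dtype=np.int64)
        for pos, c in enumerate(seq):
            i = self._index.get(c)
            if i is None:
                raise ValueError(
                    f"residue {c!r} at position {pos} of {what} is outside the "
                    f"matrix alphabet {self.alphabet!r}"
                )
            out[pos] = i
        return out

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index[a], self._index[b]])


def blosum62(gap_open: int = 11, gap_extend: int = 1) -> SubstitutionMatrix:
    """BLOSUM62 restricted to the 20 canonical residues (BLAST default gaps)."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    idx = [m.alphabet.index(c) for c in AA_ALPHABET]
    scores = np.asarray(m)[np.ix_(idx, idx)]
    return SubstitutionMatrix(AA_ALPHABET, scores, gap_open, gap_extend)


def read_ncbi_matrix(path, gap_open: int = 11, gap_extend: int = 1) -> SubstitutionMatrix:
    """Read a plain-text square score table in NCBI matrix format."""
    with open(path) as fh:
        rows = [ln.split() for ln in fh if ln.strip() and not ln.startswith("#")]
    cols = rows[0]
    alphabet = "".join(c for c in cols if len(c) == 1)
    n = len(alphabet)
    mat = np.zeros((n, n))
    lookup = {c: i for i, c in enumerate(alphabet)}
    for row in rows[1:]:
        if row[0] not in lookup:
            continue
        i = lookup[row[0]]
        for c, val in zip(cols, row[1:]):
            if c in lookup:
                mat[i, lookup[c]] = float(val)
    return SubstitutionMatrix(alphabet, mat, gap_open, gap_extend)


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A pairwise alignment: gapped strings plus score and region coordinates.

    Coordinates are 0-based half-open on the original (ungapped) sequences.
    """

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    def recompute_score(self, matrix: SubstitutionMatrix) -> float:
        """Re-derive the score from the columns (consistency check)."""
        total = 0.0
        gap_a = gap_b = False
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("column of two gaps")
            if x == "-":
                total -= matrix.gap_extend + (0 if gap_a else matrix.gap_open)
                gap_a, gap_b = True, False
            elif y == "-":
                total -= matrix.gap_extend + (0 if gap_b else matrix.gap_open)
                gap_a, gap_b = False, True
            else:
                total += matrix.score(x, y)
                gap_a = gap_b = False
        return total


class MSA:
    """A multiple sequence alignment: ordered (id, aligned sequence) rows."""

    def __init__(self, records):
        self.records = [(str(i), str(s)) for i, s in records]
        if self.records:
            n = len(self.records[0][1])
            if any(len(s) != n for _, s in self.records):
                raise ValueError("all MSA rows must have equal length")

    @property
    def ids(self):
        return [i for i, _ in self.records]

    @property
    def ncols(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def __len__(self):
        return len(self.records)

    def row(self, rid: str) -> str:
        for i, s in self.records:
            if i == rid:
                return s
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")

    def column_map(self, rid: str) -> np.ndarray:
        """For each ungapped residue of a row, the MSA column holding it."""
        return np.array([k for k, c in enumerate(self.row(rid)) if c != "-"])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, s in self.records:
                fh.write(f">{i}\n{s}\n")

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        from Bio import SeqIO

        return cls((r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta"))

    def to_stockholm(self, path) -> None:
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import AlignIO

        aln = MultipleSeqAlignment(
            [SeqRecord(Seq(s), id=i, description="") for i, s in self.records]
        )
        AlignIO.write(aln, str(path), "stockholm")

    @classmethod
    def from_stockholm(cls, path) -> "MSA":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "stockholm")
        return cls((r.id, str(r.seq)) for r in aln)


# ---------------------------------------------------------------------------
# Dynamic-programming kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gotoh_fill_global(sa, sb, S, go, ge):
    m, n = len(sa), len(sb)
    H = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)  # gap in a (consumes b)
    F = np.full((m + 1, n + 1), _NEG)  # gap in b (consumes a)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -(go + ge * j)
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -(go + ge * i)
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go - ge, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go - ge, F[i - 1, j] - ge)
            M = H[i - 1, j - 1] + S[sa[i - 1], sb[j - 1]]
            H[i, j] = max(M, max(E[i, j], F[i, j]))
    return H, E, F


@njit(cache=True)
def _gotoh_fill_local(sa, sb, S, go, ge):
    m, n = len(sa), len(sb)
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go - ge, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go - ge, F[i - 1, j] - ge)
            M = H[i - 1, j - 1] + S[sa[i - 1], sb[j - 1]]
            H[i, j] = max(0.0, max(M, max(E[i, j], F[i, j])))
    return H, E, F


@njit(cache=True, fastmath=True)
def _sw_scores_concat(q, concat, starts, ends, S, go, ge):
    """Best local score of query ``q`` against each target slice of ``concat``."""
    nt = len(starts)
    out = np.empty(nt)
    m = len(q)
    for t in range(nt):
        Hprev = np.zeros(m + 1)
        Hcur = np.zeros(m + 1)
        Egap = np.full(m + 1, _NEG)
        best = 0.0
        for j in range(starts[t], ends[t]):
            c = concat[j]
            Fcur = _NEG
            Hcur[0] = 0.0
            for i in range(1, m + 1):
                Egap[i] = max(Hprev[i] - go - ge, Egap[i] - ge)
                Fcur = max(Hcur[i - 1] - go - ge, Fcur - ge)
                M = Hprev[i - 1] + S[q[i - 1], c]
                h = max(0.0, max(M, max(Egap[i], Fcur)))
                Hcur[i] = h
                if h > best:
                    best = h
            Hprev, Hcur = Hcur, Hprev
        out[t] = best
    return out


# ---------------------------------------------------------------------------
# Pairwise alignment API
# ---------------------------------------------------------------------------


def _check_nonempty(a, b):
    if not a or not b:
        raise ValueError("alignment requires two non-empty sequences")


def _traceback(sa_str, sb_str, H, E, F, matrix, i, j, local):
    """Shared traceback.  Tie preference: match/mismatch > gap-in-a > gap-in-b;
    within a gap state, prefer closing (opening move) over extending."""
    go, ge = matrix.gap_open, matrix.gap_extend
    S = matrix.scores
    ia = matrix._index
    out_a, out_b = [], []
    state = "H"
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "H":
            h = H[i, j]
            if local and h <= eps:
                break
            if (
                i > 0
                and j > 0
                and abs(H[i - 1, j - 1] + S[ia[sa_str[i - 1]], ia[sb_str[j - 1]]] - h) < eps
            ):
                out_a.append(sa_str[i - 1])
                out_b.append(sb_str[j - 1])
                i -= 1
                j -= 1
            elif j > 0 and abs(E[i, j] - h) < eps:
                state = "E"
            elif i > 0 and abs(F[i, j] - h) < eps:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("inconsistent DP traceback")
        elif state == "E":
            out_a.append("-")
            out_b.append(sb_str[j - 1])
            opened = abs(H[i, j - 1] - go - ge - E[i, j]) < eps
            j -= 1
            if opened:
                state = "H"
        else:  # F
            out_a.append(sa_str[i - 1])
            out_b.append("-")
            opened = abs(H[i - 1, j] - go - ge - F[i, j]) < eps
            i -= 1
            if opened:
                state = "H"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def align_global(a: str, b: str, matrix: SubstitutionMatrix) -> Alignment:
    """Optimal global alignment (Gotoh affine-gap recurrence)."""
    _check_nonempty(a, b)
    sa = matrix.encode(a, what="first sequence")
    sb = matrix.encode(b, what="second sequence")
    H, E, F = _gotoh_fill_global(sa, sb, matrix.scores, float(matrix.gap_open), float(matrix.gap_extend))
    aa, ab, _, _ = _traceback(a, b, H, E, F, matrix, len(a), len(b), local=False)
    return Alignment(aa, ab, float(H[len(a), len(b)]), 0, len(a), 0, len(b))


def align_local(a: str, b: str, matrix: SubstitutionMatrix) -> Alignment:
    """Optimal local alignment (affine-gap Smith–Waterman).

    Returns an empty alignment with score 0 when no positive-scoring residue
    pair exists.  The best cell is chosen deterministically (smallest end
    coordinates on ties).
    """
    _check_nonempty(a, b)
    sa = matrix.encode(a, what="first sequence")
    sb = matrix.encode(b, what="second sequence")
    H, E, F = _gotoh_fill_local(sa, sb, matrix.scores, float(matrix.gap_open), float(matrix.gap_extend))
    best = float(H.max())
    if best <= 0:
        return Alignment("", "", 0.0)
    i, j = np.argwhere(H == best)[0]
    aa, ab, i0, j0 = _traceback(a, b, H, E, F, matrix, int(i), int(j), local=True)
    return Alignment(aa, ab, best, i0, int(i), j0, int(j))


def local_scores(query: str, targets, matrix: SubstitutionMatrix) -> np.ndarray:
    """Local-alignment scores of one query against many targets (fast path)."""
    q = matrix.encode(query, what="query")
    encoded = [matrix.encode(t, what=f"target {k}") for k, t in enumerate(targets)]
    if not encoded:
        return np.zeros(0)
    starts = np.zeros(len(encoded), dtype=np.int64)
    ends = np.zeros(len(encoded), dtype=np.int64)
    pos = 0
    for k, e in enumerate(encoded):
        starts[k] = pos
        pos += len(e)
        ends[k] = pos
    concat = np.concatenate(encoded) if encoded else np.zeros(0, dtype=np.int64)
    return _sw_scores_concat(
        q, concat, starts, ends, matrix.scores, float(matrix.gap_open), float(matrix.gap_extend)
    )


# ---------------------------------------------------------------------------
# Karlin–Altschul statistics
# ---------------------------------------------------------------------------


def evalue_pairwise(score: float, query_len: int, db_residue_count: int, lambda_: float, K: float) -> float:
    """Karlin–Altschul E-value ``K * m * n * exp(-lambda * S)``."""
    if query_len <= 0 or db_residue_count <= 0:
        raise ValueError("sequence/database lengths must be positive")
    if lambda_ <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    return float(K * query_len * db_residue_count * np.exp(-lambda_ * score))


def fit_karlin_altschul(
    matrix: SubstitutionMatrix,
    query_len: int = 200,
    target_len: int = 200,
    n_samples: int = 2000,
    seed: int = 0,
    background=None,
):
    """Estimate (lambda, K) from local scores of i.i.d. random decoy pairs.

    Scores of ungapped/gapped local alignment of random sequences follow an
    extreme-value (Gumbel) law; a maximum-likelihood Gumbel fit with location
    ``mu`` and scale ``beta`` gives ``lambda = 1/beta`` and
    ``K = exp(mu/beta) / (m*n)`` for the calibration lengths ``(m, n)``.
    """
    from scipy.stats import gumbel_r

    rng = np.random.default_rng(seed)
    n_letters = len(matrix.alphabet)
    bg = np.full(n_letters, 1.0 / n_letters) if background is None else np.asarray(background)
    scores = np.empty(n_samples)
    for k in range(n_samples):
        q = rng.choice(n_letters, size=query_len, p=bg).astype(np.int64)
        t = rng.choice(n_letters, size=target_len, p=bg).astype(np.int64)
        scores[k] = _sw_scores_concat(
            q,
            t,
            np.array([0], dtype=np.int64),
            np.array([len(t)], dtype=np.int64),
            matrix.scores,
            float(matrix.gap_open),
            float(matrix.gap_extend),
        )[0]
    mu, beta = gumbel_r.fit(scores)
    lambda_ = 1.0 / beta
    K = float(np.exp(mu / beta) / (query_len * target_len))
    return lambda_, K


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


def _identity_distance(a: str, b: str, matrix: SubstitutionMatrix) -> float:
    aln = align_global(a, b, matrix)
    cols = len(aln.aligned_a)
    same = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-")
    return 1.0 - same / cols if cols else 0.0


def _profile_freqs(rows, matrix):
    """Per-column residue frequency matrix; gap mass simply missing."""
    n_letters = len(matrix.alphabet)
    ncols = len(rows[0])
    freqs = np.zeros((ncols, n_letters))
    for r in rows:
        for k, c in enumerate(r):
            if c != "-":
                freqs[k, matrix._index[c]] += 1.0
    return freqs / len(rows)


def _align_profiles(rows_a, rows_b, matrix):
    """Global affine alignment of two profiles; returns merged gapped rows.

    Column score is the expected substitution score between the two column
    residue distributions (gaps contribute zero).
    """
    fa = _profile_freqs(rows_a, matrix)
    fb = _profile_freqs(rows_b, matrix)
    colscore = fa @ matrix.scores @ fb.T
    m, n = colscore.shape
    go, ge = float(matrix.gap_open), float(matrix.gap_extend)
    H = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -(go + ge * j)
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -(go + ge * i)
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        Ei = E[i]
        Fi = F[i]
        Hi = H[i]
        Hp = H[i - 1]
        Fp = F[i - 1]
        cs = colscore[i - 1]
        for j in range(1, n + 1):
            Ei[j] = max(Hi[j - 1] - go - ge, Ei[j - 1] - ge)
            Fi[j] = max(Hp[j] - go - ge, Fp[j] - ge)
            Hi[j] = max(Hp[j - 1] + cs[j - 1], Ei[j], Fi[j])
    # traceback over column indices
    i, j = m, n
    ops = []  # 'D' diag, 'A' gap in A-profile, 'B' gap in B-profile
    state = "H"
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "H":
            h = H[i, j]
            if i > 0 and j > 0 and abs(H[i - 1, j - 1] + colscore[i - 1, j - 1] - h) < eps:
                ops.append("D")
                i -= 1
                j -= 1
            elif j > 0 and abs(E[i, j] - h) < eps:
                state = "E"
            elif i > 0 and abs(F[i, j] - h) < eps:
                state = "F"
            else:  # pragma: no cover
                raise AssertionError("inconsistent profile traceback")
        elif state == "E":
            ops.append("A")
            opened = abs(H[i, j - 1] - go - ge - E[i, j]) < eps
            j -= 1
            if opened:
                state = "H"
        else:
            ops.append("B")
            opened = abs(H[i - 1, j] - go - ge - F[i, j]) < eps
            i -= 1
            if opened:
                state = "H"
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ia += 1
            ib += 1
        elif op == "A":
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
        else:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r in out_b:
                r.append("-")
            ia += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(seqs, matrix: SubstitutionMatrix) -> MSA:
    """Guide-tree progressive multiple alignment.

    ``seqs`` is an ordered list of ``(id, sequence)`` pairs.  The guide tree
    comes from neighbor joining on pairwise normalized global-alignment
    distances; profiles are merged at internal nodes ("once a gap, always a
    gap").  Row order in the result follows the input order.
    """
    seqs = [(str(i), str(s)) for i, s in seqs]
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        warnings.warn("single sequence: returning a trivial one-row MSA")
        return MSA(seqs)
    if len(seqs) == 2:
        aln = align_global(seqs[0][1], seqs[1][1], matrix)
        return MSA([(seqs[0][0], aln.aligned_a), (seqs[1][0], aln.aligned_b)])

    from .phylo import nj_tree  # local import: phylo depends on this module

    labels = [i for i, _ in seqs]
    by_id = dict(seqs)
    n = len(labels)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _identity_distance(seqs[i][1], seqs[j][1], matrix)
            dmat[i, j] = dmat[j, i] = d
    tree = nj_tree(labels, dmat)

    def merge(node):
        if node.is_leaf():
            return [node.name], [by_id[node.name]]
        parts = [merge(c) for c in node.children]
        ids, rows = parts[0]
        for nxt_ids, nxt_rows in parts[1:]:
            rows, nxt_rows = _align_profiles(rows, nxt_rows, matrix)
            ids = ids + nxt_ids
            rows = rows + nxt_rows
        return ids, rows

    ids, rows = merge(tree)
    by_out = dict(zip(ids, rows))
    return MSA([(i, by_out[i]) for i in labels])
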