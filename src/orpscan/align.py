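"""Pairwise alignment primitives: affine-gap Needleman-Wunsch (Gotoh).

The scorer is shared by sequence-sequence and profile-sequence alignment:
the dynamic program runs over a precomputed position-score matrix, so a
"sequence" row can equally be a profile column.

Conventions
-----------
* A gap of length ``k`` costs ``gap_open + k * gap_extend`` (the first
  gapped position pays both the opening and one extension).
* Traceback ties are broken deterministically: diagonal (match state)
  first, then up (gap in the subject), then left (gap in the query).
* ``semiglobal=True`` makes leading and trailing gaps free in both
  sequences (glocal / overlap alignment), the mode used for domain search
  and reference anchoring; ``False`` is strict global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .io import ALPHABET

_NEG = -1e18
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@lru_cache(maxsize=None)
def blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 (20 canonical + X) float matrix in ALPHABET order."""
    raw = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            m[i, j] = raw[a][b]
    return m


def encode(seq: str) -> np.ndarray:
    """Encode residues as ALPHABET indices; unknown characters are errors."""
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside alphabet {ALPHABET!r}") from None


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine gap penalties."""

    matrix: np.ndarray = field(default_factory=blosum62)
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")


@dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal pairwise alignment with identity/coverage summaries."""

    query_id: str
    subject_id: str
    score: float
    aligned_query: str
    aligned_subject: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings must have equal length")


# State codes for the three Gotoh matrices.
_M, _X, _Y = 0, 1, 2  # match/mismatch, gap-in-subject (up), gap-in-query (left)


@njit(cache=False)
def _gotoh_fill(S, gap_open, gap_extend, semiglobal):  # pragma: no cover - numba
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    go = float(gap_open)
    ge = float(gap_extend)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if semiglobal else -(go + i * ge)
        pX[i, 0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if semiglobal else -(go + j * ge)
        pY[0, j] = _M if j == 1 else _Y

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: best predecessor at (i-1, j-1), preference M > X > Y
            best = M[i - 1, j - 1]
            src = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = _Y
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = src

            # gap in subject (consume query residue i)
            best = M[i - 1, j] - (go + ge)
            src = _M
            if X[i - 1, j] - ge > best:
                best = X[i - 1, j] - ge
                src = _X
            if Y[i - 1, j] - (go + ge) > best:
                best = Y[i - 1, j] - (go + ge)
                src = _Y
            X[i, j] = best
            pX[i, j] = src

            # gap in query (consume subject residue j)
            best = M[i, j - 1] - (go + ge)
            src = _M
            if X[i, j - 1] - (go + ge) > best:
                best = X[i, j - 1] - (go + ge)
                src = _X
            if Y[i, j - 1] - ge > best:
                best = Y[i, j - 1] - ge
                src = _Y
            Y[i, j] = best
            pY[i, j] = src

    return M, X, Y, pM, pX, pY


def _best_state(M, X, Y, i, j):
    best, state = M[i, j], _M
    if X[i, j] > best:
        best, state = X[i, j], _X
    if Y[i, j] > best:
        best, state = Y[i, j], _Y
    return best, state


def _align_core(a: str, b: str, params: AlignmentParams, semiglobal: bool):
    """Run the DP and traceback; return (score, aligned_a, aligned_b)."""
    go, ge = params.gap_open, params.gap_extend
    if not a and not b:
        return 0.0, "", ""
    if not a or not b:
        k = len(a) + len(b)
        score = 0.0 if semiglobal else -float(go + k * ge)
        if not a:
            return score, "-" * len(b), b
        return score, a, "-" * len(a)

    ea, eb = encode(a), encode(b)
    S = params.matrix[np.ix_(ea, eb)].astype(np.float64)
    M, X, Y, pM, pX, pY = _gotoh_fill(S, go, ge, semiglobal)
    n, m = len(a), len(b)

    # choose endpoint: (n, m) for global; best over last row/column for
    # semiglobal, preferring (n, m), then the last row right-to-left, then
    # the last column bottom-up (strict improvement only: deterministic).
    ei, ej = n, m
    score, state = _best_state(M, X, Y, n, m)
    if semiglobal:
        for j in range(m - 1, 0, -1):
            s, st = _best_state(M, X, Y, n, j)
            if s > score:
                score, state, ei, ej = s, st, n, j
        for i in range(n - 1, 0, -1):
            s, st = _best_state(M, X, Y, i, m)
            if s > score:
                score, state, ei, ej = s, st, i, m
        if X[n, 0] > score:  # degenerate overlap: nothing aligned
            score, state, ei, ej = X[n, 0], _X, n, 0
        if Y[0, m] > score:
            score, state, ei, ej = Y[0, m], _Y, 0, m

    out_a: list[str] = []
    out_b: list[str] = []
    # free trailing gaps (semiglobal endpoints short of the corner)
    for j in range(m, ej, -1):
        out_a.append("-")
        out_b.append(b[j - 1])
    for i in range(n, ei, -1):
        out_a.append(a[i - 1])
        out_b.append("-")

    i, j = ei, ej
    while i > 0 or j > 0:
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = pM[i, j]
            i, j = i - 1, j - 1
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = pX[i, j]
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            state = pY[i, j]
            j -= 1
        if i == 0 and j > 0:
            state = _Y
        elif j == 0 and i > 0:
            state = _X

    return float(score), "".join(reversed(out_a)), "".join(reversed(out_b))


def _summaries(aligned_a: str, aligned_b: str, query_len: int) -> tuple[float, float]:
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0, 0.0
    ident = sum(x == y for x, y in pairs) / len(pairs)
    cov = len(pairs) / query_len if query_len else 0.0
    return ident, cov


def global_align(
    a: str, b: str, params: AlignmentParams | None = None,
    query_id: str = "query", subject_id: str = "subject",
) -> PairwiseAlignment:
    """Optimal global alignment of ``a`` vs ``b`` under affine gap costs."""
    params = params or AlignmentParams()
    score, aa, bb = _align_core(a, b, params, semiglobal=False)
    ident, cov = _summaries(aa, bb, len(a))
    return PairwiseAlignment(query_id, subject_id, score, aa, bb, ident, cov)


def semiglobal_align(
    a: str, b: str, params: AlignmentParams | None = None,
    query_id: str = "query", subject_id: str = "subject",
) -> PairwiseAlignment:
    """Global alignment with free end gaps — the search/anchoring mode."""
    params = params or AlignmentParams()
    score, aa, bb = _align_core(a, b, params, semiglobal=True)
    ident, cov = _summaries(aa, bb, len(a))
    return PairwiseAlignment(query_id, subject_id, score, aa, bb, ident, cov)


def profile_align(
    profile_scores: np.ndarray, seq: str, params: AlignmentParams | None = None,
    semiglobal: bool = True,
) -> tuple[float, np.ndarray]:
    """Align a position-score profile to a sequence.

    ``profile_scores`` has shape (n_columns, 21) in ALPHABET order.  Returns
    the optimal score and, per profile column, the 0-based sequence position
    aligned to it (-1 where the column aligns to a gap).
    """
    params = params or AlignmentParams()
    if profile_scores.shape[0] == 0 or not seq:
        return 0.0, np.full(profile_scores.shape[0], -1, dtype=np.int64)
    eb = encode(seq)
    S = profile_scores[:, eb].astype(np.float64)
    go, ge = params.gap_open, params.gap_extend
    M, X, Y, pM, pX, pY = _gotoh_fill(S, go, ge, semiglobal)
    n, m = S.shape

    ei, ej = n, m
    score, state = _best_state(M, X, Y, n, m)
    if semiglobal:
        for j in range(m - 1, 0, -1):
            s, st = _best_state(M, X, Y, n, j)
            if s > score:
                score, state, ei, ej = s, st, n, j
        for i in range(n - 1, 0, -1):
            s, st = _best_state(M, X, Y, i, m)
            if s > score:
                score, state, ei, ej = s, st, i, m

    mapping = np.full(n, -1, dtype=np.int64)
    i, j = ei, ej
    while i > 0 or j > 0:
        if state == _M:
            mapping[i - 1] = j - 1
            state = pM[i, j]
            i, j = i - 1, j - 1
        elif state == _X:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
        if i == 0 and j > 0:
            state = _Y
        elif j == 0 and i > 0:
            state = _X
    return float(score), mapping
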