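"""Global pairwise alignment identity with affine gap penalties.

Identity is defined as ``matches / alignment_length`` from an optimal global
(Needleman-Wunsch/Gotoh) alignment under integer scoring (default match +1,
mismatch -1, gap open -10, gap extend -1; the opening position of a gap
costs the open score, each further position the extend score).

Optimal alignments are generally not unique, and co-optimal alignments can
differ in their match counts, so "the identity of the optimal alignment" is
ambiguous.  This implementation makes it deterministic by ranking alignments
lexicographically: maximal score, then maximal matches, then maximal number
of aligned (non-gap) columns.  The three objectives are packed into a single
int64 per DP cell, so one Gotoh pass yields the canonical identity without
traceback.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["AlignmentSummary", "global_identity"]

_NEG = np.int64(-(2**62))

try:  # scalar DP kernel, ~100x faster when numba is present
    from numba import njit

    @njit(cache=False)
    def _gotoh_kernel(a_codes, b_codes, match, mismatch, open_p, ext_p,
                      C1, C2):  # pragma: no cover - exercised via wrapper
        la = a_codes.size
        lb = b_codes.size
        NEG = -(2**62)
        M = np.full(lb + 1, NEG, dtype=np.int64)
        X = np.full(lb + 1, NEG, dtype=np.int64)
        Y = np.full(lb + 1, NEG, dtype=np.int64)
        M[0] = 0
        for j in range(1, lb + 1):
            Y[j] = open_p + (j - 1) * ext_p
        Mn = np.empty(lb + 1, dtype=np.int64)
        Xn = np.empty(lb + 1, dtype=np.int64)
        Yn = np.empty(lb + 1, dtype=np.int64)
        for i in range(1, la + 1):
            Mn[0] = NEG
            Xn[0] = open_p + (i - 1) * ext_p
            Yn[0] = NEG
            ai = a_codes[i - 1]
            for j in range(1, lb + 1):
                prev = max(M[j - 1], X[j - 1], Y[j - 1])
                if b_codes[j - 1] == ai:
                    Mn[j] = prev + match * C1 + C2 + 1
                else:
                    Mn[j] = prev + mismatch * C1 + 1
                Xn[j] = max(M[j] + open_p, X[j] + ext_p, Y[j] + open_p)
                Yn[j] = max(Mn[j - 1] + open_p, Yn[j - 1] + ext_p,
                            Xn[j - 1] + open_p)
            M, Mn = Mn, M
            X, Xn = Xn, X
            Y, Yn = Yn, Y
        return max(M[lb], X[lb], Y[lb])

except ImportError:  # pragma: no cover
    _gotoh_kernel = None


@dataclasses.dataclass(frozen=True)
class AlignmentSummary:
    score: int
    matches: int
    aligned_pairs: int
    alignment_length: int
    identity: float


def global_identity(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -10,
    gap_extend: int = -1,
) -> AlignmentSummary:
    """Canonical global-alignment identity between two sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    la, lb = len(a), len(b)
    lmin = min(la, lb)
    # packing constants: score differences (integers) must dominate the
    # match/pair tie-breaks
    C2 = np.int64(lmin + 2)
    C1 = np.int64(C2 * (lmin + 2))

    a_codes = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    b_codes = np.frombuffer(b.encode("ascii"), dtype=np.uint8)

    if _gotoh_kernel is not None:
        combined = int(
            _gotoh_kernel(
                a_codes, b_codes, np.int64(match), np.int64(mismatch),
                np.int64(gap_open) * C1, np.int64(gap_extend) * C1, C1, C2
            )
        )
    else:
        combined = _gotoh_numpy(a_codes, b_codes, match, mismatch,
                                gap_open, gap_extend, C1, C2)
    tie = combined % int(C1)
    score = (combined - tie) // int(C1)
    matches = tie // int(C2)
    pairs = tie % int(C2)
    alignment_length = la + lb - pairs
    return AlignmentSummary(
        score=int(score),
        matches=int(matches),
        aligned_pairs=int(pairs),
        alignment_length=int(alignment_length),
        identity=matches / alignment_length,
    )


def _gotoh_numpy(a_codes, b_codes, match, mismatch, gap_open, gap_extend,
                 C1, C2) -> int:
    """Row-vectorised fallback for the packed Gotoh recursion."""
    la, lb = a_codes.size, b_codes.size
    open_p = np.int64(gap_open) * C1
    ext_p = np.int64(gap_extend) * C1

    # previous-row state
    M = np.full(lb + 1, _NEG, dtype=np.int64)
    X = np.full(lb + 1, _NEG, dtype=np.int64)
    Y = np.full(lb + 1, _NEG, dtype=np.int64)
    M[0] = 0
    js = np.arange(1, lb + 1, dtype=np.int64)
    Y[1:] = open_p + (js - 1) * ext_p

    ks = np.arange(lb, dtype=np.int64)
    for i in range(1, la + 1):
        best_prev = np.maximum(np.maximum(M, X), Y)
        sub = np.where(
            b_codes == a_codes[i - 1],
            np.int64(match) * C1 + C2 + 1,
            np.int64(mismatch) * C1 + 1,
        )
        M_new = np.full(lb + 1, _NEG, dtype=np.int64)
        M_new[1:] = best_prev[:-1] + sub
        X_new = np.full(lb + 1, _NEG, dtype=np.int64)
        X_new[1:] = np.maximum(
            np.maximum(M[1:] + open_p, X[1:] + ext_p), Y[1:] + open_p
        )
        X_new[0] = open_p + np.int64(i - 1) * ext_p
        # horizontal gaps within the current row via a max prefix scan:
        # Y[i, j] = open + (j-1-k)*ext + max(M[i,k], X[i,k]) over k < j
        base = np.maximum(M_new[:-1], X_new[:-1])
        t = base - ks * ext_p
        running = np.maximum.accumulate(t)
        Y_new = np.full(lb + 1, _NEG, dtype=np.int64)
        Y_new[1:] = open_p + (js - 1) * ext_p + running
        M, X, Y = M_new, X_new, Y_new

    return int(max(M[lb], X[lb], Y[lb]))
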