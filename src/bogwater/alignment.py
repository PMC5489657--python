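"""Deterministic semi-global pairwise alignment for identity routing.

Routing between the curated freshwater database and the comprehensive
database needs only a percent identity between a short (~150 bp) query
and a full-length reference.  The aligner here is a textbook semi-global
dynamic program: end gaps on the reference are free (the query may match
anywhere inside the reference), end gaps on the query are penalized,
scoring match +1 / mismatch -1 / linear gap -2.  Percent identity is
100 x identical columns / alignment columns over the traceback.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["align_identity"]

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _semiglobal(q, r):  # pragma: no cover - exercised via align_identity
    m, n = q.shape[0], r.shape[0]
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    P = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 diag, 2 up, 3 left
    H[0, :] = 0  # free reference prefix
    for i in range(1, m + 1):
        H[i, 0] = -2 * i
        P[i, 0] = 2
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = 1 if (qi == r[j - 1] and qi < 4) else -1
            best = H[i - 1, j - 1] + s
            ptr = 1
            up = H[i - 1, j] - 2
            if up > best:
                best, ptr = up, 2
            left = H[i, j - 1] - 2
            if left > best:
                best, ptr = left, 3
            H[i, j] = best
            P[i, j] = ptr
    # free reference suffix: best cell in the last row
    jbest = 0
    for j in range(1, n + 1):
        if H[m, j] > H[m, jbest]:
            jbest = j
    ident = 0
    cols = 0
    i, j = m, jbest
    while i > 0:
        ptr = P[i, j]
        if ptr == 1:
            cols += 1
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                ident += 1
            i -= 1
            j -= 1
        elif ptr == 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return ident, cols


def align_identity(query: str, reference: str) -> float:
    """Percent identity (0-100) of ``query`` aligned inside ``reference``.

    The full query must be aligned; leading/trailing unaligned reference
    sequence is free.  Identical sequences give 100; an exact substring of
    the reference gives 100.
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    ident, cols = _semiglobal(_encode(query), _encode(reference))
    return 100.0 * ident / cols if cols else 0.0
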