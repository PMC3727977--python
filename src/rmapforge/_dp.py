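"""Dynamic-programming kernel for restriction-map alignment.

Kept free of package imports so it can be JIT-compiled by numba when
available; falls back to the identical pure-Python implementation
otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def dp_fill(rcum, qcum, delta, sigma, c_miss, c_extra, cap):
    """Fill the block-alignment DP table.

    ``rcum``/``qcum`` are cumulative-mass arrays over fragment
    boundaries (lengths R+1 and Q+1).  Query boundaries 1..Q-1 are
    placed on reference boundaries 0..R; terminal query fragments are
    unscored.  Returns (D, BP) where D[j-1, i] is the minimal cost of
    placing query boundary j at reference boundary i and BP holds the
    (a, b) block shape used, encoded as a*16+b (0 = start).
    """
    R = rcum.shape[0] - 1
    Q = qcum.shape[0] - 1
    nrow = Q - 1  # query boundaries 1..Q-1
    D = np.full((nrow, R + 1), np.inf)
    BP = np.zeros((nrow, R + 1), dtype=np.int16)
    for i in range(R + 1):
        D[0, i] = 0.0
    for j in range(2, Q):
        row = j - 1
        for i in range(1, R + 1):
            best = np.inf
            best_ab = 0
            bmax = min(delta, j - 1)
            amax = min(delta, i)
            for b in range(1, bmax + 1):
                qm = qcum[j] - qcum[j - b]
                for a in range(1, amax + 1):
                    prev = D[row - b, i - a]
                    if prev == np.inf:
                        continue
                    rm = rcum[i] - rcum[i - a]
                    z = (qm - rm) / (sigma * rm)
                    z2 = z * z
                    if cap > 0.0 and z2 > cap:
                        z2 = cap
                    cost = prev + z2 + (b - 1) * c_extra + (a - 1) * c_miss
                    if cost < best:
                        best = cost
                        best_ab = a * 16 + b
            D[row, i] = best
            BP[row, i] = best_ab
    return D, BP


def traceback(BP, end_i, Q):
    """Recover block list [(ri0, ri1, qi0, qi1), ...] from backpointers."""
    blocks = []
    j = Q - 1
    i = end_i
    while j > 1:
        ab = int(BP[j - 1, i])
        a, b = ab // 16, ab % 16
        blocks.append((i - a, i, j - b, j))
        i -= a
        j -= b
    blocks.reverse()
    return blocks
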