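"""Numba dynamic-programming kernels for the toy energy model.

Sequences are integer-encoded (A=0, C=1, G=2, U=3, anything unpairable=4)
and the pairing model is a 5x5 energy matrix with +inf marking forbidden
pairs.  All intervals are half-open: table entry [i, j] covers s[i:j].
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def mfe_fill(enc, emat, min_loop):
    n = enc.size
    W = np.zeros((n + 1, n + 1))
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = W[i + 1, j]
            for k in range(i + min_loop + 1, j):
                e = emat[enc[i], enc[k]]
                if np.isfinite(e):
                    cand = e + W[i + 1, k] + W[k + 1, j]
                    if cand < best:
                        best = cand
            W[i, j] = best
    return W


@njit(cache=True)
def mfe_traceback(enc, emat, min_loop, W):
    """Recover one MFE structure; ties prefer leaving position i unpaired,
    then the smallest pairing partner k (deterministic)."""
    n = enc.size
    partner = np.full(n, -1, np.int64)
    # explicit interval stack
    si = np.empty(2 * n + 2, np.int64)
    sj = np.empty(2 * n + 2, np.int64)
    top = 0
    si[top] = 0
    sj[top] = n
    top += 1
    while top > 0:
        top -= 1
        i = si[top]
        j = sj[top]
        if j - i < min_loop + 2:
            continue
        if W[i, j] == W[i + 1, j]:
            si[top] = i + 1
            sj[top] = j
            top += 1
            continue
        for k in range(i + min_loop + 1, j):
            e = emat[enc[i], enc[k]]
            if np.isfinite(e) and W[i, j] == e + W[i + 1, k] + W[k + 1, j]:
                partner[i] = k
                partner[k] = i
                si[top] = i + 1
                sj[top] = k
                top += 1
                si[top] = k + 1
                sj[top] = j
                top += 1
                break
    return partner


@njit(cache=True)
def pf_fill(enc, emat, min_loop, rt):
    n = enc.size
    Q = np.ones((n + 1, n + 1))
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            q = Q[i + 1, j]
            for k in range(i + min_loop + 1, j):
                e = emat[enc[i], enc[k]]
                if np.isfinite(e):
                    q += np.exp(-e / rt) * Q[i + 1, k] * Q[k + 1, j]
            Q[i, j] = q
    return Q


@njit(cache=True)
def pair_probabilities(enc, emat, min_loop, rt, Q):
    """Outside algorithm; P[i, k] = Boltzmann probability of pair (i, k)."""
    n = enc.size
    O = np.zeros((n + 1, n + 1))
    O[0, n] = 1.0
    P = np.zeros((n, n))
    for span in range(n, 0, -1):
        for i in range(0, n - span + 1):
            j = i + span
            o = O[i, j]
            if o == 0.0:
                continue
            O[i + 1, j] += o  # position i unpaired
            for k in range(i + min_loop + 1, j):
                e = emat[enc[i], enc[k]]
                if np.isfinite(e):
                    qb = np.exp(-e / rt)
                    O[i + 1, k] += o * qb * Q[k + 1, j]
                    O[k + 1, j] += o * qb * Q[i + 1, k]
                    P[i, k] += o * qb * Q[i + 1, k] * Q[k + 1, j]
    P /= Q[0, n]
    return P
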