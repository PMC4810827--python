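"""Numba kernels: the Metropolis-Hastings chain, change statistics, and the
per-triple triad classifier.

The change-statistic formulas here mirror the numpy reference implementation
in :mod:`.config_statistics` (which is the documented form and the one tested
against brute-force recomputation); they are duplicated in nopython code
because the sampler evaluates them millions of times per fit.  To keep every
change statistic O(n), the chain maintains three pair-count matrices
incrementally alongside the adjacency matrix:

* ``L2[a, b]`` - two-paths a -> t -> b,
* ``CS[a, b]`` - common sinks (predators shared by a and b),
* ``CP[a, b]`` - common sources (prey shared by a and b),

each updated in O(n) when a toggle is accepted (their diagonals are not
used and not kept meaningful).

All kernels assume a 0/1 ``uint8`` adjacency matrix with a zero diagonal.
Statistic codes match ``config_statistics``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ARC, RECIPROCITY, GENERALIST, HIGHLY_PREDATED, KEYSTONE = 0, 1, 2, 3, 4
TRI_TROPHIC, APPARENT_COMP, EXPLOITATIVE_COMP, OMNIVORY, CYCLIC = 5, 6, 7, 8, 9
IN_2STAR, IN_3STAR, OUT_2STAR, OUT_3STAR = 10, 11, 12, 13
TWO_PATH, TRANSITIVE_RAW, CYCLIC_RAW = 14, 15, 16


@njit(cache=True)
def _pow_table(lams, n):
    """pows[s, c] = (1 - 1/lambda_s)^c for counts c = 0..n."""
    p = len(lams)
    pows = np.empty((p, n + 1))
    for s in range(p):
        r = 1.0 - 1.0 / lams[s]
        pows[s, 0] = 1.0
        for c in range(1, n + 1):
            pows[s, c] = pows[s, c - 1] * r
    return pows


@njit(cache=True)
def delta_vector(A, din, dout, L2, CS, CP, i, j, codes, lams, pows, out):
    """Change statistics for adding arc i -> j; requires A[i, j] == 0.

    ``pows`` is the power table from :func:`_pow_table`; ``L2``/``CS``/``CP``
    must be consistent with ``A``.
    """
    n = A.shape[0]
    for idx in range(len(codes)):
        code = codes[idx]
        lam = lams[idx]
        rp = pows[idx]
        d = 0.0
        if code == ARC:
            d = 1.0
        elif code == RECIPROCITY:
            d = A[j, i]
        elif code == GENERALIST:
            d = lam * (1.0 - rp[din[j]])
        elif code == HIGHLY_PREDATED:
            d = lam * (1.0 - rp[dout[i]])
        elif code == KEYSTONE:
            d = lam * (1.0 - rp[din[i]]) * rp[dout[i]] + rp[din[j]] * lam * (
                1.0 - rp[dout[j]]
            )
        elif code == TRI_TROPHIC:
            for k in range(n):
                if A[k, i] == 1 and k != j:
                    d += rp[L2[k, j]]
            for m in range(n):
                if A[j, m] == 1 and m != i:
                    d += rp[L2[i, m]]
        elif code == APPARENT_COMP:
            for b in range(n):
                if A[b, j] == 1 and b != i:
                    d += rp[CS[i, b]]
        elif code == EXPLOITATIVE_COMP:
            for b in range(n):
                if A[i, b] == 1 and b != j:
                    d += rp[CP[j, b]]
        elif code == OMNIVORY:
            d = lam * (1.0 - rp[L2[i, j]])
            for m in range(n):
                if A[i, m] == 1 and A[j, m] == 1:
                    d += rp[L2[i, m]]
            for k in range(n):
                if A[k, i] == 1 and A[k, j] == 1:
                    d += rp[L2[k, j]]
        elif code == CYCLIC:
            d = lam * (1.0 - rp[L2[j, i]])
            for k in range(n):
                if A[j, k] == 1 and A[k, i] == 1:
                    d += rp[L2[k, j]] + rp[L2[i, k]]
        elif code == IN_2STAR:
            d = float(din[j])
        elif code == IN_3STAR:
            d = din[j] * (din[j] - 1) / 2.0
        elif code == OUT_2STAR:
            d = float(dout[i])
        elif code == OUT_3STAR:
            d = dout[i] * (dout[i] - 1) / 2.0
        elif code == TWO_PATH:
            d = float(din[i] + dout[j] - 2 * A[j, i])
        elif code == TRANSITIVE_RAW:
            d = float(L2[i, j])
            for m in range(n):
                if A[i, m] == 1 and A[j, m] == 1:
                    d += 1.0
            for k in range(n):
                if A[k, i] == 1 and A[k, j] == 1:
                    d += 1.0
        elif code == CYCLIC_RAW:
            d = float(L2[j, i])
        out[idx] = d


@njit(cache=True)
def _apply_toggle(A, din, dout, L2, CS, CP, i, j, sign):
    """Add (sign=+1) or remove (sign=-1) arc i -> j and update all caches.

    For sign=+1, A[i, j] must be 0 on entry; for sign=-1 it must be 1.
    """
    n = A.shape[0]
    A[i, j] = 1 if sign > 0 else 0
    din[j] += sign
    dout[i] += sign
    for b in range(n):
        # arc as first leg of i -> j -> b; as second leg of a -> i -> j
        L2[i, b] += sign * A[j, b]
        L2[b, j] += sign * A[b, i]
        if b != i:
            CS[i, b] += sign * A[b, j]
            CS[b, i] += sign * A[b, j]
        if b != j:
            CP[j, b] += sign * A[i, b]
            CP[b, j] += sign * A[i, b]


@njit(cache=True)
def mh_chain(A, din, dout, z, theta, codes, lams, burn, thinning, n_samples,
             seed, keep_nets):
    """Single-arc-toggle Metropolis-Hastings chain, updated in place.

    Proposes a uniform random ordered dyad and toggles it with probability
    min(1, exp(+/- theta . delta)).  After ``burn`` proposals, records the
    model statistic vector (and optionally the adjacency matrix) every
    ``thinning`` proposals, ``n_samples`` times.

    Returns (stats, nets, accepted, proposals).
    """
    np.random.seed(seed)
    n = A.shape[0]
    p = len(codes)
    pows = _pow_table(lams, n)
    L2 = np.zeros((n, n), dtype=np.int64)
    CS = np.zeros((n, n), dtype=np.int64)
    CP = np.zeros((n, n), dtype=np.int64)
    for a in range(n):
        for b in range(n):
            for t_ in range(n):
                L2[a, b] += A[a, t_] * A[t_, b]
                CS[a, b] += A[a, t_] * A[b, t_]
                CP[a, b] += A[t_, a] * A[t_, b]
    stats = np.empty((n_samples, p), dtype=np.float64)
    if keep_nets:
        nets = np.empty((n_samples, n, n), dtype=np.uint8)
    else:
        nets = np.empty((0, n, n), dtype=np.uint8)
    delta = np.empty(p, dtype=np.float64)
    accepted = 0
    total = burn + thinning * n_samples
    rec = 0
    for t in range(total):
        i = np.random.randint(0, n)
        j = np.random.randint(0, n - 1)
        if j >= i:
            j += 1
        present = A[i, j] == 1
        if present:
            _apply_toggle(A, din, dout, L2, CS, CP, i, j, -1)
        delta_vector(A, din, dout, L2, CS, CP, i, j, codes, lams, pows, delta)
        logr = 0.0
        for s in range(p):
            logr += theta[s] * delta[s]
        if present:
            logr = -logr
        if logr >= 0.0 or np.log(np.random.random()) < logr:
            accepted += 1
            if present:  # removal accepted: stay removed
                for s in range(p):
                    z[s] -= delta[s]
            else:
                _apply_toggle(A, din, dout, L2, CS, CP, i, j, 1)
                for s in range(p):
                    z[s] += delta[s]
        elif present:  # removal rejected: restore the arc
            _apply_toggle(A, din, dout, L2, CS, CP, i, j, 1)
        if t >= burn and (t - burn + 1) % thinning == 0 and rec < n_samples:
            for s in range(p):
                stats[rec, s] = z[s]
            if keep_nets:
                for a in range(n):
                    for b in range(n):
                        nets[rec, a, b] = A[a, b]
            rec += 1
    return stats, nets, accepted, total


@njit(cache=True)
def triad_census_counts(A, code_table):
    """Counts of the 16 triad classes over all unordered node triples."""
    n = A.shape[0]
    counts = np.zeros(16, dtype=np.int64)
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            for k in range(j + 1, n):
                code = (
                    A[i, j]
                    | A[j, i] << 1
                    | A[i, k] << 2
                    | A[k, i] << 3
                    | A[j, k] << 4
                    | A[k, j] << 5
                )
                counts[code_table[code]] += 1
    return counts


@njit(cache=True)
def checkerboard_swaps(A, attempts, seed):
    """Degree-preserving randomisation by directed 2x2 swaps, in place.

    Each attempt picks two arcs (a -> b, c -> d) and rewires to (a -> d,
    c -> b) unless that would create a self-loop or duplicate an arc.
    Preserves both the in- and out-degree sequence exactly.
    """
    np.random.seed(seed)
    n = A.shape[0]
    rows = np.empty(n * n, dtype=np.int64)
    cols = np.empty(n * n, dtype=np.int64)
    L = 0
    for a in range(n):
        for b in range(n):
            if A[a, b] == 1:
                rows[L] = a
                cols[L] = b
                L += 1
    if L < 2:
        return
    for _ in range(attempts):
        e1 = np.random.randint(0, L)
        e2 = np.random.randint(0, L)
        a, b = rows[e1], cols[e1]
        c, d = rows[e2], cols[e2]
        if a == c or b == d or a == d or c == b:
            continue
        if A[a, d] == 1 or A[c, b] == 1:
            continue
        A[a, b] = 0
        A[c, d] = 0
        A[a, d] = 1
        A[c, b] = 1
        cols[e1] = d
        cols[e2] = b
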