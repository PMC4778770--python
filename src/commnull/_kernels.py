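"""Compiled hot loops (numba).

The error sweeps need on the order of 1e9 swap attempts and 1e6 metric
evaluations, so the independent-swap chain, the C-Score, the row-shuffle
maximizer and the site-level nearest-neighbour metric live here as jitted
kernels.  Randomness comes from an inline xorshift64* generator (seeded per
call with a 31-bit seed, mixed through splitmix64), so results are
bit-reproducible for a given seed and fast enough for ~50 ns swap attempts.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_XORSHIFT_MULT = U64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _mix_seed(seed):
    """splitmix64 finalizer: spread a small seed over 64 bits, never zero."""
    z = U64(seed) + U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    z = z ^ (z >> U64(31))
    if z == U64(0):
        z = U64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True, inline="always")
def _rand_u32(state):
    """xorshift64*: advance state[0], return the high 32 bits of the output."""
    s = state[0]
    s ^= s >> U64(12)
    s ^= s << U64(25)
    s ^= s >> U64(27)
    state[0] = s
    return (s * _XORSHIFT_MULT) >> U64(32)


@njit(cache=True, inline="always")
def _rand_below(state, k):
    """Uniform integer in [0, k) via Lemire multiply-shift (k << 2^32)."""
    return np.int64((_rand_u32(state) * U64(k)) >> U64(32))


@njit(cache=True)
def c_score_kernel(occ):
    """Mean checkerboard-unit count (r_i - S)(r_j - S) over species pairs."""
    m, n = occ.shape
    r = np.zeros(m, dtype=np.int64)
    for i in range(m):
        for k in range(n):
            r[i] += occ[i, k]
    total = 0.0
    for i in range(m - 1):
        for j in range(i + 1, m):
            s = 0
            for k in range(n):
                if occ[i, k] == 1 and occ[j, k] == 1:
                    s += 1
            total += (r[i] - s) * (r[j] - s)
    return total / (m * (m - 1) / 2.0)


@njit(cache=True, inline="always")
def _attempt_swaps(occ, m, n, n_attempts, state):
    """``n_attempts`` trial swaps on ``occ`` in place; returns successes.

    Each attempt picks two distinct random rows and columns and exchanges the
    induced 2x2 sub-matrix's diagonal when it is a checkerboard.  Counting
    attempts (self-looping on failures) keeps the chain doubly stochastic, so
    its stationary distribution is uniform over the fixed-margin space;
    counting only successes would weight matrices by their checkerboard count.
    """
    successes = 0
    for _ in range(n_attempts):
        i = _rand_below(state, m)
        j = _rand_below(state, m - 1)
        if j >= i:
            j += 1
        a = _rand_below(state, n)
        b = _rand_below(state, n - 1)
        if b >= a:
            b += 1
        if occ[i, a] != occ[i, b] and occ[i, a] == occ[j, b] and occ[i, b] == occ[j, a]:
            occ[i, a] = 1 - occ[i, a]
            occ[i, b] = 1 - occ[i, b]
            occ[j, a] = 1 - occ[j, a]
            occ[j, b] = 1 - occ[j, b]
            successes += 1
    return successes


@njit(cache=True)
def swap_chain_kernel(occ, n_attempts, seed):
    """Run the independent-swap chain in place; returns successful swap count."""
    state = np.empty(1, dtype=np.uint64)
    state[0] = _mix_seed(seed)
    m, n = occ.shape
    return _attempt_swaps(occ, m, n, n_attempts, state)


@njit(cache=True)
def cscore_null_kernel(occ, n_randomizations, n_attempts, seed):
    """C-Score null distribution from independent restarts of the swap chain.

    Each randomization starts from a fresh copy of the focal matrix.  Returns
    (null_values, zero_success_count, margin_violations); margin_violations
    is a hard internal check and must come back 0.
    """
    state = np.empty(1, dtype=np.uint64)
    state[0] = _mix_seed(seed)
    m, n = occ.shape
    row0 = np.zeros(m, dtype=np.int64)
    col0 = np.zeros(n, dtype=np.int64)
    for i in range(m):
        for k in range(n):
            row0[i] += occ[i, k]
            col0[k] += occ[i, k]
    nulls = np.empty(n_randomizations, dtype=np.float64)
    zero_success = 0
    violations = 0
    work = np.empty_like(occ)
    for t in range(n_randomizations):
        work[:, :] = occ
        if _attempt_swaps(work, m, n, n_attempts, state) == 0:
            zero_success += 1
        for i in range(m):
            rs = 0
            for k in range(n):
                rs += work[i, k]
            if rs != row0[i]:
                violations += 1
        for k in range(n):
            cs = 0
            for i in range(m):
                cs += work[i, k]
            if cs != col0[k]:
                violations += 1
        nulls[t] = c_score_kernel(work)
    return nulls, zero_success, violations


@njit(cache=True)
def fy_maximize_kernel(occ, n_iterations, seed):
    """Hill-climb the C-Score by repeated Fisher-Yates row shuffles.

    Every iteration re-places each species' occurrences uniformly among
    sites (a full Fisher-Yates shuffle of each row preserves row totals but
    not column totals), keeping the arrangement whenever it beats the best
    C-Score so far.  Returns (best_matrix, best_score, improvements).
    """
    state = np.empty(1, dtype=np.uint64)
    state[0] = _mix_seed(seed)
    m, n = occ.shape
    work = occ.copy()
    best = occ.copy()
    best_score = c_score_kernel(occ)
    improvements = 0
    for _ in range(n_iterations):
        for i in range(m):
            for k in range(n - 1, 0, -1):
                j = _rand_below(state, k + 1)
                tmp = work[i, k]
                work[i, k] = work[i, j]
                work[i, j] = tmp
        score = c_score_kernel(work)
        if score > best_score:
            best_score = score
            best[:, :] = work
            improvements += 1
    return best, best_score, improvements


@njit(cache=True)
def nn_metric_kernel(members, offsets, traits, buf):
    """Community NN and SDNN from per-site species membership (CSR layout).

    ``members``/``offsets`` index species present at each site; only sites
    with >= 2 species contribute.  Per site: nearest-neighbour distance of
    each present species to any other present species' trait, site NN = mean
    of those distances, site SDNN = their sample (n-1) standard deviation
    (0 when the site holds exactly two species, whose two distances tie).
    Returns (mean site NN, mean site SDNN, number of contributing sites).
    """
    n_sites = offsets.size - 1
    nn_total = 0.0
    sd_total = 0.0
    defined = 0
    for s in range(n_sites):
        lo = offsets[s]
        hi = offsets[s + 1]
        k = hi - lo
        if k < 2:
            continue
        for t in range(k):
            buf[t] = traits[members[lo + t]]
        # insertion sort: site occupancies are small
        for t in range(1, k):
            v = buf[t]
            u = t - 1
            while u >= 0 and buf[u] > v:
                buf[u + 1] = buf[u]
                u -= 1
            buf[u + 1] = v
        mean = 0.0
        msq = 0.0
        for t in range(k):
            if t == 0:
                d = buf[1] - buf[0]
            elif t == k - 1:
                d = buf[k - 1] - buf[k - 2]
            else:
                left = buf[t] - buf[t - 1]
                right = buf[t + 1] - buf[t]
                d = left if left < right else right
            delta = d - mean
            mean += delta / (t + 1)
            msq += delta * (d - mean)
        nn_total += mean
        sd_total += np.sqrt(msq / (k - 1))
        defined += 1
    if defined == 0:
        return np.nan, np.nan, 0
    return nn_total / defined, sd_total / defined, defined
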