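"""Scaled forward-backward and Viterbi kernels.

Both kernels take a stack of transition matrices ``A`` of shape
(G, S, S) and a per-gap index array mapping gap t (between sites t and
t+1) to a matrix in the stack.  This one signature covers the
homogeneous case (G=1), distance-corrected decoding (one matrix per
unique inter-SNP gap) and the left-to-right model (one matrix per gap).

The forward-backward recursion uses per-site scaling, which is exact
and keeps everything in linear space; emission likelihoods are passed
already rescaled (exp(loglik - rowmax)) with the row offsets added back
into the returned log-likelihood by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e300


@njit(cache=True)
def forward_backward_kernel(pi, A, gap_idx, B):
    """Scaled forward-backward.

    Parameters: pi (S,), A (G,S,S) row-stochastic, gap_idx (n-1,) int,
    B (n,S) nonnegative scaled emission likelihoods.

    Returns (gamma (n,S), xi (n-1,S,S), log_c_sum).  Raises on an
    all-zero emission row (impossible observation).
    """
    n, S = B.shape
    alpha = np.empty((n, S))
    c = np.empty(n)

    for s in range(S):
        alpha[0, s] = pi[s] * B[0, s]
    c0 = alpha[0].sum()
    if c0 <= 0.0:
        raise ValueError("zero emission likelihood at site 0")
    alpha[0] /= c0
    c[0] = c0

    for t in range(1, n):
        a = A[gap_idx[t - 1]]
        for s in range(S):
            acc = 0.0
            for r in range(S):
                acc += alpha[t - 1, r] * a[r, s]
            alpha[t, s] = acc * B[t, s]
        ct = alpha[t].sum()
        if ct <= 0.0:
            raise ValueError("zero emission likelihood at a site")
        alpha[t] /= ct
        c[t] = ct

    beta = np.empty((n, S))
    for s in range(S):
        beta[n - 1, s] = 1.0
    for t in range(n - 2, -1, -1):
        a = A[gap_idx[t]]
        for s in range(S):
            acc = 0.0
            for r in range(S):
                acc += a[s, r] * B[t + 1, r] * beta[t + 1, r]
            beta[t, s] = acc / c[t + 1]

    gamma = alpha * beta
    # normalize defensively against rounding
    for t in range(n):
        g = gamma[t].sum()
        if g > 0.0:
            gamma[t] /= g

    xi = np.empty((n - 1, S, S))
    for t in range(n - 1):
        a = A[gap_idx[t]]
        tot = 0.0
        for r in range(S):
            for s in range(S):
                v = (
                    alpha[t, r]
                    * a[r, s]
                    * B[t + 1, s]
                    * beta[t + 1, s]
                    / c[t + 1]
                )
                xi[t, r, s] = v
                tot += v
        if tot > 0.0:
            for r in range(S):
                for s in range(S):
                    xi[t, r, s] /= tot

    log_c_sum = 0.0
    for t in range(n):
        log_c_sum += np.log(c[t])
    return gamma, xi, log_c_sum


@njit(cache=True)
def viterbi_kernel(log_pi, logA, gap_idx, logB):
    """Max-probability state path; ties resolved toward lower state index.

    Returns (path (n,) int64, best joint log-probability).
    """
    n, S = logB.shape
    delta = np.empty((n, S))
    psi = np.empty((n, S), dtype=np.int64)
    for s in range(S):
        delta[0, s] = log_pi[s] + logB[0, s]
        psi[0, s] = 0
    for t in range(1, n):
        la = logA[gap_idx[t - 1]]
        for s in range(S):
            best = NEG_INF
            arg = 0
            for r in range(S):
                v = delta[t - 1, r] + la[r, s]
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = r
            delta[t, s] = best + logB[t, s]
            psi[t, s] = arg
    best = NEG_INF
    last = 0
    for s in range(S):
        if delta[n - 1, s] > best:
            best = delta[n - 1, s]
            last = s
    path = np.empty(n, dtype=np.int64)
    path[n - 1] = last
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
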