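"""Numerical kernels for the HMM recursions.

Scaled (Rabiner) forward/backward in linear space and Viterbi in log space,
written as explicit loops and JIT-compiled with numba.  If numba is
unavailable the same functions run as pure Python (slow but correct).

``emis`` is the (n_states, n_patterns) emission matrix and ``pat`` the
per-site pattern index, so emissions are computed once per distinct
alignment column rather than once per site.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def forward_ll(pi, trans, emis, pat):
    """Total log-likelihood via the scaled forward recursion."""
    n_sites = pat.shape[0]
    n_states = pi.shape[0]
    alpha = np.empty(n_states)
    nxt = np.empty(n_states)
    ll = 0.0
    for j in range(n_states):
        alpha[j] = pi[j] * emis[j, pat[0]]
    c = alpha.sum()
    if c <= 0.0:
        return -np.inf
    alpha /= c
    ll += np.log(c)
    for t in range(1, n_sites):
        p = pat[t]
        for j in range(n_states):
            acc = 0.0
            for i in range(n_states):
                acc += alpha[i] * trans[i, j]
            nxt[j] = acc * emis[j, p]
        c = nxt.sum()
        if c <= 0.0:
            return -np.inf
        for j in range(n_states):
            alpha[j] = nxt[j] / c
        ll += np.log(c)
    return ll


@njit(cache=True)
def forward_pass(pi, trans, emis, pat):
    """Scaled forward pass keeping the per-site vectors.

    Returns (alpha_hat (L,S), scales (L,), log_likelihood); scales[t] is the
    normaliser of site t, so sum(log(scales)) is the log-likelihood.
    """
    n_sites = pat.shape[0]
    n_states = pi.shape[0]
    alpha = np.empty((n_sites, n_states))
    scales = np.empty(n_sites)
    for j in range(n_states):
        alpha[0, j] = pi[j] * emis[j, pat[0]]
    c = alpha[0].sum()
    scales[0] = c
    if c > 0.0:
        for j in range(n_states):
            alpha[0, j] /= c
    for t in range(1, n_sites):
        p = pat[t]
        for j in range(n_states):
            acc = 0.0
            for i in range(n_states):
                acc += alpha[t - 1, i] * trans[i, j]
            alpha[t, j] = acc * emis[j, p]
        c = alpha[t].sum()
        scales[t] = c
        if c > 0.0:
            for j in range(n_states):
                alpha[t, j] /= c
    ll = 0.0
    for t in range(n_sites):
        if scales[t] <= 0.0:
            return alpha, scales, -np.inf
        ll += np.log(scales[t])
    return alpha, scales, ll


@njit(cache=True)
def backward_pass(trans, emis, pat, scales):
    """Backward vectors scaled with the forward normalisers."""
    n_sites = pat.shape[0]
    n_states = trans.shape[0]
    beta = np.empty((n_sites, n_states))
    for j in range(n_states):
        beta[n_sites - 1, j] = 1.0
    for t in range(n_sites - 2, -1, -1):
        p = pat[t + 1]
        c = scales[t + 1]
        for i in range(n_states):
            acc = 0.0
            for j in range(n_states):
                acc += trans[i, j] * emis[j, p] * beta[t + 1, j]
            beta[t, i] = acc / c
    return beta


@njit(cache=True)
def backward_ll(pi, trans, emis, pat):
    """Total log-likelihood via an independently scaled backward
    recursion (used to cross-check the forward value)."""
    n_sites = pat.shape[0]
    n_states = pi.shape[0]
    beta = np.ones(n_states)
    nxt = np.empty(n_states)
    ll = 0.0
    for t in range(n_sites - 2, -1, -1):
        p = pat[t + 1]
        for i in range(n_states):
            acc = 0.0
            for j in range(n_states):
                acc += trans[i, j] * emis[j, p] * beta[j]
            nxt[i] = acc
        c = nxt.sum() / n_states
        if c <= 0.0:
            return -np.inf
        for i in range(n_states):
            beta[i] = nxt[i] / c
        ll += np.log(c)
    acc = 0.0
    for j in range(n_states):
        acc += pi[j] * emis[j, pat[0]] * beta[j]
    if acc <= 0.0:
        return -np.inf
    return ll + np.log(acc)


@njit(cache=True)
def viterbi_path(log_pi, log_trans, log_emis, pat):
    """Most probable state path; ties break toward the lowest state
    index.  Returns (path, joint log-probability)."""
    n_sites = pat.shape[0]
    n_states = log_pi.shape[0]
    score = np.empty((n_sites, n_states))
    back = np.zeros((n_sites, n_states), dtype=np.int64)
    for j in range(n_states):
        score[0, j] = log_pi[j] + log_emis[j, pat[0]]
    for t in range(1, n_sites):
        p = pat[t]
        for j in range(n_states):
            best = -np.inf
            arg = 0
            for i in range(n_states):
                s = score[t - 1, i] + log_trans[i, j]
                if s > best:
                    best = s
                    arg = i
            score[t, j] = best + log_emis[j, p]
            back[t, j] = arg
    best = -np.inf
    arg = 0
    for j in range(n_states):
        if score[n_sites - 1, j] > best:
            best = score[n_sites - 1, j]
            arg = j
    path = np.empty(n_sites, dtype=np.int64)
    path[n_sites - 1] = arg
    for t in range(n_sites - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, best
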