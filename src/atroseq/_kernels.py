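"""Hot loops for event-sequence likelihood search.

The event-based-model likelihood of a sequence S over n subjects is

    log L(S) = sum_j log[ (1/(N+1)) * sum_{k=0..N}
               prod_{i<=k} p_abn,S(i)(x_j) * prod_{i>k} p_norm,S(i)(x_j) ]

evaluated from precomputed per-subject log-density matrices.  Greedy ascent
and Metropolis MCMC over permutations call this millions of times, so the
kernels are compiled with numba when available; a NumPy reference
implementation with identical semantics is always present and serves both
as fallback and as the oracle the compiled path is tested against.

Both searches memoise the log-likelihood of every transposition neighbour
of the *current* sequence (the cache is invalidated whenever a proposal is
accepted).  Because a rejected proposal leaves the state unchanged, repeat
proposals of the same transposition hit the cache instead of re-evaluating;
the accept/reject trajectory is bit-identical to the uncached computation.

All randomness (chain initialisations, transposition proposals, acceptance
draws) is pre-generated by the caller from a single ``numpy.random.Generator``
so results are identical for a given seed regardless of which path runs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

try:  # pragma: no cover - exercised implicitly by the active path
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

#: density floor applied before taking logs, guarding underflow
DENSITY_FLOOR = 1e-250


def loglik_reference(logN: np.ndarray, logA: np.ndarray, S) -> float:
    """Vectorised reference log-likelihood of sequence ``S``.

    ``logN``/``logA`` are (n_subjects, n_events) log densities under the
    normal/abnormal mixture components, indexed by *event*; ``S`` is the
    event permutation (position -> event index).
    """
    S = np.asarray(S, dtype=np.int64)
    M = logN[:, S]
    B = logA[:, S]
    n, N = M.shape
    # vals[:, k] = sum_{i<=k} logA + sum_{i>k} logN, k = 0..N
    cum = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(B - M, axis=1)], axis=1
    )
    vals = M.sum(axis=1, keepdims=True) + cum
    return float(logsumexp(vals, axis=1).sum() - n * np.log(N + 1))


def _greedy_py(logN, logA, S, pi, pj):
    cur = loglik_reference(logN, logA, S)
    cache = {}
    for t in range(len(pi)):
        i, j = int(pi[t]), int(pj[t])
        key = (i, j) if i < j else (j, i)
        if key in cache:
            new = cache[key]
        else:
            S[i], S[j] = S[j], S[i]
            new = loglik_reference(logN, logA, S)
            S[i], S[j] = S[j], S[i]
            cache[key] = new
        if new > cur:
            S[i], S[j] = S[j], S[i]
            cur = new
            cache = {}
    return cur


def _mcmc_py(logN, logA, S, pi, pj, logu, trace):
    cur = loglik_reference(logN, logA, S)
    best = cur
    bestS = S.copy()
    n_accept = 0
    cache = {}
    for t in range(len(pi)):
        i, j = int(pi[t]), int(pj[t])
        key = (i, j) if i < j else (j, i)
        if key in cache:
            new = cache[key]
        else:
            S[i], S[j] = S[j], S[i]
            new = loglik_reference(logN, logA, S)
            S[i], S[j] = S[j], S[i]
            cache[key] = new
        if logu[t] <= new - cur:
            S[i], S[j] = S[j], S[i]
            cur = new
            n_accept += 1
            cache = {}
            if cur > best:
                best = cur
                bestS[:] = S
        trace[t] = cur
    return best, bestS, n_accept


if HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _loglik_nb(logN, logA, S, work):  # pragma: no cover - compiled
        n, N = logN.shape
        total = 0.0
        for j in range(n):
            acc = 0.0
            for i in range(N):
                acc += logN[j, S[i]]
            work[0] = acc
            vmax = acc
            for k in range(1, N + 1):
                e = S[k - 1]
                acc = acc + logA[j, e] - logN[j, e]
                work[k] = acc
                if acc > vmax:
                    vmax = acc
            ssum = 0.0
            for k in range(N + 1):
                ssum += np.exp(work[k] - vmax)
            total += vmax + np.log(ssum)
        return total - n * np.log(N + 1.0)

    @njit(cache=True)
    def _neighbour_ll(logN, logA, S, i, j, work):  # pragma: no cover
        tmp = S[i]
        S[i] = S[j]
        S[j] = tmp
        val = _loglik_nb(logN, logA, S, work)
        tmp = S[i]
        S[i] = S[j]
        S[j] = tmp
        return val

    @njit(cache=True)
    def _greedy_nb(logN, logA, S, pi, pj, work, cache):  # pragma: no cover
        cur = _loglik_nb(logN, logA, S, work)
        cache[:] = np.nan
        for t in range(pi.shape[0]):
            i = pi[t]
            j = pj[t]
            a, b = (i, j) if i < j else (j, i)
            new = cache[a, b]
            if np.isnan(new):
                new = _neighbour_ll(logN, logA, S, i, j, work)
                cache[a, b] = new
            if new > cur:
                tmp = S[i]
                S[i] = S[j]
                S[j] = tmp
                cur = new
                cache[:] = np.nan
        return cur

    @njit(cache=True)
    def _mcmc_nb(logN, logA, S, pi, pj, logu, trace, bestS, work, cache):  # pragma: no cover
        cur = _loglik_nb(logN, logA, S, work)
        best = cur
        for i in range(S.shape[0]):
            bestS[i] = S[i]
        n_accept = 0
        cache[:] = np.nan
        for t in range(pi.shape[0]):
            i = pi[t]
            j = pj[t]
            a, b = (i, j) if i < j else (j, i)
            new = cache[a, b]
            if np.isnan(new):
                new = _neighbour_ll(logN, logA, S, i, j, work)
                cache[a, b] = new
            if logu[t] <= new - cur:
                tmp = S[i]
                S[i] = S[j]
                S[j] = tmp
                cur = new
                n_accept += 1
                cache[:] = np.nan
                if cur > best:
                    best = cur
                    for q in range(S.shape[0]):
                        bestS[q] = S[q]
            trace[t] = cur
        return best, n_accept


def _prep(logN, logA, S):
    logN = np.ascontiguousarray(logN, dtype=np.float64)
    logA = np.ascontiguousarray(logA, dtype=np.float64)
    S = np.ascontiguousarray(S, dtype=np.int64)
    return logN, logA, S


def log_likelihood(logN, logA, S) -> float:
    """Sequence log-likelihood (compiled path when numba is available)."""
    logN, logA, S = _prep(logN, logA, S)
    if HAVE_NUMBA:
        work = np.empty(logN.shape[1] + 1)
        return float(_loglik_nb(logN, logA, S, work))
    return loglik_reference(logN, logA, S)


def greedy_chain(logN, logA, S, pi, pj) -> float:
    """Run one greedy-ascent chain in place; returns the final log-likelihood.

    ``pi``/``pj`` are pre-drawn transposition position pairs; a proposal is
    accepted only when it strictly increases the likelihood.
    """
    logN, logA, S0 = _prep(logN, logA, S)
    pi = np.ascontiguousarray(pi, dtype=np.int64)
    pj = np.ascontiguousarray(pj, dtype=np.int64)
    N = logN.shape[1]
    if HAVE_NUMBA:
        work = np.empty(N + 1)
        cache = np.empty((N, N))
        ll = float(_greedy_nb(logN, logA, S0, pi, pj, work, cache))
    else:
        ll = _greedy_py(logN, logA, S0, pi, pj)
    S[:] = S0
    return ll


def mcmc_chain(logN, logA, S, pi, pj, logu):
    """Metropolis chain over permutations with transposition proposals.

    Acceptance rule: accept when ``log(u) <= delta_logL`` (so equal-likelihood
    proposals are always accepted).  Returns ``(best_ll, best_S, trace,
    n_accept)`` where ``best_S`` is the highest-likelihood sequence visited.
    """
    logN, logA, S0 = _prep(logN, logA, S)
    pi = np.ascontiguousarray(pi, dtype=np.int64)
    pj = np.ascontiguousarray(pj, dtype=np.int64)
    logu = np.ascontiguousarray(logu, dtype=np.float64)
    trace = np.empty(len(pi))
    N = logN.shape[1]
    if HAVE_NUMBA:
        work = np.empty(N + 1)
        cache = np.empty((N, N))
        bestS = np.empty_like(S0)
        best, n_accept = _mcmc_nb(logN, logA, S0, pi, pj, logu, trace, bestS,
                                  work, cache)
    else:
        best, bestS, n_accept = _mcmc_py(logN, logA, S0, pi, pj, logu, trace)
    return float(best), bestS, trace, int(n_accept)


def transposition_proposals(rng: np.random.Generator, n_events: int, n_iter: int):
    """Uniform-random distinct position pairs for transposition proposals."""
    pi = rng.integers(0, n_events, size=n_iter)
    pj = (pi + 1 + rng.integers(0, n_events - 1, size=n_iter)) % n_events
    return pi.astype(np.int64), pj.astype(np.int64)
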