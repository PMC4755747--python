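"""Compiled trial-loop kernels used by the fitting routines.

The readable reference implementation lives in :mod:`gengrad.core_model`;
these numba kernels compute identical quantities on pre-packed arrays so that
multi-start maximum-likelihood fitting stays fast.  Equality of the two paths
is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _logsig(z):
    # log(1/(1+exp(-z))), stable for any finite z
    if z >= 0.0:
        return -np.log1p(np.exp(-z))
    return z - np.log1p(np.exp(z))


@njit(cache=True)
def _kernels(dist, s_i, s_e, gaussian):
    n = dist.shape[0]
    eS = np.empty((n, n))
    iS = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            d = dist[a, b]
            if gaussian:
                eS[a, b] = np.exp(-(d * d) / (2.0 * s_e * s_e))
                iS[a, b] = np.exp(-(d * d) / (2.0 * s_i * s_i))
            else:
                eS[a, b] = np.exp(-d / (2.0 * s_e * s_e))
                iS[a, b] = np.exp(-d / (2.0 * s_i * s_i))
    return eS, iS


@njit(cache=True)
def loglik_stacked(
    dist,
    gaussian,
    s_i,
    s_e,
    beta,
    a,
    alpha_train,
    alpha_test,
    stim_idx,
    outcome,
    resp_plus,
    use_ll,
    is_train,
    do_update,
    ptr,
):
    """Total log-likelihood over a stacked cohort.

    ``ptr`` delimits subjects in the concatenated per-trial arrays; each
    subject starts from zero associations.  ``use_ll`` marks trials whose
    observed response (``resp_plus``: 1 = "+", 0 = other) contributes a
    likelihood term; all trials with ``do_update`` drive learning.
    """
    n_or = dist.shape[0]
    eS, iS = _kernels(dist, s_i, s_e, gaussian)
    total = 0.0
    for s in range(ptr.size - 1):
        E = np.zeros(n_or)
        I = np.zeros(n_or)
        for t in range(ptr[s], ptr[s + 1]):
            k = stim_idx[t]
            v = 0.0
            for j in range(n_or):
                v += E[j] * eS[j, k] - I[j] * iS[j, k]
            if not np.isfinite(v) or abs(v) > 1e12:
                return -1e15  # runaway dynamics under pathological parameters
            if use_ll[t]:
                z = beta * (v - a)
                if resp_plus[t] == 1:
                    total += _logsig(z)
                else:
                    total += _logsig(-z)
            if do_update[t]:
                alpha = alpha_train if is_train[t] else alpha_test
                d = outcome[t] - v
                if d > 0.0:
                    E[k] += alpha * d
                elif d < 0.0:
                    I[k] -= alpha * d
    return total


@njit(cache=True)
def trace_stacked(
    dist,
    gaussian,
    s_i,
    s_e,
    beta,
    a,
    alpha_train,
    alpha_test,
    stim_idx,
    outcome,
    is_train,
    do_update,
    ptr,
):
    """Per-trial value and choice probability for every stacked trial."""
    n_or = dist.shape[0]
    eS, iS = _kernels(dist, s_i, s_e, gaussian)
    n_tr = stim_idx.size
    V = np.empty(n_tr)
    P = np.empty(n_tr)
    for s in range(ptr.size - 1):
        E = np.zeros(n_or)
        I = np.zeros(n_or)
        for t in range(ptr[s], ptr[s + 1]):
            k = stim_idx[t]
            v = 0.0
            for j in range(n_or):
                v += E[j] * eS[j, k] - I[j] * iS[j, k]
            V[t] = v
            P[t] = np.exp(_logsig(beta * (v - a)))
            if do_update[t]:
                alpha = alpha_train if is_train[t] else alpha_test
                d = outcome[t] - v
                if d > 0.0:
                    E[k] += alpha * d
                elif d < 0.0:
                    I[k] -= alpha * d
    return V, P
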