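"""Minimal C-SVC solver (SMO, linear kernel) for LOOCV permutation testing.

Solves the standard soft-margin SVM dual

    min  0.5 a' Q a - e' a   s.t.  0 <= a <= C,  y' a = 0,   Q_ij = y_i y_j K_ij

by sequential minimal optimization with maximal-violating-pair working-set
selection and an analytic two-variable update, the classic LIBSVM scheme.
The solver works on a precomputed Gram matrix, is deterministic, and is
numba-compiled so that label-permutation tests (hundreds of thousands of
refits on small cohorts) stay cheap.  Agreement with an independent
reference implementation is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["smo_fit", "loocv_decisions", "permuted_loocv_accuracies"]

_TAU = 1e-12


@njit(cache=False)
def smo_fit(K, y, C, eps=1e-4, max_iter=100000):
    """Solve the C-SVC dual on Gram matrix ``K`` with labels y in {-1, +1}.

    Returns (alpha, b); the decision value of a point x is
    ``sum_i alpha_i y_i K(x_i, x) + b``.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of the dual objective, Q a - e
    for _ in range(max_iter):
        # maximal violating pair: i from I_up, j from I_low
        g_max = -1e300
        g_min = 1e300
        i = -1
        j = -1
        for t in range(n):
            v = -y[t] * grad[t]
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                if v > g_max:
                    g_max = v
                    i = t
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                if v < g_min:
                    g_min = v
                    j = t
        if i < 0 or j < 0 or g_max - g_min < eps:
            break
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= _TAU:
            quad = _TAU
        step = (g_max - g_min) / quad
        # direction (d_i, d_j) = (y_i, -y_j) * step keeps y' a = 0;
        # clip the step so both multipliers stay inside [0, C]
        cap_i = (C - alpha[i]) if y[i] > 0.0 else alpha[i]
        cap_j = alpha[j] if y[j] > 0.0 else (C - alpha[j])
        if step > cap_i:
            step = cap_i
        if step > cap_j:
            step = cap_j
        alpha[i] += y[i] * step
        alpha[j] -= y[j] * step
        for s in range(n):
            grad[s] += y[s] * step * (K[s, i] - K[s, j])

    # intercept from the KKT conditions: b = -y_i grad_i on free vectors,
    # otherwise the midpoint of the violating-pair bounds
    b_sum = 0.0
    n_free = 0
    for t in range(n):
        if 0.0 < alpha[t] < C:
            b_sum += -y[t] * grad[t]
            n_free += 1
    if n_free > 0:
        b = b_sum / n_free
    else:
        g_max = -1e300
        g_min = 1e300
        for t in range(n):
            v = -y[t] * grad[t]
            if (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0):
                if v > g_max:
                    g_max = v
            if (y[t] > 0.0 and alpha[t] > 0.0) or (y[t] < 0.0 and alpha[t] < C):
                if v < g_min:
                    g_min = v
        b = (g_max + g_min) / 2.0
    return alpha, b


@njit(cache=False)
def loocv_decisions(K_folds, k_test, y, C):
    """Signed decision value for each held-out subject.

    ``K_folds[f]`` is the training Gram matrix of fold f (subject f held
    out), ``k_test[f]`` the kernel row between the held-out subject and the
    training subjects.  Both depend only on the features, so permutation
    tests reuse them with shuffled labels.
    """
    n = y.shape[0]
    out = np.empty(n)
    y_tr = np.empty(n - 1)
    for f in range(n):
        m = 0
        for s in range(n):
            if s != f:
                y_tr[m] = y[s]
                m += 1
        alpha, b = smo_fit(K_folds[f], y_tr, C)
        dec = b
        for s in range(n - 1):
            dec += alpha[s] * y_tr[s] * k_test[f, s]
        out[f] = dec
    return out


@njit(cache=False)
def permuted_loocv_accuracies(K_folds, k_test, y_perms, C):
    """LOOCV accuracy for each permuted label vector (rows of ``y_perms``)."""
    n_perm = y_perms.shape[0]
    n = y_perms.shape[1]
    acc = np.empty(n_perm)
    for p in range(n_perm):
        dec = loocv_decisions(K_folds, k_test, y_perms[p], C)
        hits = 0
        for s in range(n):
            pred = 1.0 if dec[s] > 0.0 else -1.0
            if pred == y_perms[p, s]:
                hits += 1
        acc[p] = hits / n
    return acc
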