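"""Numba single-site Gibbs kernel for the whole-genome mixture regression.

Kept in its own module so the jitted function stays free of Python-object
state: everything enters as flat numpy arrays and scalars, and the chain
is exactly reproducible from the integer seed (numba's np.random state is
local to the compiled function).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(y, X, Z, pi, n_iter, burn_in, thin,
              nu_a, s_a, nu_e, s_e, seed, locus_specific_var):
    n = y.shape[0]
    p = X.shape[1]
    k = Z.shape[1]
    np.random.seed(seed)

    xx = np.empty(p)
    for t in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, t] * X[i, t]
        xx[t] = acc
    zz = np.empty(k)
    for j in range(k):
        acc = 0.0
        for i in range(n):
            acc += Z[i, j] * Z[i, j]
        zz[j] = acc

    b = np.zeros(p)
    a = np.zeros(k)
    sigma2_j = np.empty(k)
    for j in range(k):
        sigma2_j[j] = nu_a * s_a / np.random.chisquare(nu_a)
    common_var = nu_a * s_a / np.random.chisquare(nu_a)
    sigma2_e = nu_e * s_e / np.random.chisquare(nu_e)
    if sigma2_e <= 0.0:
        sigma2_e = 1.0

    e = y.copy()  # residuals with b = 0, a = 0

    n_states = (n_iter - burn_in) // thin
    saved_a = np.zeros((n_states, k))
    saved_b = np.zeros((n_states, p))
    saved_s2e = np.zeros(n_states)
    s = 0
    odds0 = pi / (1.0 - pi) if pi < 1.0 else np.inf

    for it in range(1, n_iter + 1):
        # fixed effects: normal full conditionals, flat prior
        for t in range(p):
            if xx[t] <= 0.0:
                continue
            r = 0.0
            for i in range(n):
                r += X[i, t] * e[i]
            r += xx[t] * b[t]
            bnew = r / xx[t] + np.random.standard_normal() * np.sqrt(sigma2_e / xx[t])
            diff = b[t] - bnew
            if diff != 0.0:
                for i in range(n):
                    e[i] += X[i, t] * diff
                b[t] = bnew

        # markers: delta from the integrated likelihood ratio, then the
        # effect from its normal full conditional
        for j in range(k):
            if zz[j] <= 0.0:
                a[j] = 0.0
                continue
            aj = a[j]
            r = 0.0
            for i in range(n):
                r += Z[i, j] * e[i]
            r += zz[j] * aj

            if locus_specific_var:
                if aj != 0.0:
                    sigma2_j[j] = (nu_a * s_a + aj * aj) / np.random.chisquare(nu_a + 1.0)
                else:
                    sigma2_j[j] = nu_a * s_a / np.random.chisquare(nu_a)
                s2j = sigma2_j[j]
            else:
                s2j = common_var

            denom = zz[j] * s2j + sigma2_e
            log_ratio = 0.5 * (np.log(sigma2_e / denom) + r * r * s2j / (sigma2_e * denom))
            if np.isinf(odds0):
                prob1 = 0.0
            else:
                prob1 = 1.0 / (1.0 + odds0 * np.exp(-log_ratio))

            if np.random.random() < prob1:
                v = sigma2_e * s2j / denom
                anew = v * r / sigma2_e + np.random.standard_normal() * np.sqrt(v)
            else:
                anew = 0.0
            diff = aj - anew
            if diff != 0.0:
                for i in range(n):
                    e[i] += Z[i, j] * diff
                a[j] = anew

        if not locus_specific_var:
            ssq = 0.0
            m = 0
            for j in range(k):
                if a[j] != 0.0:
                    ssq += a[j] * a[j]
                    m += 1
            common_var = (nu_a * s_a + ssq) / np.random.chisquare(nu_a + m)

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2_e = (sse + nu_e * s_e) / np.random.chisquare(n + nu_e)

        if it > burn_in and (it - burn_in) % thin == 0 and s < n_states:
            for j in range(k):
                saved_a[s, j] = a[j]
            for t in range(p):
                saved_b[s, t] = b[t]
            saved_s2e[s] = sigma2_e
            s += 1

    return saved_b, saved_a, saved_s2e
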