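"""Numba-compiled numerical kernels for the count model.

The likelihood of one species is a forward recursion over weeks: the
log-mean of week j depends on the observed count and the mean of week j-1,
so it cannot be vectorized in j. These kernels keep the recursion cheap
enough for MCMC.
"""

import math

import numpy as np
from numba import njit

#: cap on the log-mean inside the sampler; a larger value means the proposed
#: state is rejected (the public linear_predictor raises instead)
ETA_MAX = 30.0


@njit(cache=True)
def nb_logpmf_scalar(y, lam, theta):
    """log NB(y | mean lam, dispersion theta), gamma-mixture form."""
    return (math.lgamma(y + theta) - math.lgamma(y + 1.0)
            - math.lgamma(theta)
            + y * math.log(lam / (lam + theta))
            + theta * math.log(theta / (lam + theta)))


@njit(cache=True)
def species_forward(y, mask, X, offset, a0, alpha, w, delta, beta, theta,
                    ar_log, lam_out):
    """Log-likelihood of one species' panel; fills lam_out with the means.

    y, mask, offset : (I, J); X : (V, I, J); alpha, w : (V,).
    The week-0 lagged state is y=0 and lam = exp(a0 + offset[i,0]).
    At masked cells (no effort / missing covariate) the cell is skipped in
    the likelihood and the lagged count is imputed by the conditional mean.
    Returns -inf if any log-mean exceeds ETA_MAX (numerical guard).
    """
    I, J = y.shape
    V = X.shape[0]
    ll = 0.0
    for i in range(I):
        lam_prev = math.exp(min(a0 + offset[i, 0], ETA_MAX))
        y_prev = 0.0
        for j in range(J):
            eta = a0 + offset[i, j]
            for v in range(V):
                if w[v] == 1:
                    eta += alpha[v] * X[v, i, j]
            if ar_log:
                eta += delta * math.log(1.0 + y_prev) \
                    + beta * math.log(lam_prev)
            else:
                eta += delta * (1.0 + y_prev) + beta * lam_prev
            if not math.isfinite(eta):
                return -np.inf
            if mask[i, j]:
                if eta > ETA_MAX:
                    return -np.inf
                lam = math.exp(eta)
                lam_out[i, j] = lam
                ll += nb_logpmf_scalar(y[i, j], lam, theta)
                y_prev = y[i, j]
            else:
                # cell outside the likelihood: clamp rather than reject so
                # the guard never truncates the prior
                lam = math.exp(min(eta, ETA_MAX))
                lam_out[i, j] = lam
                y_prev = lam
            lam_prev = lam
    return ll


@njit(cache=True)
def species_loglik(y, mask, X, offset, a0, alpha, w, delta, beta, theta,
                   ar_log):
    lam_out = np.empty_like(offset)
    return species_forward(y, mask, X, offset, a0, alpha, w, delta, beta,
                           theta, ar_log, lam_out)


@njit(cache=True)
def freeman_tukey(y, lam, mask):
    d = 0.0
    I, J = y.shape
    for i in range(I):
        for j in range(J):
            if mask[i, j]:
                r = math.sqrt(y[i, j]) - math.sqrt(lam[i, j])
                d += r * r
    return d


@njit(cache=True)
def chi_square(y, lam, mask, theta):
    d = 0.0
    I, J = y.shape
    for i in range(I):
        for j in range(J):
            if mask[i, j]:
                var = lam[i, j] + lam[i, j] * lam[i, j] / theta
                r = y[i, j] - lam[i, j]
                d += r * r / var
    return d
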