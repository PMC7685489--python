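"""Adaptive Metropolis-within-Gibbs sampler for VisitCountModel.

Continuous parameters get scalar random-walk Metropolis steps whose proposal
scales adapt toward a 0.44 acceptance rate during burn-in (Robbins–Monro on
the log scale, frozen afterwards so the post-burn-in chain is a genuine
Markov chain). Inclusion indicators w[v,k] are drawn exactly from their
Bernoulli full conditionals (Kuo–Mallick): the slope of an excluded
covariate is refreshed from its hierarchical prior, so the indicator's full
conditional is available in closed form. Slope-pool means μ_v are conjugate
Gibbs draws. All randomness flows through one numpy Generator per chain, so
a fixed seed reproduces draws bit for bit.
"""

from __future__ import annotations

import math

import numpy as np

from .model import ParamState, VisitCountModel

ACC_TARGET = 0.44
#: bound on log(sigma_v) and log(theta) proposals; a numerical truncation at
#: e^±40 that keeps the chain away from under/overflow
LOG_SCALE_BOUND = 40.0


def _adapt_step(t: int) -> float:
    return min(0.2, 2.0 / math.sqrt(t + 20.0))


def _init_state(model: VisitCountModel, rng, start: ParamState | None,
                shrink: float = 1.0) -> ParamState:
    K, V = model.K, model.V
    if start is not None:
        st = start.copy()
        if st.mu is None:
            st.mu = np.zeros(V)
        if st.sigma is None:
            st.sigma = np.ones(V)
        return st
    if model.mask.any():
        mean_off = float(model.offset[model.mask].mean())
        ybar = np.array([model.y[k][model.mask].mean()
                         for k in range(K)])
    else:
        mean_off, ybar = 0.0, np.ones(K)
    a0 = np.log(ybar + 0.1) - mean_off \
        + shrink * rng.normal(0.0, 0.5, size=K)
    alpha = shrink * rng.normal(0.0, 0.1, size=(V, K))
    alpha[~model.candidate] = 0.0
    w = ((rng.random((V, K)) < model.priors.inclusion_prob)
         & model.candidate).astype(np.int8)
    delta = shrink * rng.normal(0.0, 0.05, size=K)
    beta = shrink * rng.normal(0.0, 0.05, size=K)
    if model.theta_per_species:
        theta = np.exp(rng.normal(0.0, 0.5 * shrink, size=K))
    else:
        theta = float(np.exp(rng.normal(0.0, 0.5 * shrink)))
    return ParamState(a0, alpha, w, delta, beta, theta,
                      mu=np.zeros(V), sigma=np.ones(V))


def run_chain(model: VisitCountModel, draws: int, burn: int, thin: int,
              rng: np.random.Generator,
              start: ParamState | None = None) -> dict:
    pri = model.priors
    K, V = model.K, model.V
    p_incl = pri.inclusion_prob
    prior_logodds = math.log(p_incl / (1.0 - p_incl))

    state = None
    for attempt in range(25):
        cand_state = _init_state(model, rng, start,
                                 shrink=0.5 ** attempt if start is None
                                 else 1.0)
        ll = np.array([model._species_loglik(cand_state, k)
                       for k in range(K)])
        if np.all(np.isfinite(ll)):
            state = cand_state
            break
    if state is None:
        raise RuntimeError("could not find a starting state with finite "
                           "posterior; check the data scale and priors")

    cand_v = [np.flatnonzero(model.candidate[:, k]) for k in range(K)]
    cand_k = [np.flatnonzero(model.candidate[v, :]) for v in range(V)]

    # adaptive proposal log-scales
    ls_a0 = np.full(K, math.log(0.1))
    ls_alpha = np.full((V, K), math.log(0.1))
    ls_delta = np.full(K, math.log(0.1))
    ls_beta = np.full(K, math.log(0.1))
    ls_sigma = np.full(V, math.log(0.3))
    ls_theta = np.full(K if model.theta_per_species else 1, math.log(0.3))

    n_keep = draws
    out = {
        "alpha0": np.empty((n_keep, K)),
        "alpha": np.empty((n_keep, V, K)),
        "w": np.empty((n_keep, V, K), dtype=np.int8),
        "delta": np.empty((n_keep, K)),
        "beta": np.empty((n_keep, K)),
        "theta": np.empty((n_keep, K) if model.theta_per_species
                          else n_keep),
        "mu": np.empty((n_keep, V)),
        "sigma": np.empty((n_keep, V)),
    }

    n_total = burn + draws * thin
    kept = 0
    for t in range(n_total):
        adapting = t < burn
        step = _adapt_step(t) if adapting else 0.0

        for k in range(K):
            # intercept
            prop = state.alpha0[k] + math.exp(ls_a0[k]) * rng.standard_normal()
            llp = model._species_loglik(state, k, alpha0=prop)
            la = llp - ll[k] + (state.alpha0[k] ** 2 - prop ** 2) \
                / (2.0 * pri.intercept_sd ** 2)
            acc = math.log(rng.random()) < la
            if acc:
                state.alpha0[k] = prop
                ll[k] = llp
            if adapting:
                ls_a0[k] += step * ((1.0 if acc else 0.0) - ACC_TARGET)

            # inclusion indicators: exact Bernoulli full conditionals
            for v in cand_v[k]:
                w_alt = state.w[:, k].copy()
                w_alt[v] = 1 - w_alt[v]
                ll_alt = model._species_loglik(state, k, w=w_alt)
                if w_alt[v] == 1:
                    l1, l0 = ll_alt, ll[k]
                else:
                    l1, l0 = ll[k], ll_alt
                logodds = l1 - l0 + prior_logodds
                p1 = 1.0 / (1.0 + math.exp(-min(max(logodds, -700.0),
                                                700.0)))
                new_w = 1 if rng.random() < p1 else 0
                if new_w != state.w[v, k]:
                    state.w[v, k] = new_w
                    ll[k] = ll_alt

            # slopes: prior refresh when excluded, RW-MH when included
            for v in cand_v[k]:
                if state.w[v, k] == 0:
                    state.alpha[v, k] = state.mu[v] \
                        + state.sigma[v] * rng.standard_normal()
                    continue
                prop = state.alpha[v, k] \
                    + math.exp(ls_alpha[v, k]) * rng.standard_normal()
                avec = state.alpha[:, k].copy()
                avec[v] = prop
                llp = model._species_loglik(state, k, alpha=avec)
                la = llp - ll[k] \
                    + ((state.alpha[v, k] - state.mu[v]) ** 2
                       - (prop - state.mu[v]) ** 2) \
                    / (2.0 * state.sigma[v] ** 2)
                acc = math.log(rng.random()) < la
                if acc:
                    state.alpha[v, k] = prop
                    ll[k] = llp
                if adapting:
                    ls_alpha[v, k] += step * ((1.0 if acc else 0.0)
                                              - ACC_TARGET)

            # AR coefficients
            for name, arr, ls in (("delta", state.delta, ls_delta),
                                  ("beta", state.beta, ls_beta)):
                prop = arr[k] + math.exp(ls[k]) * rng.standard_normal()
                llp = model._species_loglik(state, k, **{name: prop})
                la = llp - ll[k] + (arr[k] ** 2 - prop ** 2) \
                    / (2.0 * pri.ar_sd ** 2)
                acc = math.log(rng.random()) < la
                if acc:
                    arr[k] = prop
                    ll[k] = llp
                if adapting:
                    ls[k] += step * ((1.0 if acc else 0.0) - ACC_TARGET)

        # slope-pool hyperparameters
        for v in range(V):
            ks = cand_k[v]
            if len(ks) == 0:
                continue
            mlen = len(ks)
            sig2 = state.sigma[v] ** 2
            prec = 1.0 / pri.intercept_sd ** 2 + mlen / sig2
            mean = (state.alpha[v, ks].sum() / sig2) / prec
            state.mu[v] = mean + rng.standard_normal() / math.sqrt(prec)

            x = math.log(state.sigma[v])
            propx = x + math.exp(ls_sigma[v]) * rng.standard_normal()
            ssq = float(((state.alpha[v, ks] - state.mu[v]) ** 2).sum())
            c2 = pri.slope_sigma_scale ** 2

            def _logp_sigma(xx):
                s2 = math.exp(2.0 * xx)
                return -0.5 * ssq / s2 - mlen * xx - s2 / (2.0 * c2) + xx

            acc = (abs(propx) < LOG_SCALE_BOUND
                   and math.log(rng.random())
                   < _logp_sigma(propx) - _logp_sigma(x))
            if acc:
                state.sigma[v] = math.exp(propx)
            if adapting:
                ls_sigma[v] += step * ((1.0 if acc else 0.0) - ACC_TARGET)

        # dispersion: one shared value, or one per species
        if model.theta_per_species:
            for k in range(K):
                x = math.log(state.theta[k])
                propx = x + math.exp(ls_theta[k]) * rng.standard_normal()
                theta_p = math.exp(propx)
                llp_k = model._species_loglik(state, k, theta=theta_p)
                la = llp_k - ll[k] \
                    + (pri.theta_shape * propx - pri.theta_rate * theta_p) \
                    - (pri.theta_shape * x
                       - pri.theta_rate * state.theta[k])
                acc = (abs(propx) < LOG_SCALE_BOUND
                       and math.log(rng.random()) < la)
                if acc:
                    state.theta[k] = theta_p
                    ll[k] = llp_k
                if adapting:
                    ls_theta[k] += step * ((1.0 if acc else 0.0)
                                           - ACC_TARGET)
        else:
            x = math.log(state.theta)
            propx = x + math.exp(ls_theta[0]) * rng.standard_normal()
            theta_p = math.exp(propx)
            llp = np.array([model._species_loglik(state, k, theta=theta_p)
                            for k in range(K)])
            la = float(llp.sum() - ll.sum()) \
                + (pri.theta_shape * propx - pri.theta_rate * theta_p) \
                - (pri.theta_shape * x - pri.theta_rate * state.theta)
            acc = (abs(propx) < LOG_SCALE_BOUND
                   and math.log(rng.random()) < la)
            if acc:
                state.theta = theta_p
                ll = llp
            if adapting:
                ls_theta[0] += step * ((1.0 if acc else 0.0) - ACC_TARGET)

        if t >= burn and (t - burn) % thin == 0 and kept < n_keep:
            out["alpha0"][kept] = state.alpha0
            out["alpha"][kept] = state.alpha
            out["w"][kept] = state.w
            out["delta"][kept] = state.delta
            out["beta"][kept] = state.beta
            out["theta"][kept] = state.theta
            out["mu"][kept] = state.mu
            out["sigma"][kept] = state.sigma
            kept += 1
    return out
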