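"""Hierarchical multi-species negative-binomial autoregressive count model.

Weekly visit counts y[i,j,k] (location i, week j, species k) are modelled as
negative binomial — a Poisson whose mean is multiplied by a gamma(θ, θ)
deviate, so the marginal pmf is

    P(y | λ, θ) = Γ(y+θ) / (Γ(y+1) Γ(θ)) · (λ/(λ+θ))^y · (θ/(λ+θ))^θ

with variance λ + λ²/θ; θ → ∞ recovers the Poisson. The log mean follows an
observation-driven autoregression with a camera-effort offset:

    log λ[i,j,k] = α0[k] + Σ_v w[v,k] α[v,k] X[v,i,j]
                   + δ[k] g(1 + y[i,j-1,k]) + β[k] h(λ[i,j-1,k])
                   + log(camera-days[i,j])

where δ captures short-term dependence on the previous week's count and β
long-term dependence through the lagged mean. The default transform is
g = h = log (``ar_form="log"``); ``ar_form="linear"`` uses the identity.
w[v,k] ∈ {0,1} are Bernoulli(0.5) inclusion indicators (Kuo–Mallick
spike-and-slab); a covariate whose posterior inclusion probability exceeds
0.70 is flagged as highly supported. Slopes pool across species,
α[v,k] ~ Normal(μ_v, σ_v²), which is how auxiliary species sharpen the
variance estimation for the focal ones. Dispersion θ is shared across
locations (and, by default, species).

Fitting is by MCMC: adaptive random-walk Metropolis for the continuous
parameters, exact Bernoulli full-conditional draws for the indicators, and
Gibbs for the slope-pool means. ``VisitCountModel.fit`` returns a
:class:`VisitCountResults` with draws, Gelman–Rubin diagnostics, inclusion
probabilities, posterior-predictive Bayesian p-values and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._kernels import (chi_square, freeman_tukey, species_forward,
                       species_loglik)

WEATHER_COVARIATES = ("TMAX", "RH", "P1", "P6")


def nb_logpmf(y, lam, theta):
    """Log-pmf of the negative binomial in (mean λ, dispersion θ) form.

    Vectorized and numerically stable via log-gamma. θ → ∞ converges to the
    Poisson log-pmf.
    """
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(lam))
            and np.all(np.isfinite(theta))):
        raise ValueError("nb_logpmf requires finite inputs")
    if np.any(lam <= 0) or np.any(theta <= 0):
        raise ValueError("nb_logpmf requires lam > 0 and theta > 0")
    return (gammaln(y + theta) - gammaln(y + 1.0) - gammaln(theta)
            + y * np.log(lam / (lam + theta))
            + theta * np.log(theta / (lam + theta)))


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is (m, n): m ≥ 2 chains of n post-burn-in draws each.
    R̂ = sqrt(V̂ / W) with V̂ = (n-1)/n · W + (1 + 1/m) · B/n, where W is the
    mean within-chain variance and B/n the variance of the chain means.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("gelman_rubin requires >= 2 chains of equal length")
    m, n = x.shape
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        return 1.0
    vhat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(vhat / W))


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative default priors; all configurable."""

    intercept_sd: float = 10.0        # α0[k], μ_v ~ Normal(0, sd²)
    slope_sigma_scale: float = 1.0    # σ_v ~ Half-Normal(scale)
    ar_sd: float = 1.0                # δ[k], β[k] ~ Normal(0, sd²)
    theta_shape: float = 0.01         # θ ~ Gamma(shape, rate)
    theta_rate: float = 0.01
    inclusion_prob: float = 0.5       # Pr(w[v,k] = 1) a priori


@dataclass
class ParamState:
    """One point in parameter space (one MCMC state or a truth bundle)."""

    alpha0: np.ndarray          # (K,)
    alpha: np.ndarray           # (V, K)
    w: np.ndarray               # (V, K) in {0, 1}
    delta: np.ndarray           # (K,)
    beta: np.ndarray            # (K,)
    theta: float | np.ndarray   # scalar (shared) or (K,) per species
    mu: np.ndarray | None = None     # (V,) slope-pool means
    sigma: np.ndarray | None = None  # (V,) slope-pool SDs

    def theta_for(self, k: int) -> float:
        arr = np.asarray(self.theta, dtype=float)
        return float(arr) if arr.ndim == 0 else float(arr[k])

    def copy(self) -> "ParamState":
        theta = self.theta
        theta = float(theta) if np.ndim(theta) == 0 else np.array(theta)
        return ParamState(self.alpha0.copy(), self.alpha.copy(),
                          self.w.copy(), self.delta.copy(), self.beta.copy(),
                          theta,
                          None if self.mu is None else self.mu.copy(),
                          None if self.sigma is None else self.sigma.copy())


class VisitCountModel:
    """Negative-binomial AR(1) visitation model for a multi-species panel.

    Parameters
    ----------
    y : (K, I, J) array of non-negative counts
    offset : (I, J) array, log camera-days (finite wherever mask is True)
    X : (V, I, J) array of standardized covariates, or None
    mask : (I, J) bool, cells entering the likelihood; default: offset finite
    species, covariates : labels
    candidate : (V, K) bool, which covariates are candidates for which
        species (prey-count covariates enter predator models only);
        default all True
    ar_form : "log" (default) or "linear" lagged-term transform
    theta_per_species : fit one dispersion per species instead of a single
        shared value (default shared across locations and species)
    priors : PriorConfig
    """

    def __init__(self, y, offset, X=None, mask=None, species=None,
                 covariates=None, candidate=None, ar_form="log",
                 theta_per_species: bool = False,
                 priors: PriorConfig | None = None):
        y = np.asarray(y, dtype=float)
        if y.ndim != 3:
            raise ValueError("y must be (K, I, J)")
        K, I, J = y.shape
        offset = np.asarray(offset, dtype=float)
        if offset.shape != (I, J):
            raise ValueError("offset must be (I, J)")
        if X is None:
            X = np.zeros((0, I, J))
        X = np.asarray(X, dtype=float)
        V = X.shape[0]
        if mask is None:
            mask = np.isfinite(offset)
        self.y = y
        self.offset = np.where(np.asarray(mask, bool), offset, 0.0)
        self.X = np.where(np.isfinite(X), X, 0.0)
        self.mask = np.asarray(mask, dtype=bool)
        self.nobs = int(self.mask.sum()) * K
        self.species = list(species) if species is not None else \
            [f"sp{k}" for k in range(K)]
        self.covariates = list(covariates) if covariates is not None else \
            [f"x{v}" for v in range(V)]
        if candidate is None:
            candidate = np.ones((V, K), dtype=bool)
        self.candidate = np.asarray(candidate, dtype=bool)
        if self.candidate.shape != (V, K):
            raise ValueError("candidate must be (V, K)")
        if ar_form not in ("log", "linear"):
            raise ValueError("ar_form must be 'log' or 'linear'")
        self.ar_form = ar_form
        self.theta_per_species = bool(theta_per_species)
        self.priors = priors or PriorConfig()
        self.K, self.I, self.J, self.V = K, I, J, V
        # populated by from_design for back-transformation / reporting
        self.covariate_scale: dict[str, tuple[float, float]] = {}
        self.locations: list = list(range(I))

    # ------------------------------------------------------------------ #
    @classmethod
    def from_design(cls, design: pd.DataFrame, species=None,
                    covariates=WEATHER_COVARIATES, prey_covariates=None,
                    ar_form="log", priors=None):
        """Build the model from a long design table.

        ``design`` has one row per (location, week, species) with columns
        ``location, week, species, y, camera_days`` plus unstandardized
        covariate columns (constant across species within a location-week).
        Covariates are standardized here, over exactly the cells entering
        the likelihood. ``prey_covariates`` maps a predator species to a
        list of prey species whose same-week standardized counts enter that
        predator's linear predictor as candidate covariates.
        """
        df = design.copy()
        if species is None:
            species = sorted(df["species"].unique())
        species = list(species)
        df = df[df["species"].isin(species)]
        locations = sorted(df["location"].unique())
        weeks = np.arange(df["week"].min(), df["week"].max() + 1)
        I, J, K = len(locations), len(weeks), len(species)
        loc_ix = {l: i for i, l in enumerate(locations)}
        wk_ix = {w: j for j, w in enumerate(weeks)}
        sp_ix = {s: k for k, s in enumerate(species)}

        y = np.zeros((K, I, J))
        has_y = np.zeros((K, I, J), dtype=bool)
        cdays = np.full((I, J), np.nan)
        covariates = list(covariates)
        Xraw = np.full((len(covariates), I, J), np.nan)
        for row in df.itertuples(index=False):
            i, j = loc_ix[row.location], wk_ix[row.week]
            k = sp_ix[row.species]
            y[k, i, j] = row.y
            has_y[k, i, j] = True
            cdays[i, j] = row.camera_days
            for v, name in enumerate(covariates):
                Xraw[v, i, j] = getattr(row, name)

        mask = (has_y.all(axis=0) & np.isfinite(cdays) & (cdays > 0)
                & np.all(np.isfinite(Xraw), axis=0))
        offset = np.where(mask, np.log(np.where(mask, cdays, 1.0)), 0.0)

        names = covariates.copy()
        candidate_cols = [np.ones(K, dtype=bool) for _ in covariates]
        if prey_covariates:
            prey_all = sorted({p for ps in prey_covariates.values()
                               for p in ps})
            for prey in prey_all:
                col = y[sp_ix[prey]].copy()
                Xraw = np.concatenate([Xraw, col[None]], axis=0)
                names.append(f"prey:{prey}")
                cand = np.zeros(K, dtype=bool)
                for pred, ps in prey_covariates.items():
                    if prey in ps:
                        cand[sp_ix[pred]] = True
                candidate_cols.append(cand)

        scale: dict[str, tuple[float, float]] = {}
        Xstd = np.zeros_like(Xraw)
        for v, name in enumerate(names):
            vals = Xraw[v][mask]
            m, s = float(vals.mean()), float(vals.std(ddof=1))
            if s == 0.0:
                raise ValueError(f"covariate {name!r} is constant over the "
                                 "fitted cells; cannot standardize")
            Xstd[v][mask] = (Xraw[v][mask] - m) / s
            scale[name] = (m, s)

        model = cls(y, offset, X=Xstd, mask=mask, species=species,
                    covariates=names,
                    candidate=np.column_stack(candidate_cols).T
                    if candidate_cols else None,
                    ar_form=ar_form, priors=priors)
        model.covariate_scale = scale
        model.locations = locations
        return model

    # ------------------------------------------------------------------ #
    def _species_loglik(self, params: ParamState, k: int, *, w=None,
                        alpha0=None, alpha=None, delta=None, beta=None,
                        theta=None) -> float:
        return species_loglik(
            self.y[k], self.mask, self.X, self.offset,
            float(params.alpha0[k] if alpha0 is None else alpha0),
            np.ascontiguousarray(params.alpha[:, k] if alpha is None
                                 else alpha),
            np.ascontiguousarray((params.w[:, k] if w is None else w)
                                 .astype(np.int8)),
            float(params.delta[k] if delta is None else delta),
            float(params.beta[k] if beta is None else beta),
            params.theta_for(k) if theta is None else float(theta),
            self.ar_form == "log")

    def loglike(self, params: ParamState) -> float:
        """Total log-likelihood over all species and unmasked cells."""
        return float(sum(self._species_loglik(params, k)
                         for k in range(self.K)))

    def linear_predictor(self, params: ParamState) -> np.ndarray:
        """Conditional means λ[k,i,j] from the forward recursion.

        Raises OverflowError naming the first offending cell if the log-mean
        exceeds the numerical cap (check parameter scales / priors).
        """
        lam = np.empty((self.K, self.I, self.J))
        for k in range(self.K):
            out = np.empty((self.I, self.J))
            ll = species_forward(
                self.y[k], self.mask, self.X, self.offset,
                float(params.alpha0[k]),
                np.ascontiguousarray(params.alpha[:, k]),
                np.ascontiguousarray(params.w[:, k].astype(np.int8)),
                float(params.delta[k]), float(params.beta[k]),
                params.theta_for(k), self.ar_form == "log", out)
            if not np.isfinite(ll):
                bad = np.argwhere(~np.isfinite(out) | (out <= 0))
                cell = tuple(bad[0]) if len(bad) else (0, 0)
                raise OverflowError(
                    f"log-mean overflow for species {self.species[k]!r} at "
                    f"(location {cell[0]}, week {cell[1]}); check parameter "
                    "scales or priors")
            lam[k] = out
        return lam

    # ------------------------------------------------------------------ #
    def fit(self, draws=4000, burn=1000, chains=4, thin=1, seed=0,
            start: ParamState | None = None) -> "VisitCountResults":
        """Sample the posterior by MCMC.

        ``draws`` kept iterations per chain after ``burn`` discarded ones
        (thinning applied to the kept stretch). Production-scale analyses
        use 4 chains × 150,000 iterations with 50,000 burn-in; the
        desk-scale preset is 4 × 6,000 with 1,000 burn-in. Fixed seed gives
        bit-identical draws.
        """
        from ._sampler import run_chain
        seeds = np.random.SeedSequence(seed).spawn(chains)
        chain_draws = []
        for c in range(chains):
            rng = np.random.default_rng(seeds[c])
            chain_draws.append(run_chain(self, draws, burn, thin, rng,
                                         start=start))
        stacked = {name: np.stack([cd[name] for cd in chain_draws])
                   for name in chain_draws[0]}
        return VisitCountResults(self, stacked, seed=seed, n_draws=draws,
                                 n_burn=burn, thin=thin)


class VisitCountResults:
    """Posterior draws plus diagnostics for a fitted VisitCountModel.

    ``draws`` maps parameter names to arrays of shape (chains, n, ...):
    ``alpha0`` (K,), ``alpha`` (V, K), ``w`` (V, K), ``delta`` (K,),
    ``beta`` (K,), ``theta`` (), ``mu`` (V,), ``sigma`` (V,).
    """

    def __init__(self, model: VisitCountModel, draws: dict, seed: int,
                 n_draws: int, n_burn: int, thin: int):
        self.model = model
        self.draws = draws
        self.seed = seed
        self.n_draws = n_draws
        self.n_burn = n_burn
        self.thin = thin

    # -- basic posterior summaries ------------------------------------- #
    def _flat(self, name: str) -> np.ndarray:
        """(chains*n, ...) pooled draws for one parameter."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def posterior_mean(self, name: str) -> np.ndarray:
        return self._flat(name).mean(axis=0)

    def ci(self, name: str, level: float = 0.95) -> np.ndarray:
        """Equal-tailed credible interval; shape (2, ...param shape)."""
        q = (1 - level) / 2
        return np.quantile(self._flat(name), [q, 1 - q], axis=0)

    # -- diagnostics ----------------------------------------------------- #
    def _scalar_items(self, include_w=False):
        m = self.model
        labels = []
        for k, sp in enumerate(m.species):
            labels.append((f"alpha0[{sp}]", "alpha0", (k,)))
        for v, cv in enumerate(m.covariates):
            for k, sp in enumerate(m.species):
                if m.candidate[v, k]:
                    labels.append((f"alpha[{cv},{sp}]", "alpha", (v, k)))
                    if include_w:
                        labels.append((f"w[{cv},{sp}]", "w", (v, k)))
        for k, sp in enumerate(m.species):
            labels.append((f"delta[{sp}]", "delta", (k,)))
            labels.append((f"beta[{sp}]", "beta", (k,)))
        if self.draws["theta"].ndim == 3:  # per-species dispersion
            for k, sp in enumerate(m.species):
                labels.append((f"theta[{sp}]", "theta", (k,)))
        else:
            labels.append(("theta", "theta", ()))
        for v, cv in enumerate(m.covariates):
            labels.append((f"mu[{cv}]", "mu", (v,)))
            labels.append((f"sigma[{cv}]", "sigma", (v,)))
        return labels

    def rhat(self) -> pd.Series:
        """Gelman–Rubin R̂ for every continuous scalar parameter."""
        out = {}
        for label, name, idx in self._scalar_items():
            x = self.draws[name][(slice(None), slice(None)) + idx]
            out[label] = gelman_rubin(x)
        return pd.Series(out, name="rhat")

    def inclusion_probabilities(self, threshold: float = 0.70) -> pd.DataFrame:
        """Posterior Pr(w=1) per candidate covariate × species.

        ``retained`` is strict: Pr > threshold (0.70 by default); a
        probability of exactly 0.70 is not retained.
        """
        m = self.model
        w = self._flat("w")  # (n, V, K)
        rows = []
        for v, cv in enumerate(m.covariates):
            for k, sp in enumerate(m.species):
                if m.candidate[v, k]:
                    p = float(w[:, v, k].mean())
                    rows.append({"covariate": cv, "species": sp,
                                 "inclusion_prob": p,
                                 "retained": p > threshold})
        return pd.DataFrame(rows)

    def bayesian_pvalue(self, discrepancy: str = "freeman-tukey",
                        n_samples: int = 200, seed: int = 0) -> float:
        """Posterior-predictive Bayesian p-value P_D.

        For a thinned subset of draws, replicate data y* are simulated from
        the fitted negative binomial at the draw's conditional means, and
        P_D is the fraction of draws where D(y*, λ) > D(y, λ). Values near
        0.5 indicate adequate fit; near 0 or 1, lack of fit. The default
        discrepancy is Freeman–Tukey, Σ(√y − √λ)²; "chi-square" uses
        Σ(y − λ)²/(λ + λ²/θ).
        """
        if discrepancy not in ("freeman-tukey", "chi-square"):
            raise ValueError(f"unknown discrepancy {discrepancy!r}")
        m = self.model
        flat = {k: self._flat(k) for k in
                ("alpha0", "alpha", "w", "delta", "beta", "theta")}
        n_total = flat["theta"].shape[0]
        idx = np.unique(np.linspace(0, n_total - 1,
                                    min(n_samples, n_total)).astype(int))
        rng = np.random.default_rng(seed)
        mask = m.mask
        exceed = 0
        for t in idx:
            theta_t = flat["theta"][t]
            theta_t = float(theta_t) if np.ndim(theta_t) == 0 else theta_t
            params = ParamState(flat["alpha0"][t], flat["alpha"][t],
                                flat["w"][t], flat["delta"][t],
                                flat["beta"][t], theta_t)
            d_obs = d_rep = 0.0
            lam = self.model.linear_predictor(params)
            for k in range(m.K):
                theta = params.theta_for(k)
                lk = np.where(mask, lam[k], 1.0)
                yrep = rng.negative_binomial(theta, theta / (theta + lk))
                if discrepancy == "freeman-tukey":
                    d_obs += freeman_tukey(m.y[k], lk, mask)
                    d_rep += freeman_tukey(yrep.astype(float), lk, mask)
                else:
                    d_obs += chi_square(m.y[k], lk, mask, theta)
                    d_rep += chi_square(yrep.astype(float), lk, mask, theta)
            if d_rep > d_obs:
                exceed += 1
        return exceed / len(idx)

    # -- presentation ---------------------------------------------------- #
    def params_frame(self) -> pd.DataFrame:
        rows = []
        rhats = self.rhat()
        for label, name, idx in self._scalar_items():
            x = self._flat(name)[(slice(None),) + idx]
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append({"parameter": label, "mean": x.mean(),
                         "sd": x.std(ddof=1), "ci2.5": lo, "ci97.5": hi,
                         "rhat": rhats[label]})
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self) -> str:
        m = self.model
        lines = [
            "Negative-binomial AR(1) visitation model",
            f"  species: {', '.join(m.species)}",
            f"  covariates: {', '.join(m.covariates) or '(none)'}",
            f"  panel: {m.I} locations x {m.J} weeks "
            f"({int(m.mask.sum())} cells per species in likelihood)",
            f"  chains: {self.draws['theta'].shape[0]}, kept draws/chain: "
            f"{self.draws['theta'].shape[1]}, ar_form: {m.ar_form}",
            "",
            self.params_frame().round(4).to_string(),
        ]
        inc = self.inclusion_probabilities()
        if len(inc):
            lines += ["", "Inclusion probabilities (retained if Pr > 0.70):",
                      inc.round(4).to_string(index=False)]
        return "\n".join(lines)

    def to_dataframe(self) -> pd.DataFrame:
        """All scalar draws, one column per parameter, pooled over chains."""
        cols = {}
        for label, name, idx in self._scalar_items(include_w=True):
            cols[label] = self._flat(name)[(slice(None),) + idx]
        return pd.DataFrame(cols)
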