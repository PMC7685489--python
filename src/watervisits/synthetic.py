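"""Synthetic data with the statistical structure the analysis assumes.

Everything the pipeline ingests can be generated here: hourly logger weather
(diurnal + annual sinusoids), daily station precipitation (marked events),
camera deployment logs with dropout, model-true weekly count panels driven
by the negative-binomial autoregression, and image-level detection streams
that collapse back to their generating visits exactly. Every generator is a
pure function of (config, seed), and each bundle carries its truth so
recovery tests can score themselves.

The desk-scale default (10 locations × 104 weeks × 4 species) emulates a
two-year multi-site camera study and runs end to end in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ParamState, VisitCountModel
from .visits import WeekScheme
from ._kernels import ETA_MAX

HOURS_PER_WEEK = 168


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    Weather mimics a hot-desert annual cycle: daily maximum temperature
    peaking ~38 °C in early July with a 12 °C seasonal swing and an 8 °C
    diurnal swing; daily minimum relative humidity ~25% mid-scale, drier in
    summer; precipitation as sparse marked events (~1 wet day per 10 days,
    exponential magnitudes, mean 6 mm). Counts follow the fitted model's own
    generative form with modest dispersion (θ = 2) and weak-to-moderate
    autoregression (δ = β = 0.15). The default covariate effects make the
    first species strongly temperature-driven (a bighorn-like seasonal
    concentrator) and include a zero effect for variable-selection checks.
    """

    I: int = 10                      # camera locations
    J: int = 104                     # weeks (two years)
    K: int = 4                       # species
    start: str = "2012-01-02"        # first week's Monday
    # weather
    tmax_mean: float = 26.0          # °C annual mean of daily maxima
    tmax_amp: float = 12.0           # seasonal amplitude
    tmax_diurnal: float = 8.0        # half the day-night swing
    tmax_peak_doy: int = 185         # early July
    rh_mean: float = 25.0            # % annual mean of daily minima
    rh_amp: float = 12.0             # seasonal amplitude
    rh_trough_doy: int = 120         # driest air ~May, before the monsoon
    rh_diurnal: float = 10.0         # half the day-night RH swing
    rh_weekly_sd: float = 5.0        # synoptic (week-scale) RH variation
    weather_noise: float = 1.5       # hourly noise SD
    precip_rate: float = 0.1         # wet-day probability
    precip_mean: float = 6.0         # mean event size, mm
    # effort
    mean_camera_days: float = 7.0
    dropout_prob: float = 0.05       # probability a week is lost entirely
    # true model parameters (columns = species)
    alpha0: tuple = (-1.0, -0.7, -1.3, -2.0)
    #: rows TMAX, RH, P1, P6; species 4 has an all-zero row partner below
    alpha: tuple = ((0.8, 0.5, 0.2, 0.3),
                    (-0.3, -0.2, -0.4, -0.1),
                    (0.0, 0.0, 0.0, 0.0),
                    (-0.5, -0.6, -0.3, -0.4))
    delta: tuple = (0.15, 0.15, 0.15, 0.15)
    beta: tuple = (0.15, 0.15, 0.15, 0.15)
    theta: float = 2.0
    eps_mode: str = "location"       # "location" or "cell" gamma deviates
    ar_form: str = "log"
    # image-level process
    mean_images_per_visit: float = 3.0
    mean_group_size: float = 1.5
    intra_visit_spacing_min: tuple = (1.0, 10.0)  # uniform, minutes
    species_names: tuple = ("bighorn", "muledeer", "coyote", "lion")
    covariate_names: tuple = ("TMAX", "RH", "P1", "P6")
    seed: int = 0

    def species(self) -> tuple:
        names = tuple(self.species_names)[:self.K]
        return names + tuple(f"sp{k}" for k in range(len(names), self.K))

    def true_params(self) -> ParamState:
        alpha = np.asarray(self.alpha, dtype=float)[:, :self.K]
        return ParamState(
            alpha0=np.asarray(self.alpha0, dtype=float)[:self.K],
            alpha=alpha,
            w=(alpha != 0).astype(np.int8),
            delta=np.asarray(self.delta, dtype=float)[:self.K],
            beta=np.asarray(self.beta, dtype=float)[:self.K],
            theta=float(self.theta))


def simulate_weather(cfg: SimConfig, rng=None):
    """Hourly logger series per location and a daily station series.

    Temperature combines an annual sinusoid (peak at ``tmax_peak_doy``), a
    diurnal sinusoid (peak at 15:00) and Gaussian noise; RH runs in
    anti-phase, clipped to [0, 100]. Precipitation is an independent
    Bernoulli-exponential daily process. Deterministic under the seed.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start)
    hours = pd.date_range(start, periods=cfg.J * HOURS_PER_WEEK, freq="h")
    doy = hours.dayofyear.to_numpy()
    hod = hours.hour.to_numpy()
    annual = np.cos(2 * np.pi * (doy - cfg.tmax_peak_doy) / 365.25)
    # RH runs on the monsoon cycle, phase-shifted from the temperature peak
    rh_annual = np.cos(2 * np.pi * (doy - cfg.rh_trough_doy) / 365.25)
    diurnal = np.cos(2 * np.pi * (hod - 15) / 24)
    week_of = np.arange(len(hours)) // HOURS_PER_WEEK
    frames = []
    for i in range(cfg.I):
        temp = (cfg.tmax_mean - cfg.tmax_diurnal + cfg.tmax_amp * annual
                + cfg.tmax_diurnal * diurnal
                + rng.normal(0, cfg.weather_noise, len(hours)))
        synoptic = rng.normal(0, cfg.rh_weekly_sd, cfg.J)[week_of]
        rh = np.clip(cfg.rh_mean + cfg.rh_diurnal - cfg.rh_amp * rh_annual
                     - cfg.rh_diurnal * diurnal + synoptic
                     + rng.normal(0, 2 * cfg.weather_noise, len(hours)),
                     0, 100)
        frames.append(pd.DataFrame({"location": f"L{i:02d}",
                                    "timestamp": hours,
                                    "temp": temp, "rh": rh}))
    hourly = pd.concat(frames, ignore_index=True)

    days = pd.date_range(start, periods=cfg.J * 7, freq="D")
    wet = rng.random(len(days)) < cfg.precip_rate
    amount = np.where(wet, rng.exponential(cfg.precip_mean, len(days)), 0.0)
    d_annual = np.cos(2 * np.pi * (days.dayofyear - cfg.tmax_peak_doy)
                      / 365.25)
    d_rh = np.cos(2 * np.pi * (days.dayofyear - cfg.rh_trough_doy) / 365.25)
    daily = pd.DataFrame({
        "site": "S1", "date": days, "precip": amount,
        "temp_max": cfg.tmax_mean + cfg.tmax_amp * d_annual,
        "rh_min": np.clip(cfg.rh_mean - cfg.rh_amp * d_rh, 0, 100),
    })
    return hourly, daily


def simulate_effort(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Weekly camera-days per location with random whole-week dropout."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    rows = []
    for i in range(cfg.I):
        for j in range(cfg.J):
            if rng.random() < cfg.dropout_prob:
                days = 0.0
            else:
                days = min(7.0, rng.normal(cfg.mean_camera_days, 0.5))
                days = max(days, 0.5)
            rows.append({"location": f"L{i:02d}", "week": j,
                         "camera_days": days})
    return pd.DataFrame(rows)


def standardized_design(cfg: SimConfig, rng=None):
    """Weekly standardized covariate array X (V, I, J) + effort, via the
    weather pipeline run on a simulated weather series."""
    from . import weather as weather_mod

    rng = rng or np.random.default_rng(cfg.seed)
    hourly, daily = simulate_weather(cfg, rng)
    weeks = WeekScheme(anchor=pd.Timestamp(cfg.start).date())
    t = weather_mod.weekly_tmax(hourly, weeks)
    r = weather_mod.weekly_rhmin(hourly, weeks)
    p = weather_mod.weekly_precip(daily, weeks)
    X = np.zeros((4, cfg.I, cfg.J))
    for i in range(cfg.I):
        loc = f"L{i:02d}"
        tv = t[t["location"] == loc].set_index("week")["TMAX"]
        rv = r[r["location"] == loc].set_index("week")["RH"]
        X[0, i] = tv.reindex(range(cfg.J)).to_numpy()
        X[1, i] = rv.reindex(range(cfg.J)).to_numpy()
    p = p.set_index("week")
    X[2] = np.broadcast_to(p["P1"].reindex(range(cfg.J)).to_numpy(),
                           (cfg.I, cfg.J))
    X[3] = np.broadcast_to(np.nan_to_num(
        p["P6"].reindex(range(cfg.J)).to_numpy(),
        nan=np.nanmean(p["P6"])), (cfg.I, cfg.J))
    for v in range(4):
        flat = X[v].ravel()
        X[v] = ((flat - flat.mean()) / flat.std(ddof=1)).reshape(X[v].shape)
    return X


def simulate_counts(cfg: SimConfig, X: np.ndarray, effort: pd.DataFrame,
                    rng=None):
    """Weekly counts from the model's own generative recursion.

    λ follows the fitted model's forward equation with the true parameters;
    y is Poisson(λ·ε) with gamma(θ, θ) heterogeneity ε drawn once per
    location (``eps_mode="location"``, the location-level overdispersion of
    the analysis) or independently per cell (``eps_mode="cell"``, the pure
    marginal negative binomial). Weeks with zero camera-days are masked.

    Returns (counts long-DataFrame, truth dict with the ParamState, λ array,
    y array and mask).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    params = cfg.true_params()
    I, J, K = cfg.I, cfg.J, cfg.K
    V = X.shape[0]
    eff = effort.pivot(index="location", columns="week",
                       values="camera_days").to_numpy()
    mask = eff > 0
    offset = np.where(mask, np.log(np.where(mask, eff, 1.0)), 0.0)

    if cfg.eps_mode == "location":
        eps = np.broadcast_to(
            rng.gamma(cfg.theta, 1.0 / cfg.theta, size=(K, I, 1)), (K, I, J))
    elif cfg.eps_mode == "cell":
        eps = rng.gamma(cfg.theta, 1.0 / cfg.theta, size=(K, I, J))
    else:
        raise ValueError(f"unknown eps_mode {cfg.eps_mode!r}")

    y = np.zeros((K, I, J))
    lam = np.zeros((K, I, J))
    use_log = cfg.ar_form == "log"
    for k in range(K):
        y_prev = np.zeros(I)
        lam_prev = np.exp(params.alpha0[k] + offset[:, 0])
        for j in range(J):
            eta = params.alpha0[k] + offset[:, j]
            for v in range(V):
                if params.w[v, k]:
                    eta = eta + params.alpha[v, k] * X[v, :, j]
            if use_log:
                eta = eta + params.delta[k] * np.log1p(y_prev) \
                    + params.beta[k] * np.log(lam_prev)
            else:
                eta = eta + params.delta[k] * (1.0 + y_prev) \
                    + params.beta[k] * lam_prev
            if np.any(np.abs(eta) > ETA_MAX):
                raise RuntimeError(
                    f"divergent mean at week {j}, species {k}: "
                    f"|log lambda| > {ETA_MAX}; true-parameter report: "
                    f"alpha0={params.alpha0[k]}, delta={params.delta[k]}, "
                    f"beta={params.beta[k]}")
            lam[k, :, j] = np.exp(eta)
            y[k, :, j] = rng.poisson(lam[k, :, j] * eps[k, :, j])
            y_prev = np.where(mask[:, j], y[k, :, j], lam[k, :, j])
            lam_prev = lam[k, :, j]

    locs = sorted(effort["location"].unique())
    rows = []
    for k in range(K):
        for i, loc in enumerate(locs):
            for j in range(J):
                if mask[i, j]:
                    rows.append({"site": "S1", "location": loc, "week": j,
                                 "species": cfg.species()[k],
                                 "y": int(y[k, i, j]),
                                 "camera_days": eff[i, j]})
    counts = pd.DataFrame(rows)
    truth = {"params": params, "lam": lam, "y": y, "mask": mask,
             "offset": offset, "X": X, "seed": cfg.seed}
    return counts, truth


def simulate_visits(weekly: pd.DataFrame, weeks: WeekScheme, rng=None,
                    mean_group_size: float = 1.5) -> pd.DataFrame:
    """Decompose weekly summed group sizes into individual visit records.

    Each location-week-species total y is split into visits with group
    sizes >= 1 summing to y; visit start times are placed inside the week at
    least one hour apart so independence is preserved by construction.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for row in weekly.itertuples(index=False):
        y = int(row.y)
        if y == 0:
            continue
        sizes = []
        remaining = y
        while remaining > 0:
            g = min(remaining, 1 + rng.poisson(mean_group_size - 1.0))
            sizes.append(int(g))
            remaining -= g
        all_slots = np.arange(0, HOURS_PER_WEEK, 2)
        if len(sizes) > len(all_slots):
            # busy week: merge into fewer visits with larger groups so the
            # 2-hour spacing still fits (weekly totals stay exact)
            n = len(all_slots)
            base, extra = divmod(y, n)
            sizes = [base + (1 if m < extra else 0) for m in range(n)]
        n = len(sizes)
        # visit starts: sorted hours within the week, >= 2 h apart
        slots = rng.choice(all_slots, size=n, replace=False)
        base = weeks.week_start(row.week)
        for g, h in zip(sizes, sorted(slots)):
            rows.append({"site": row.site, "location": row.location,
                         "species": row.species,
                         "start": base + pd.Timedelta(hours=float(h)),
                         "group_size": g})
    return pd.DataFrame(rows,
                        columns=["site", "location", "species", "start",
                                 "group_size"])


def simulate_detections(cfg: SimConfig, visit_truth: pd.DataFrame,
                        rng=None) -> pd.DataFrame:
    """Expand visit truth into an image-level detection stream.

    Each visit yields >= 1 images spaced under an hour apart (uniform
    ``intra_visit_spacing_min`` minutes); per-image counts never exceed the
    visit's group size and the maximum attains it, so collapsing the stream
    with the one-hour rule recovers the generating visits exactly.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    lo, hi = cfg.intra_visit_spacing_min
    rows = []
    for row in visit_truth.itertuples(index=False):
        n_img = 1 + rng.poisson(cfg.mean_images_per_visit - 1.0)
        # keep the whole visit inside 105 min so it can never bleed into the
        # next visit's slot (visits are placed >= 2 h apart)
        hi_eff = min(hi, 105.0 / max(n_img - 1, 1))
        t = pd.Timestamp(row.start)
        seen = [int(row.group_size)] + list(
            rng.integers(1, row.group_size + 1, size=n_img - 1))
        rng.shuffle(seen)
        for c in seen:
            rows.append({"site": row.site, "location": row.location,
                         "timestamp": t, "species": row.species,
                         "n_in_image": int(c)})
            t = t + pd.Timedelta(minutes=float(rng.uniform(min(lo, hi_eff),
                                                           hi_eff)))
    df = pd.DataFrame(rows, columns=["site", "location", "timestamp",
                                     "species", "n_in_image"])
    return df.sort_values(["location", "species", "timestamp"],
                          kind="mergesort").reset_index(drop=True)


def model_from_truth(cfg: SimConfig, truth: dict,
                     priors=None) -> VisitCountModel:
    """VisitCountModel over a simulated panel, built straight from arrays.

    Uses the generator's own y, standardized X, offset and mask, bypassing
    the CSV ingestion path (for parameter-recovery studies)."""
    return VisitCountModel(truth["y"], truth["offset"], X=truth["X"],
                           mask=truth["mask"],
                           species=list(cfg.species()),
                           covariates=list(cfg.covariate_names),
                           ar_form=cfg.ar_form, priors=priors)


@dataclass
class SyntheticDataset:
    """One fully-linked synthetic study: raw streams plus their truth."""

    cfg: SimConfig
    hourly: pd.DataFrame
    daily: pd.DataFrame
    camera_log: pd.DataFrame
    detections: pd.DataFrame
    visit_truth: pd.DataFrame
    counts: pd.DataFrame
    truth: dict
    weeks: WeekScheme


def simulate_dataset(cfg: SimConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic study."""
    cfg = cfg or SimConfig()
    if seed is not None:
        from dataclasses import replace
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    hourly, daily = simulate_weather(cfg, rng)
    effort = simulate_effort(cfg, rng)
    X = standardized_design(cfg, np.random.default_rng(cfg.seed))
    counts, truth = simulate_counts(cfg, X, effort, rng)
    weeks = WeekScheme(anchor=pd.Timestamp(cfg.start).date())
    visit_truth = simulate_visits(counts, weeks, rng,
                                  mean_group_size=cfg.mean_group_size)
    detections = simulate_detections(cfg, visit_truth, rng)
    truth["X"] = X

    # camera log matching the weekly effort: one interval per operated week
    rows = []
    for r in effort.itertuples(index=False):
        if r.camera_days > 0:
            start = weeks.week_start(r.week)
            rows.append({"location": r.location, "start": start,
                         "end": start + pd.Timedelta(days=r.camera_days)})
    camera_log = pd.DataFrame(rows)
    return SyntheticDataset(cfg, hourly, daily, camera_log, detections,
                            visit_truth, counts, truth, weeks)


def export_csv(ds: SyntheticDataset, outdir) -> dict:
    """Write the dataset in the CSV dialects the ingestion modules read."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("detections", ds.detections),
                     ("camera_log", ds.camera_log),
                     ("hourly_weather", ds.hourly),
                     ("daily_station", ds.daily),
                     ("weekly_counts", ds.counts)):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
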