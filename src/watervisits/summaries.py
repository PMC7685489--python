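"""Effort-corrected seasonal visitation summaries.

Monthly profiles normalize each site-year: visits per month are divided by
the month's camera-trap days, and the twelve rates are rescaled to sum to 1.
Only full years (all twelve months with positive effort) are eligible.
Profiles pool across site-years within a desert; the peak window is the
contiguous 4- or 5-month span (December–January wraparound allowed) with the
largest pooled share. Under uniform visitation a species would record
8.3% of visits per month — 33% in any 4-month window and 42% in any
5-month window — so shares above those baselines indicate concentration.
Standardized slopes from separate fits are compared as ratios of magnitudes
("species a is |α_a|/|α_b| times more responsive per unit of covariate v").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import VisitCountResults

MONTH_LABELS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass
class MonthlyProfile:
    site: object
    year: int
    species: str
    p: np.ndarray          # (12,) proportions, months 1..12
    eligible: bool


@dataclass
class WindowSummary:
    window: tuple[int, ...]   # contiguous calendar months, 1..12
    share: float              # mean over site-years
    sd: float
    n_site_years: int


def monthly_camera_days(camera_log: pd.DataFrame, year: int) -> np.ndarray:
    """Camera-days per calendar month of ``year`` from deployment intervals."""
    days = np.zeros(12)
    starts = pd.to_datetime(camera_log["start"], format="mixed")
    ends = pd.to_datetime(camera_log["end"], format="mixed")
    for m in range(1, 13):
        m0 = pd.Timestamp(year=year, month=m, day=1)
        m1 = m0 + pd.offsets.MonthBegin(1)
        for s, e in zip(starts, ends):
            lo, hi = max(s, m0), min(e, m1)
            if hi > lo:
                days[m - 1] += (hi - lo) / pd.Timedelta(days=1)
    return days


def monthly_profile(visits: pd.DataFrame, camera_log: pd.DataFrame,
                    site, year: int, species: str) -> MonthlyProfile:
    """Effort-corrected monthly visit proportions for one site-year-species.

    Each visit is attributed to the calendar month of its start timestamp.
    rate[m] = (summed group sizes in month m) / (camera-days in month m);
    p[m] = rate[m] / Σ rate. Site-years without all twelve months of
    positive effort are ineligible (p set to NaN).
    """
    effort = monthly_camera_days(camera_log[camera_log["site"] == site]
                                 if "site" in camera_log.columns
                                 else camera_log, year)
    eligible = bool(np.all(effort > 0))
    v = visits[(visits["site"] == site) & (visits["species"] == species)]
    start = pd.to_datetime(v["start"])
    v = v[start.dt.year == year]
    start = start[start.dt.year == year]
    counts = np.zeros(12)
    for m, g in zip(start.dt.month, v["group_size"]):
        counts[m - 1] += g
    if np.any((counts > 0) & (effort <= 0)):
        raise ValueError(f"visits recorded in a zero-effort month at site "
                         f"{site!r}, year {year}")
    if not eligible:
        return MonthlyProfile(site, year, species, np.full(12, np.nan),
                              False)
    rate = counts / effort
    total = rate.sum()
    p = rate / total if total > 0 else np.zeros(12)
    return MonthlyProfile(site, year, species, p, True)


def pooled_profile(profiles: list[MonthlyProfile]):
    """Unweighted mean and sample SD of p[m] across eligible site-years.

    Returns (mean (12,), sd (12,), n). With a single profile the SD is
    reported as 0. Empty input is an error.
    """
    ps = np.array([pr.p for pr in profiles if pr.eligible])
    if len(ps) == 0:
        raise ValueError("pooled_profile: no eligible site-year profiles")
    mean = ps.mean(axis=0)
    sd = ps.std(axis=0, ddof=1) if len(ps) > 1 else np.zeros(12)
    return mean, sd, len(ps)


def _windows(width: int):
    for start in range(1, 13):
        yield tuple((start - 1 + d) % 12 + 1 for d in range(width))


def peak_window(pooled_mean: np.ndarray, width: int) -> tuple[tuple, float]:
    """Contiguous ``width``-month window maximizing the pooled share.

    Wraparound (e.g. Nov–Feb) is allowed; ties break to the earliest start
    month. Returns (window months 1..12, summed mean share).
    """
    pooled_mean = np.asarray(pooled_mean, dtype=float)
    if pooled_mean.shape != (12,):
        raise ValueError("peak_window expects 12 monthly means")
    if not 1 <= width <= 12:
        raise ValueError("window width must be in 1..12")
    best, best_share = None, -np.inf
    for win in _windows(width):
        share = float(sum(pooled_mean[m - 1] for m in win))
        if share > best_share + 1e-15:
            best, best_share = win, share
    return best, best_share


def window_share(profiles: list[MonthlyProfile],
                 window: tuple[int, ...]) -> WindowSummary:
    """Mean and SD across site-years of the visit share inside ``window``.

    ``window`` is normally the focal species' peak window; the profiles may
    belong to any species (e.g. predator visits inside the bighorn window).
    """
    shares = np.array([sum(pr.p[m - 1] for m in window)
                       for pr in profiles if pr.eligible])
    if len(shares) == 0:
        raise ValueError("window_share: no eligible profiles")
    sd = float(shares.std(ddof=1)) if len(shares) > 1 else 0.0
    return WindowSummary(tuple(window), float(shares.mean()), sd,
                         len(shares))


def uniform_baseline(width: int) -> float:
    """Expected window share (percent) under uniform monthly visitation."""
    if not 1 <= width <= 12:
        raise ValueError("window width must be in 1..12")
    return 100.0 * width / 12.0


def auto_window(pooled_mean: np.ndarray,
                widths: tuple[int, ...] = (4, 5)) -> tuple[tuple, float]:
    """Pick the window over candidate widths maximizing share per month."""
    best, best_rate = None, -np.inf
    for width in widths:
        win, share = peak_window(pooled_mean, width)
        if share / width > best_rate + 1e-15:
            best, best_rate = (win, share), share / width
    return best


def slope_ratio(results: VisitCountResults, covariate: str, species_a: str,
                species_b: str, level: float = 0.95) -> dict:
    """Posterior ratio |α[v,a]| / |α[v,b]| of standardized slopes.

    "Species a is r times more likely to visit per unit of covariate v than
    species b" is read as the ratio of standardized slope magnitudes. The
    ratio is flagged unstable when the denominator's credible interval
    covers zero (the per-draw ratio is then heavy-tailed).
    """
    m = results.model
    v = m.covariates.index(covariate)
    ka, kb = m.species.index(species_a), m.species.index(species_b)
    a = results._flat("alpha")[:, v, ka]
    b = results._flat("alpha")[:, v, kb]
    q = (1 - level) / 2
    blo, bhi = np.quantile(b, [q, 1 - q])
    ratio = np.abs(a) / np.abs(b)
    lo, hi = np.quantile(ratio, [q, 1 - q])
    return {"covariate": covariate, "species_a": species_a,
            "species_b": species_b, "ratio_mean": float(ratio.mean()),
            "ratio_ci": (float(lo), float(hi)),
            "unstable": bool(blo <= 0.0 <= bhi)}


def aggregate_slope_ratios(ratios: list[dict]) -> dict:
    """Cross-site mean and SD of per-fit posterior-mean slope ratios."""
    vals = np.array([r["ratio_mean"] for r in ratios])
    return {"mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n_sites": len(vals)}


def polar_plot_data(pooled_mean: np.ndarray, pooled_sd: np.ndarray,
                    window: tuple[int, ...]) -> pd.DataFrame:
    """Polar-plot-ready table: exactly the pooled means, no re-normalizing."""
    return pd.DataFrame({
        "month": np.arange(1, 13),
        "label": MONTH_LABELS,
        "mean": np.asarray(pooled_mean, dtype=float),
        "sd": np.asarray(pooled_sd, dtype=float),
        "in_window": [m in set(window) for m in range(1, 13)],
    })


def plot_polar(pooled_mean, pooled_sd, window, species="", ax=None):
    """Polar bar chart of the monthly profile (peak window highlighted)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.arange(12) * 2 * np.pi / 12
    colors = ["crimson" if (m in set(window)) else "0.25"
              for m in range(1, 13)]
    ax.bar(theta, pooled_mean, width=2 * np.pi / 12 * 0.9, color=colors)
    ax.set_xticks(theta)
    ax.set_xticklabels([str(m) for m in range(1, 13)])
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    if species:
        ax.set_title(species)
    return ax
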