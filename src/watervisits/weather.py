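"""Weekly weather covariates for the visitation count model.

Four covariates drive the model: TMAX, the weekly average of daily maximum
temperature (°C); RH, the weekly average of daily minimum relative humidity
(%); P1, total precipitation within the week (mm); and P6, total
precipitation in the week plus the previous five weeks (mm). TMAX and RH
come from hourly loggers at the camera locations, precipitation from the
nearest daily station. Gaps are filled from an ordered list of donor series;
covariates are standardized to mean 0, SD 1 over the rows entering a fit;
and covariate pairs with Pearson |r| >= 0.60 are not used together.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .visits import WeekScheme

logger = logging.getLogger(__name__)

#: priority when the correlation screen must drop one of a pair
DEFAULT_PRIORITY = ("TMAX", "P6", "P1", "RH")


def _daily_stat(hourly: pd.DataFrame, col: str, stat: str) -> pd.DataFrame:
    df = hourly.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()
    return (df.groupby(["location", "date"])[col]
              .agg(stat).rename(col).reset_index())


def _weekly_mean_of_daily(daily: pd.DataFrame, col: str, weeks: WeekScheme,
                          out: str) -> pd.DataFrame:
    daily = daily.copy()
    daily["week"] = [weeks.week_index(d) for d in daily["date"]]
    agg = (daily.groupby(["location", "week"])[col]
                .mean().rename(out).reset_index())
    # weeks inside each location's observed span but with no data at all
    # must surface as missing, never as silent zeros
    rows = []
    for loc, grp in agg.groupby("location"):
        full = pd.DataFrame({"location": loc,
                             "week": range(grp["week"].min(),
                                           grp["week"].max() + 1)})
        rows.append(full.merge(grp, on=["location", "week"], how="left"))
    return pd.concat(rows, ignore_index=True)


def weekly_tmax(hourly: pd.DataFrame, weeks: WeekScheme) -> pd.DataFrame:
    """Weekly average of daily maximum temperature per location.

    Days average over whatever hours were observed; a week with zero days of
    data gets a missing value (NaN) for later gap-filling.
    """
    daily = _daily_stat(hourly, "temp", "max")
    return _weekly_mean_of_daily(daily, "temp", weeks, "TMAX")


def weekly_rhmin(hourly: pd.DataFrame, weeks: WeekScheme) -> pd.DataFrame:
    """Weekly average of daily minimum relative humidity per location."""
    daily = _daily_stat(hourly, "rh", "min")
    return _weekly_mean_of_daily(daily, "rh", weeks, "RH")


def weekly_precip(daily: pd.DataFrame, weeks: WeekScheme) -> pd.DataFrame:
    """Weekly (P1) and rolling six-week (P6) precipitation totals per site.

    P6 for week j sums P1 over weeks j-5..j; the first five weeks of a
    series have missing P6. Negative precipitation is a validation error.
    """
    df = daily.copy()
    if (df["precip"] < 0).any():
        bad = df.loc[df["precip"] < 0]
        raise ValueError(f"negative precipitation in {len(bad)} row(s), "
                         f"first at date {bad['date'].iloc[0]}")
    df["date"] = pd.to_datetime(df["date"])
    df["week"] = [weeks.week_index(d) for d in df["date"]]
    out = []
    for site, grp in df.groupby("site"):
        p1 = grp.groupby("week")["precip"].sum()
        p1 = p1.reindex(range(p1.index.min(), p1.index.max() + 1),
                        fill_value=0.0)
        p6 = p1.rolling(6).sum()
        out.append(pd.DataFrame({"site": site, "week": p1.index,
                                 "P1": p1.to_numpy(), "P6": p6.to_numpy()}))
    return pd.concat(out, ignore_index=True)


def fill_gaps(target: pd.Series, donors: list[pd.Series]):
    """Fill missing cells of a weekly series from ordered donor series.

    Each missing cell takes the value of the first donor (in the given
    proximity/preference order) that has it. Observed cells are never
    altered.

    Returns
    -------
    filled : Series
    source : Series of str
        "observed", "donor<i>" (1-based), or "missing".
    fill_fraction : float
        Share of originally-missing cells that were filled, over all cells.
    """
    filled = target.copy()
    source = pd.Series(np.where(target.notna(), "observed", "missing"),
                       index=target.index, dtype=object)
    for rank, donor in enumerate(donors, start=1):
        donor = donor.reindex(target.index)
        takeable = filled.isna() & donor.notna()
        filled[takeable] = donor[takeable]
        source[takeable] = f"donor{rank}"
    still = int(filled.isna().sum())
    if still:
        logger.warning("fill_gaps: %d cell(s) missing in target and all "
                       "donors remain missing", still)
    n_filled = int((source.str.startswith("donor")).sum())
    fill_fraction = n_filled / len(target) if len(target) else 0.0
    return filled, source, fill_fraction


def standardize(x) -> tuple[np.ndarray, float, float]:
    """Center and scale a covariate column to mean 0, SD 1 (sample SD).

    Returns the unitless column plus (mean, sd) for back-transformation
    ``x = sd * z + mean``. A constant column is an error.
    """
    arr = np.asarray(x, dtype=float)
    name = getattr(x, "name", None)
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError(f"cannot standardize constant covariate"
                         f"{' ' + repr(name) if name else ''} (sd = 0)")
    return (arr - mean) / sd, mean, sd


def correlation_screen(X: pd.DataFrame, r_max: float = 0.60,
                       priority: tuple[str, ...] = DEFAULT_PRIORITY):
    """Drop covariates so that no retained pair has Pearson |r| >= r_max.

    Pairs are examined in priority order (default TMAX > P6 > P1 > RH;
    columns not listed rank after listed ones, in input order): whenever a
    retained higher-priority column and a lower-priority column correlate at
    |r| >= r_max, the lower-priority column is dropped.

    Returns
    -------
    retained : list of str
    report : DataFrame with one row per examined pair
        (col_a, col_b, r, action).
    """
    cols = list(X.columns)
    rank = {c: priority.index(c) if c in priority else len(priority) + i
            for i, c in enumerate(cols)}
    ordered = sorted(cols, key=lambda c: rank[c])
    retained: list[str] = []
    rows = []
    for c in ordered:
        drop = False
        for kept in retained:
            r = float(np.corrcoef(X[kept].to_numpy(dtype=float),
                                  X[c].to_numpy(dtype=float))[0, 1])
            action = "drop " + c if abs(r) >= r_max else "keep both"
            rows.append({"col_a": kept, "col_b": c, "r": r, "action": action})
            if abs(r) >= r_max:
                drop = True
                break
        if not drop:
            retained.append(c)
    retained = [c for c in cols if c in retained]  # restore input order
    return retained, pd.DataFrame(rows, columns=["col_a", "col_b", "r",
                                                 "action"])


def build_covariate_table(hourly: pd.DataFrame, daily: pd.DataFrame,
                          weeks: WeekScheme,
                          location_site: dict) -> pd.DataFrame:
    """Join the four weekly covariates into one location × week table.

    TMAX and RH are per location (logger); P1 and P6 are per site (station)
    and broadcast to the site's locations via ``location_site``.
    Standardization is NOT applied here — it happens over the exact rows
    entering a model fit.
    """
    t = weekly_tmax(hourly, weeks)
    r = weekly_rhmin(hourly, weeks)
    p = weekly_precip(daily, weeks)
    tab = t.merge(r, on=["location", "week"], how="outer")
    tab["site"] = tab["location"].map(location_site)
    tab = tab.merge(p, on=["site", "week"], how="left")
    return tab[["site", "location", "week", "TMAX", "RH", "P1", "P6"]]
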