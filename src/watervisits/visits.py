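"""Independent-visit extraction from camera-trap image records.

A camera at a managed water source fires many images per animal visit. The
analysis unit is the *independent visit*: a run of images of one species at
one location in which every successive pair of images is less than a fixed
gap apart (default one hour). Images one hour or more apart start a new
visit. Each visit contributes its maximum single-image group count, and these
counts are summed per week per species per location to form the response of
the count model.

Effort is measured in camera-trap days: the overlap, in days, of each
camera's operational intervals with each 7-day week.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["site", "location", "timestamp", "species", "n_in_image"]
VISIT_COLUMNS = ["site", "location", "species", "start", "end",
                 "group_size", "n_images"]

DEFAULT_GAP = timedelta(hours=1)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class EffortInconsistencyError(ValueError):
    """A visit was recorded in a location-week with zero logged effort."""


@dataclass(frozen=True)
class WeekScheme:
    """Contiguous 7-day weeks anchored at a fixed date.

    Week ``j`` covers ``[anchor + 7j days, anchor + 7(j+1) days)``. Anchoring
    at the earliest camera deployment of a site avoids a partial first week;
    an ISO-style variant anchors at the Monday on or before that date.
    """

    anchor: date

    def week_index(self, ts) -> int:
        ts = pd.Timestamp(ts)
        return int((ts - pd.Timestamp(self.anchor)) // pd.Timedelta(days=7))

    def week_start(self, j: int) -> pd.Timestamp:
        return pd.Timestamp(self.anchor) + pd.Timedelta(days=7 * int(j))

    def month_of_week(self, j: int) -> int:
        """Calendar month of the week's start date (covariate alignment)."""
        return self.week_start(j).month


def week_scheme_from_log(camera_log: pd.DataFrame,
                         mode: str = "site-start") -> WeekScheme:
    """Build the week scheme from a camera deployment log.

    mode="site-start" anchors at the earliest deployment date;
    mode="iso" anchors at the Monday on or before it, so week boundaries
    fall on ISO week boundaries.
    """
    earliest = pd.Timestamp(pd.to_datetime(camera_log["start"]).min()).normalize()
    if mode == "iso":
        earliest = earliest - pd.Timedelta(days=earliest.weekday())
    elif mode != "site-start":
        raise ValueError(f"unknown week-anchor mode {mode!r}")
    return WeekScheme(anchor=earliest.date())


def read_detections(path, schema: dict | None = None) -> pd.DataFrame:
    """Read an image-level detection table from delimited text.

    Parameters
    ----------
    path : str or file-like
        CSV with one row per image.
    schema : dict, optional
        Maps the canonical column names (``site``, ``location``,
        ``timestamp``, ``species``, ``n_in_image``) to the file's column
        names. Identity by default.

    Returns
    -------
    DataFrame with canonical columns, sorted by (location, species,
    timestamp). Rows with unparseable timestamps or negative/missing image
    counts are dropped and reported, with their 1-based data line numbers,
    through the module logger.
    """
    schema = schema or {}
    raw = pd.read_csv(path)
    colmap = {schema.get(c, c): c for c in DETECTION_COLUMNS}
    missing = [src for src in colmap if src not in raw.columns]
    if missing:
        raise SchemaError(
            f"detection table is missing required column(s): {missing}; "
            f"found columns {list(raw.columns)}")
    df = raw[list(colmap)].rename(columns=colmap)

    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    n = pd.to_numeric(df["n_in_image"], errors="coerce")
    bad = ts.isna() | n.isna() | (n < 0)
    if bad.any():
        lines = (df.index[bad] + 1).tolist()
        logger.warning("read_detections: rejected %d malformed row(s) at data "
                       "line(s) %s", int(bad.sum()), lines)
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    df["n_in_image"] = n[~bad].astype(int)
    return (df.sort_values(["location", "species", "timestamp"],
                           kind="mergesort")
              .reset_index(drop=True))


def collapse_visits(detections: pd.DataFrame,
                    gap: timedelta = DEFAULT_GAP) -> pd.DataFrame:
    """Collapse image records into independent visits.

    Within each (location, species), time-sorted images are partitioned:
    a new visit starts whenever the interval since the previous image is
    greater than or equal to ``gap`` (images exactly one hour apart are
    independent). Each visit's ``group_size`` is the maximum ``n_in_image``
    over its images.
    """
    if len(detections) == 0:
        return pd.DataFrame(columns=VISIT_COLUMNS)
    gap = pd.Timedelta(gap)
    out = []
    for (loc, sp), grp in detections.groupby(["location", "species"],
                                             sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        t = grp["timestamp"].to_numpy()
        new_visit = np.ones(len(grp), dtype=bool)
        new_visit[1:] = (t[1:] - t[:-1]) >= gap.to_numpy()
        visit_id = np.cumsum(new_visit)
        agg = grp.groupby(visit_id).agg(
            site=("site", "first"),
            start=("timestamp", "min"),
            end=("timestamp", "max"),
            group_size=("n_in_image", "max"),
            n_images=("n_in_image", "size"),
        )
        agg["location"] = loc
        agg["species"] = sp
        out.append(agg)
    visits = pd.concat(out, ignore_index=True)
    return visits[VISIT_COLUMNS].sort_values(
        ["location", "species", "start"], kind="mergesort"
    ).reset_index(drop=True)


def compute_effort(camera_log: pd.DataFrame, weeks: WeekScheme,
                   n_weeks: int | None = None) -> pd.DataFrame:
    """Camera-trap days per location per week from deployment intervals.

    ``camera_log`` has columns location, start, end (one row per deployment
    interval of one camera). Overlapping intervals at a location are merged
    (with a warning) so a week can never exceed 7 camera-days per camera
    stream; effort is the total overlap in days of the merged intervals with
    each week.
    """
    log = camera_log.copy()
    log["start"] = pd.to_datetime(log["start"], format="mixed")
    log["end"] = pd.to_datetime(log["end"], format="mixed")
    if (log["end"] < log["start"]).any():
        raise ValueError("camera log contains interval(s) with end < start")

    rows = []
    for loc, grp in log.groupby("location", sort=True):
        ivs = sorted(zip(grp["start"], grp["end"]))
        merged = [list(ivs[0])]
        overlapped = False
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                overlapped = overlapped or s < merged[-1][1]
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if overlapped:
            logger.warning("compute_effort: merged overlapping deployment "
                           "intervals at location %r", loc)
        j_lo = min(weeks.week_index(s) for s, _ in merged)
        j_hi = max(weeks.week_index(e - pd.Timedelta(microseconds=1))
                   if e > s else weeks.week_index(e)
                   for s, e in merged)
        if n_weeks is not None:
            j_lo, j_hi = 0, n_weeks - 1
        for j in range(j_lo, j_hi + 1):
            w0, w1 = weeks.week_start(j), weeks.week_start(j + 1)
            days = 0.0
            for s, e in merged:
                lo, hi = max(s, w0), min(e, w1)
                if hi > lo:
                    days += (hi - lo) / pd.Timedelta(days=1)
            rows.append({"location": loc, "week": j, "camera_days": days})
    return pd.DataFrame(rows, columns=["location", "week", "camera_days"])


def weekly_counts(visits: pd.DataFrame, effort: pd.DataFrame,
                  weeks: WeekScheme,
                  count_mode: str = "group-size") -> pd.DataFrame:
    """Weekly response table y (location × week × species).

    y sums the per-visit group sizes of visits starting in each week
    (``count_mode="visits"`` counts visits instead). Weeks with positive
    effort but no visits appear with y = 0 for every species seen at that
    location; weeks with zero camera-days are excluded entirely. A visit in
    a zero-effort (or unlogged) location-week raises
    :class:`EffortInconsistencyError`.
    """
    if count_mode not in ("group-size", "visits"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    eff = effort[effort["camera_days"] > 0]
    eff_idx = set(zip(eff["location"], eff["week"]))

    v = visits.copy()
    v["week"] = [weeks.week_index(t) for t in v["start"]]
    for _, row in v.iterrows():
        if (row["location"], row["week"]) not in eff_idx:
            raise EffortInconsistencyError(
                f"visit at location {row['location']!r} in week "
                f"{row['week']} has no recorded camera effort")

    value = v["group_size"] if count_mode == "group-size" else 1
    v = v.assign(_y=value)
    sums = (v.groupby(["location", "week", "species"])["_y"].sum()
             .rename("y").reset_index())

    species = sorted(v["species"].unique())
    site_of = dict(zip(visits["location"], visits["site"]))
    full = pd.MultiIndex.from_tuples(
        [(loc, wk, sp) for (loc, wk) in sorted(eff_idx) for sp in species],
        names=["location", "week", "species"])
    table = (sums.set_index(["location", "week", "species"])
                 .reindex(full, fill_value=0).reset_index())
    table["y"] = table["y"].astype(int)
    table["site"] = table["location"].map(site_of)
    table["month"] = [weeks.month_of_week(j) for j in table["week"]]
    days = eff.set_index(["location", "week"])["camera_days"]
    table["camera_days"] = [days.loc[(l, w)] for l, w in
                            zip(table["location"], table["week"])]
    return table[["site", "location", "week", "species", "y", "month",
                  "camera_days"]]
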