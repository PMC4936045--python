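"""Telemetry preparation: quality filtering, analysis periods, clusters.

The analysis window runs from 1 May to each mother's end of monitoring:
the date of complete litter loss for unsuccessful mothers, and a randomly
assigned end date for successful mothers drawn from the density of
observed loss events, so the two groups cover comparable monitoring
periods.  The whole study period is truncated at the last observed loss
date.  Relocations with DOP >= 5 are removed before any spatial use is
computed.

Cluster sites (>= 3 consecutive fixes within 15 m of the running
centroid) mirror the field protocol used to locate cub remains; they are
provided for completeness and diagnostics, not used by the selection
models.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SEASON_START
from .telemetry import BearYearRecord

__all__ = [
    "ClusterSite",
    "PrepResult",
    "filter_dop",
    "compute_fix_rate",
    "welch_t_test",
    "assign_end_dates",
    "truncate_period",
    "detect_clusters",
    "prepare_records",
]

DOP_THRESHOLD = 5.0
MIN_MONITORED_DAYS = 2
MIN_RETAINED_FIXES = 50


def filter_dop(fixes: pd.DataFrame, threshold: float = DOP_THRESHOLD) -> pd.DataFrame:
    """Keep exactly the fixes with ``dop < threshold`` (boundary removed), order preserved."""
    if threshold <= 0:
        raise ValueError("DOP threshold must be positive")
    return fixes.loc[fixes["dop"] < threshold].reset_index(drop=True)


def compute_fix_rate(
    fixes: pd.DataFrame,
    period: tuple[dt.date, dt.date],
    schedule_minutes: int = 30,
) -> float:
    """Retained fixes divided by the number scheduled over the (closed) period."""
    start, end = period
    n_days = (end - start).days + 1
    if n_days <= 0:
        raise ValueError("period is empty")
    expected = n_days * (24 * 60) // schedule_minutes
    if expected == 0:
        raise ValueError("period shorter than one schedule interval")
    return len(fixes) / expected


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Unequal-variance two-sample t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Identical samples
    give t = 0, p = 1; degenerate (zero-variance) samples raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both samples have zero variance")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _silverman_bandwidth(days: np.ndarray) -> float:
    n = len(days)
    sd = days.std(ddof=1) if n > 1 else 0.0
    if sd == 0:
        return 0.0  # degenerate: all events on one day
    iqr = np.subtract(*np.percentile(days, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def assign_end_dates(
    successful,
    loss_events,
    season: tuple[dt.date, dt.date],
    seed,
) -> list[BearYearRecord]:
    """Randomly assign monitoring end dates to successful mothers.

    Dates are drawn from a Gaussian kernel-density estimate (Silverman
    bandwidth, day resolution) over the observed loss events, rejected and
    redrawn until they fall inside [season start, season truncation date].
    With a single loss event the density is degenerate and every end date
    equals that event.
    """
    if not loss_events:
        raise ValueError("no loss events to build the end-date density from")
    season_start, season_end = season
    rng = np.random.default_rng(seed)
    origin = season_start
    days = np.array([(d - origin).days for d in loss_events], dtype=float)
    h = _silverman_bandwidth(days)
    lo, hi = 0.0, float((season_end - origin).days)

    n = len(successful)
    drawn = np.empty(0, dtype=int)
    while len(drawn) < n:
        m = max(2 * (n - len(drawn)), 64)
        raw = rng.choice(days, m) + (rng.normal(0.0, h, m) if h > 0 else 0.0)
        day = np.round(raw)
        drawn = np.concatenate([drawn, day[(day >= lo) & (day <= hi)].astype(int)])
    return [
        replace(rec, end_date=origin + dt.timedelta(days=int(d)))
        for rec, d in zip(successful, drawn)
    ]


def truncate_period(
    record: BearYearRecord,
    truncation_date: dt.date,
    season_start: dt.date | None = None,
) -> BearYearRecord:
    """Restrict a bear-year's fixes to [1 May, its analysis end], day resolution.

    The end is the loss date (unsuccessful) or assigned end date
    (successful), never later than the study-wide ``truncation_date`` (the
    last observed loss).  Both interval ends are inclusive.  Mothers with
    partial litter loss are excluded (raises with that reason).
    """
    if record.fate == "partial_loss":
        raise ValueError("partial litter loss: record excluded from analysis")
    if season_start is None:
        season_start = dt.date(record.year, *SEASON_START)
    end = record.analysis_end
    if end is None:
        raise ValueError(f"{record.bear_id}/{record.year}: no loss or end date assigned")
    end = min(end, truncation_date)
    dates = record.fixes["timestamp"].dt.date
    keep = (dates >= season_start) & (dates <= end)
    return record.with_fixes(record.fixes.loc[keep])


@dataclass(frozen=True)
class ClusterSite:
    """A run of >= 3 consecutive fixes within 15 m of their running centroid."""

    bear_id: str
    year: int
    member_indices: tuple[int, ...]
    centroid: tuple[float, float]

    @property
    def size(self) -> int:
        return len(self.member_indices)


def detect_clusters(
    record: BearYearRecord,
    min_run: int = 3,
    radius: float = 15.0,
    about: str = "centroid",
) -> list[ClusterSite]:
    """Maximal non-overlapping runs of consecutive fixes forming cluster sites.

    ``about="centroid"`` (default): as the run extends, the centroid is
    recomputed and *every* member must remain within ``radius`` of it.
    ``about="first"``: members must lie within ``radius`` of the first fix.
    """
    if about not in ("centroid", "first"):
        raise ValueError("about must be 'centroid' or 'first'")
    xy = record.fixes[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    clusters: list[ClusterSite] = []
    i = 0
    while i < n:
        j = i + 1
        while j < n:
            cand = xy[i : j + 1]
            ref = cand.mean(axis=0) if about == "centroid" else xy[i]
            if np.hypot(*(cand - ref).T).max() <= radius:
                j += 1
            else:
                break
        run = xy[i:j]
        if len(run) >= min_run:
            ref = run.mean(axis=0) if about == "centroid" else xy[i]
            clusters.append(
                ClusterSite(
                    bear_id=record.bear_id,
                    year=record.year,
                    member_indices=tuple(range(i, j)),
                    centroid=(float(ref[0]), float(ref[1])),
                )
            )
            i = j
        else:
            i += 1
    return clusters


@dataclass
class PrepResult:
    """Analysis-ready bear-years plus the exclusion log."""

    records: list[BearYearRecord]
    excluded: pd.DataFrame  # columns: bear_id, year, reason
    truncation_date: dt.date
    season: tuple[dt.date, dt.date]


def prepare_records(
    bear_years,
    seed,
    dop_threshold: float = DOP_THRESHOLD,
    min_days: int = MIN_MONITORED_DAYS,
    min_fixes: int = MIN_RETAINED_FIXES,
) -> PrepResult:
    """Run the full preparation chain on raw bear-year records.

    DOP filter -> end-date randomization for successful mothers (from the
    observed loss events) -> season truncation -> minimum-data exclusions
    (too few monitored days or retained fixes).  Partial-loss mothers are
    excluded up front.  Seasons are aligned by calendar day across years.
    """
    excluded = []
    kept = []
    for rec in bear_years:
        if rec.fate == "partial_loss":
            excluded.append((rec.bear_id, rec.year, "partial litter loss"))
            continue
        kept.append(rec.with_fixes(filter_dop(rec.fixes, dop_threshold)))

    losses = [r for r in kept if r.fate == "lost"]
    if not losses:
        raise ValueError("no litter-loss events: cannot randomize end dates")
    loss_days = [(r.loss_date.month, r.loss_date.day) for r in losses]
    ref_year = 2000  # leap-safe alignment year for cross-year day arithmetic
    ref_events = [dt.date(ref_year, m, d) for m, d in loss_days]
    season_ref = (dt.date(ref_year, *SEASON_START), max(ref_events))
    truncation_md = max(loss_days, key=lambda md: (md[0], md[1]))

    successful = [r for r in kept if r.fate == "survived"]
    # draw on the reference year, then map the day back to each record's year
    drawn = assign_end_dates(successful, ref_events, season_ref, seed)
    survivors = []
    for rec in drawn:
        end = dt.date(rec.year, rec.end_date.month, rec.end_date.day)
        survivors.append(replace(rec, end_date=end))

    out_records = []
    for rec in survivors + losses:
        trunc = dt.date(rec.year, *truncation_md)
        rec = truncate_period(rec, trunc)
        n_days = rec.fixes["timestamp"].dt.date.nunique()
        if n_days < min_days:
            excluded.append((rec.bear_id, rec.year, f"monitored days {n_days} < {min_days}"))
            continue
        if rec.n_fixes < min_fixes:
            excluded.append((rec.bear_id, rec.year, f"retained fixes {rec.n_fixes} < {min_fixes}"))
            continue
        season = (dt.date(rec.year, *SEASON_START), dt.date(rec.year, *truncation_md))
        rec = replace(rec, fix_rate=compute_fix_rate(rec.fixes, (season[0], rec.analysis_end if rec.analysis_end <= season[1] else season[1])))
        out_records.append(rec)

    return PrepResult(
        records=out_records,
        excluded=pd.DataFrame(excluded, columns=["bear_id", "year", "reason"]),
        truncation_date=dt.date(ref_year, *truncation_md),
        season=season_ref,
    )
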