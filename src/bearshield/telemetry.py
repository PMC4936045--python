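"""Telemetry containers: GPS relocations and monitored mother-years.

Relocations are kept as pandas DataFrames with columns ``timestamp``
(datetime), ``x``, ``y`` (planar metres) and ``dop`` (dilution of
precision, unitless; larger = less precise).  A :class:`BearYearRecord`
bundles one mother's season: identity, year, litter fate, the dated loss
(or assigned end date), and her relocations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = ["FIX_COLUMNS", "BearYearRecord", "records_to_frame", "frame_to_records"]

FIX_COLUMNS = ("timestamp", "x", "y", "dop")

#: Litter fates.  ``partial_loss`` records are excluded from analysis.
FATES = ("survived", "lost", "partial_loss")


@dataclass
class BearYearRecord:
    """One monitored mother-year."""

    bear_id: str
    year: int
    fixes: pd.DataFrame
    fate: str | None = None
    loss_date: dt.date | None = None  # set for fate == "lost"
    end_date: dt.date | None = None  # assigned for fate == "survived"
    fix_rate: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FIX_COLUMNS if c not in self.fixes.columns]
        if missing:
            raise ValueError(f"fixes missing columns {missing}")
        if self.fate is not None and self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.fate == "lost" and self.loss_date is None:
            raise ValueError("fate 'lost' requires a loss_date")
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be non-decreasing within a bear-year")
        if len(self.fixes) and (self.fixes["dop"] <= 0).any():
            raise ValueError("DOP values must be positive")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def analysis_end(self) -> dt.date | None:
        """Loss date for unsuccessful mothers, assigned end date for successful."""
        return self.loss_date if self.fate == "lost" else self.end_date

    def with_fixes(self, fixes: pd.DataFrame) -> "BearYearRecord":
        return replace(self, fixes=fixes.reset_index(drop=True))


def records_to_frame(records) -> pd.DataFrame:
    """Flatten bear-year records into one relocation table (CSV-ready)."""
    frames = []
    for rec in records:
        f = rec.fixes.copy()
        f.insert(0, "bear_id", rec.bear_id)
        f.insert(1, "year", rec.year)
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["bear_id", "year", *FIX_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def frame_to_records(frame: pd.DataFrame, fates: pd.DataFrame | None = None):
    """Group a flat relocation table back into BearYearRecords.

    ``fates``, if given, has columns bear_id, year, fate, loss_date and is
    merged on (bear_id, year).
    """
    fate_map = {}
    if fates is not None:
        for row in fates.itertuples(index=False):
            loss = getattr(row, "loss_date", None)
            if pd.isna(loss):
                loss = None
            elif isinstance(loss, str):
                loss = dt.date.fromisoformat(loss)
            elif isinstance(loss, pd.Timestamp):
                loss = loss.date()
            fate_map[(row.bear_id, int(row.year))] = (row.fate, loss)
    records = []
    for (bear_id, year), grp in frame.groupby(["bear_id", "year"], sort=True):
        fate, loss = fate_map.get((bear_id, int(year)), (None, None))
        records.append(
            BearYearRecord(
                bear_id=str(bear_id),
                year=int(year),
                fixes=grp[list(FIX_COLUMNS)].reset_index(drop=True),
                fate=fate,
                loss_date=loss,
            )
        )
    return records
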