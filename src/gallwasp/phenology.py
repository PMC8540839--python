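"""Adult flight phenology from interval-exposed sticky-trap catches.

Yellow adhesive traps are deployed on trees and replaced every 3–4 days
through the flight season (June–August).  Each replacement yields one
interval-censored count per trap.  This module converts those records into

* a per-interval **daily catch rate** — mean count across the traps present
  in the interval, divided by the exposure in days, stamped at the interval
  midpoint;
* the **seasonal total per trap** — season-wide sum of counts divided by the
  number of distinct traps;
* the **flight window** — start (deploy date of the first interval with a
  catch), peak (midpoint of the maximum-rate interval, earliest on ties) and
  end (collect date of the last interval with a catch).  An all-zero season
  has an undefined window.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LookupError_, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["FlightSummary", "catch_rates", "seasonal_total", "flight_window", "summarize_flight"]

_REQUIRED_COLS = ("locality", "year", "tree", "trap", "deploy_date", "collect_date", "count")


@dataclass(frozen=True)
class FlightSummary:
    """Season-level flight summary for one locality-year."""

    locality_id: str
    year: int
    rates: pd.DataFrame = field(repr=False)
    total_per_trap: float = 0.0
    start_date: datetime.date | None = None
    peak_date: datetime.date | None = None
    end_date: datetime.date | None = None

    @property
    def defined(self) -> bool:
        return self.peak_date is not None


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in records.columns]
    if missing:
        raise SchemaError(f"trap records missing columns: {missing}")
    rec = records.copy()
    rec["deploy_date"] = pd.to_datetime(rec["deploy_date"])
    rec["collect_date"] = pd.to_datetime(rec["collect_date"])
    if (rec["collect_date"] <= rec["deploy_date"]).any():
        bad = rec[rec["collect_date"] <= rec["deploy_date"]].iloc[0]
        raise SchemaError(
            f"non-positive trap exposure: deploy {bad['deploy_date'].date()} "
            f">= collect {bad['collect_date'].date()}"
        )
    if (rec["count"] < 0).any():
        raise SchemaError("trap counts must be non-negative")
    return rec


def _select(records: pd.DataFrame, locality: str, year: int) -> pd.DataFrame:
    rec = _validate(records)
    sel = rec[(rec["locality"] == locality) & (rec["year"] == year)]
    if sel.empty:
        raise LookupError_(f"no trap records for ({locality}, {year})")
    return sel


def catch_rates(records: pd.DataFrame, locality: str, year: int) -> pd.DataFrame:
    """Per-interval daily catch rates for one locality-year.

    Returns one row per collection interval with columns ``deploy_date``,
    ``collect_date``, ``midpoint`` (interval midpoint timestamp),
    ``exposure_days``, ``n_traps`` (traps actually present), ``mean_count``
    and ``rate`` (individuals per trap per day), ordered by interval.
    """
    sel = _select(records, locality, year)
    n_design = sel.groupby(["tree", "trap"]).ngroups
    rows = []
    for (dep, col), grp in sel.groupby(["deploy_date", "collect_date"], sort=True):
        exposure = (col - dep).days
        n_traps = grp.groupby(["tree", "trap"]).ngroups
        if n_traps < n_design:
            logger.info(
                "%s %s interval %s–%s: %d of %d traps present",
                locality, year, dep.date(), col.date(), n_traps, n_design,
            )
        mean_count = grp["count"].sum() / n_traps
        rows.append(
            {
                "deploy_date": dep.date(),
                "collect_date": col.date(),
                "midpoint": dep + (col - dep) / 2,
                "exposure_days": exposure,
                "n_traps": n_traps,
                "mean_count": mean_count,
                "rate": mean_count / exposure,
            }
        )
    return pd.DataFrame(rows)


def seasonal_total(records: pd.DataFrame, locality: str, year: int) -> float:
    """Total individuals per trap over the season: Σ counts / #distinct traps."""
    sel = _select(records, locality, year)
    n_traps = sel.groupby(["tree", "trap"]).ngroups
    return float(sel["count"].sum() / n_traps)


def flight_window(
    rates: pd.DataFrame,
) -> tuple[datetime.date | None, datetime.date | None, datetime.date | None]:
    """(start, peak, end) of the flight period from a rate series.

    Start is the deploy date of the first interval with a nonzero catch, end
    the collect date of the last such interval, and the peak is the midpoint
    of the maximum-rate interval (earliest interval on ties).  All three are
    None when every interval caught nothing.
    """
    nz = rates[rates["mean_count"] > 0]
    if nz.empty:
        return (None, None, None)
    start = nz.iloc[0]["deploy_date"]
    end = nz.iloc[-1]["collect_date"]
    peak_idx = int(np.argmax(nz["rate"].to_numpy()))  # argmax takes first maximum
    peak = pd.Timestamp(nz.iloc[peak_idx]["midpoint"]).date()
    return (start, peak, end)


def summarize_flight(records: pd.DataFrame, locality: str, year: int) -> FlightSummary:
    """Full seasonal summary: rates, total per trap and the flight window."""
    rates = catch_rates(records, locality, year)
    start, peak, end = flight_window(rates)
    return FlightSummary(
        locality_id=locality,
        year=int(year),
        rates=rates,
        total_per_trap=seasonal_total(records, locality, year),
        start_date=start,
        peak_date=peak,
        end_date=end,
    )
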