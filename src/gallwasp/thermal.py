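"""Locality temperature estimation and cumulative-degree accumulation.

Daily mean temperatures are rarely measured at every study site.  Instead, a
single well-maintained reference station provides a daily record, and each
locality is characterised by its historical monthly normals (e.g. from a
1 km² climate atlas).  The downscaling used here is the classic *delta*
(anomaly) method: for each calendar month, the offset between a locality's
historical monthly normal and the reference station's normal is added to the
station's daily record.  The result is a locality-level daily series sharing
the station's day-to-day variability but shifted to the locality's thermal
regime.

Physiological time is tracked as *cumulative °C*: the running sum of daily
mean temperatures from a season-specific anchor date (by convention, the
previous season's adult flight peak).  The accumulation window is half-open,
``(anchor, target]`` — the anchor day itself does not contribute.  No lower
development threshold is subtracted by default; an optional base temperature
is available for conventional degree-day accounting.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "LocalityNormals",
    "DailySeries",
    "AnomalyProfile",
    "DegreeAccumulation",
    "monthly_anomalies",
    "downscale_daily",
    "season_anchor",
    "cumulative_degrees",
    "degree_accumulation",
]


@dataclass(frozen=True)
class LocalityNormals:
    """Historical monthly and annual mean temperatures of one locality.

    Parameters
    ----------
    locality_id : str
        Locality name or station code.
    monthly_mean : tuple of 12 floats
        Historical monthly mean temperature, January..December, °C.
    annual_mean : float
        Historical annual mean temperature, °C.  Must lie within the range
        of the monthly means.
    """

    locality_id: str
    monthly_mean: tuple[float, ...]
    annual_mean: float

    def __post_init__(self) -> None:
        if len(self.monthly_mean) != 12:
            raise SchemaError(
                f"{self.locality_id}: expected 12 monthly means, "
                f"got {len(self.monthly_mean)}"
            )
        vals = np.asarray(self.monthly_mean, dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0]) + 1
            raise SchemaError(f"{self.locality_id}: non-finite normal for month {bad}")
        if not (vals.min() - 1e-9 <= self.annual_mean <= vals.max() + 1e-9):
            raise SchemaError(
                f"{self.locality_id}: annual mean {self.annual_mean} outside "
                f"monthly range [{vals.min()}, {vals.max()}]"
            )
        object.__setattr__(self, "monthly_mean", tuple(float(v) for v in vals))


@dataclass
class DailySeries:
    """A calendar-contiguous daily mean temperature record for one locality.

    ``values`` is a pandas Series of °C indexed by a daily ``DatetimeIndex``
    with no gaps.
    """

    locality_id: str
    values: pd.Series

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.values.index)
        if len(idx) == 0:
            raise SchemaError(f"{self.locality_id}: empty daily series")
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise SchemaError(f"{self.locality_id}: dates must strictly increase")
        deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            gap = idx[int(np.flatnonzero(deltas != 1)[0])]
            raise SchemaError(f"{self.locality_id}: gap in daily series after {gap.date()}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise SchemaError(f"{self.locality_id}: non-finite temperature value")
        self.values = pd.Series(
            self.values.to_numpy(dtype=float), index=idx, name="tmean"
        )

    @property
    def start(self) -> datetime.date:
        return self.values.index[0].date()

    @property
    def end(self) -> datetime.date:
        return self.values.index[-1].date()

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame with columns (locality, date, tmean)."""
        return pd.DataFrame(
            {
                "locality": self.locality_id,
                "date": self.values.index.date,
                "tmean": self.values.to_numpy(),
            }
        )


@dataclass(frozen=True)
class AnomalyProfile:
    """Monthly temperature offsets of a locality relative to the reference."""

    locality_id: str
    monthly_offset: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.monthly_offset) != 12:
            raise SchemaError(
                f"{self.locality_id}: expected 12 offsets, got {len(self.monthly_offset)}"
            )
        vals = np.asarray(self.monthly_offset, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise SchemaError(f"{self.locality_id}: non-finite monthly offset")
        object.__setattr__(self, "monthly_offset", tuple(float(v) for v in vals))


@dataclass
class DegreeAccumulation:
    """Cumulative °C from a season anchor, one value per subsequent day.

    Entries start the day *after* ``anchor_date`` (half-open accumulation
    window); each entry is the sum of daily means from anchor+1 through that
    day.
    """

    locality_id: str
    season: str
    anchor_date: datetime.date
    entries: pd.Series = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locality": self.locality_id,
                "season": self.season,
                "date": self.entries.index.date,
                "cum_degc": self.entries.to_numpy(),
            }
        )


def monthly_anomalies(
    locality: LocalityNormals, reference: LocalityNormals
) -> AnomalyProfile:
    """Monthly delta of a locality's normals relative to the reference station.

    ``offset[m] = locality.monthly_mean[m] − reference.monthly_mean[m]``.
    """
    offsets = tuple(
        l - r for l, r in zip(locality.monthly_mean, reference.monthly_mean)
    )
    return AnomalyProfile(locality_id=locality.locality_id, monthly_offset=offsets)


def downscale_daily(reference_series: DailySeries, anomaly: AnomalyProfile) -> DailySeries:
    """Estimate a locality's daily means by adding its monthly delta to the
    reference station's record.

    Each day receives the offset of its calendar month; no smoothing is
    applied across month boundaries.
    """
    months = pd.DatetimeIndex(reference_series.values.index).month
    offsets = np.asarray(anomaly.monthly_offset, dtype=float)[months - 1]
    shifted = reference_series.values.to_numpy() + offsets
    return DailySeries(
        locality_id=anomaly.locality_id,
        values=pd.Series(shifted, index=reference_series.values.index),
    )


def season_anchor(previous_flight, fallback_date: datetime.date) -> datetime.date:
    """Anchor date for a season's degree accumulation.

    Returns the previous season's flight-peak date when one is available;
    otherwise the configured fallback (default convention: 1 July of the
    prior year, since adult flight spans late spring to mid-summer).
    Accumulation starts the day after the returned anchor.

    Parameters
    ----------
    previous_flight : object with a ``peak_date`` attribute, or None
        Typically a :class:`gallwasp.phenology.FlightSummary`.
    fallback_date : datetime.date
        Used when no previous season exists or its peak is undefined.
    """
    if previous_flight is None:
        return fallback_date
    peak = getattr(previous_flight, "peak_date", None)
    if peak is None:
        logger.warning(
            "previous season has no defined flight peak (no catches); "
            "falling back to %s",
            fallback_date,
        )
        return fallback_date
    return _as_date(peak)


def _as_date(d) -> datetime.date:
    if isinstance(d, datetime.datetime):
        return d.date()
    if isinstance(d, datetime.date):
        return d
    return pd.Timestamp(d).date()


def cumulative_degrees(
    series: DailySeries,
    anchor_date: datetime.date,
    target_date: datetime.date,
    base_temp: float = 0.0,
) -> float:
    """Cumulative °C over the half-open window ``(anchor, target]``.

    Sums the raw daily mean temperatures of every day strictly after
    ``anchor_date`` up to and including ``target_date``.  With the default
    ``base_temp=0`` no threshold is applied and negative daily means are
    summed as-is; with ``base_temp > 0`` each day contributes
    ``max(tmean − base_temp, 0)`` (conventional degree-days).
    """
    anchor_date = _as_date(anchor_date)
    target_date = _as_date(target_date)
    if target_date <= anchor_date:
        raise DomainError(
            f"target date {target_date} must be after anchor date {anchor_date}"
        )
    if anchor_date < series.start or target_date > series.end:
        raise CoverageError(
            f"window ({anchor_date}, {target_date}] not covered by series "
            f"[{series.start}, {series.end}] for {series.locality_id}"
        )
    window = series.values.loc[
        pd.Timestamp(anchor_date) + pd.Timedelta(days=1) : pd.Timestamp(target_date)
    ]
    vals = window.to_numpy()
    if base_temp > 0.0:
        vals = np.clip(vals - base_temp, 0.0, None)
    return float(vals.sum())


def degree_accumulation(
    series: DailySeries,
    anchor_date: datetime.date,
    season: str,
    end_date: datetime.date | None = None,
    base_temp: float = 0.0,
) -> DegreeAccumulation:
    """Daily cumulative-°C trajectory from an anchor through ``end_date``.

    Convenience wrapper producing one cumulative value per day after the
    anchor (consistent with :func:`cumulative_degrees` at every date).
    """
    anchor_date = _as_date(anchor_date)
    end_date = series.end if end_date is None else _as_date(end_date)
    if anchor_date < series.start or anchor_date >= series.end:
        raise CoverageError(
            f"anchor {anchor_date} leaves no accumulation days within series "
            f"[{series.start}, {series.end}]"
        )
    window = series.values.loc[
        pd.Timestamp(anchor_date) + pd.Timedelta(days=1) : pd.Timestamp(end_date)
    ]
    vals = window.to_numpy()
    if base_temp > 0.0:
        vals = np.clip(vals - base_temp, 0.0, None)
    return DegreeAccumulation(
        locality_id=series.locality_id,
        season=season,
        anchor_date=anchor_date,
        entries=pd.Series(np.cumsum(vals), index=window.index, name="cum_degc"),
    )
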