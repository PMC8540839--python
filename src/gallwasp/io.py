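"""CSV readers and writers for the pipeline's tabular interfaces.

Schemas
-------
locality normals : locality, month_01..month_12, annual_mean
reference daily  : date, tmean
dissections      : locality, cohort, date, bud_id, egg, l1, l2, l3, pupa, adult
traps            : locality, year, tree, trap, deploy_date, collect_date, count
sprouts          : locality, year, tree, sprout, galls
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .lifetables import STAGES
from .thermal import DailySeries, LocalityNormals

__all__ = [
    "read_normals_csv",
    "read_daily_csv",
    "read_dissections_csv",
    "read_traps_csv",
    "read_sprouts_csv",
]

_MONTH_COLS = [f"month_{m:02d}" for m in range(1, 13)]


def _require(frame: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_normals_csv(path: str | Path) -> dict[str, LocalityNormals]:
    """Locality normals keyed by locality id."""
    frame = pd.read_csv(path)
    _require(frame, ["locality", "annual_mean", *_MONTH_COLS], path)
    return {
        row["locality"]: LocalityNormals(
            locality_id=row["locality"],
            monthly_mean=tuple(float(row[c]) for c in _MONTH_COLS),
            annual_mean=float(row["annual_mean"]),
        )
        for _, row in frame.iterrows()
    }


def read_daily_csv(path: str | Path, locality_id: str = "reference") -> DailySeries:
    """A daily mean-temperature series (columns ``date``, ``tmean``)."""
    frame = pd.read_csv(path)
    _require(frame, ["date", "tmean"], path)
    idx = pd.to_datetime(frame["date"])
    return DailySeries(locality_id=locality_id, values=pd.Series(frame["tmean"].to_numpy(), index=idx))


def read_dissections_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require(frame, ["locality", "cohort", "date", "bud_id", *STAGES], path)
    return frame


def read_traps_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require(
        frame,
        ["locality", "year", "tree", "trap", "deploy_date", "collect_date", "count"],
        path,
    )
    return frame


def read_sprouts_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require(frame, ["locality", "year", "tree", "sprout", "galls"], path)
    return frame
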