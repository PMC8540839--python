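"""Tree-damage metrics from per-sprout gall counts.

Sprouts produced in the previous vegetative period are the gall wasp's most
frequently attacked organ, so per-sprout gall counts sampled in mid-autumn
index the level of infestation.  Two tree-level metrics are computed:

* ``infested_fraction`` — share of sampled sprouts carrying at least one
  gall (the paper-style "rate of sprouts with galls");
* ``mean_galls_per_sprout`` — mean gall count over *all* sampled sprouts,
  zeros included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LookupError_, SchemaError

__all__ = ["DamageSummary", "damage_summary", "damage_panel"]

_REQUIRED_COLS = ("locality", "year", "tree", "sprout", "galls")


@dataclass(frozen=True)
class DamageSummary:
    """Per-tree damage metrics for one locality-year."""

    locality_id: str
    year: int
    tree_id: str
    n_sprouts: int
    infested_fraction: float
    mean_galls_per_sprout: float


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in records.columns]
    if missing:
        raise SchemaError(f"sprout records missing columns: {missing}")
    if (records["galls"] < 0).any():
        raise SchemaError("gall counts must be non-negative")
    return records


def damage_summary(
    records: pd.DataFrame, locality: str, year: int, tree: str
) -> DamageSummary:
    """Damage metrics for one tree; raises on an empty (locality, year, tree)."""
    rec = _validate(records)
    sel = rec[
        (rec["locality"] == locality) & (rec["year"] == year) & (rec["tree"] == tree)
    ]
    if sel.empty:
        raise LookupError_(f"no sprout records for ({locality}, {year}, {tree})")
    galls = sel["galls"].to_numpy(dtype=float)
    return DamageSummary(
        locality_id=locality,
        year=int(year),
        tree_id=str(tree),
        n_sprouts=len(galls),
        infested_fraction=float((galls > 0).mean()),
        mean_galls_per_sprout=float(galls.mean()),
    )


def damage_panel(records: pd.DataFrame) -> pd.DataFrame:
    """Tree-level damage table: one row per (locality, year, tree).

    Sprout identity is keyed by (tree, sprout), so duplicated sprout ids on
    different trees stay distinct.  The frame is ready as response data for
    the inference layer (columns ``locality``, ``year``, ``tree``,
    ``n_sprouts``, ``infested_fraction``, ``mean_galls_per_sprout``).
    """
    rec = _validate(records)
    grouped = rec.groupby(["locality", "year", "tree"], sort=True)["galls"]
    out = grouped.agg(
        n_sprouts="size",
        infested_fraction=lambda g: float((g > 0).mean()),
        mean_galls_per_sprout="mean",
    ).reset_index()
    out["n_sprouts"] = out["n_sprouts"].astype(int)
    return out
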