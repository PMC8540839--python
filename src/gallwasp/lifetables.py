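"""Stage profiles, survival schedules and age-specific life tables.

The chestnut gall wasp is parthenogenetic and univoltine: a cohort of eggs
laid in one summer develops through three larval instars (L1 overwinters in
the infested bud), pupates inside the gall, and emerges as adult females the
following summer.  Cross-sectional bud dissections at successive sampling
dates give per-bud counts of each stage {egg, L1, L2, L3, pupa, adult}.

From those counts this module derives:

* per-sampling **stage profiles** (mean individuals per bud and relative
  stage abundances),
* a **survival schedule** — one survival probability per stage transition,
  estimated as the ratio of successive stage-wise peak densities (stages
  overlap in time, so the across-date peak of a stage's per-bud density
  approximates the total number that ever reached that stage),
* an **age-specific life table** (survivorship l_x, fecundity b_x) and the
  classical population parameters:

  - net reproduction rate  R0 = Σ l_x·b_x
  - generation time        T
  - intrinsic rate of increase  r = ln R0 / T
  - finite rate of change  λ = N_{t+1}/N_t = e^{rΔt}

R0 > 1 (equivalently r > 0, λ > 1) indicates an increasing population;
R0 = 1 a stationary one; R0 < 1 a declining one.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, LookupError_, SchemaError

logger = logging.getLogger(__name__)

#: Ordered development stages; index doubles as the stage score used by
#: :func:`mean_development_stage` (egg=0 ... adult=5).
STAGES: tuple[str, ...] = ("egg", "l1", "l2", "l3", "pupa", "adult")

#: Stage transitions, in order.
TRANSITIONS: tuple[str, ...] = (
    "egg_to_l1",
    "l1_to_l2",
    "l2_to_l3",
    "l3_to_pupa",
    "pupa_to_adult",
)

#: Default age (years since oviposition) at which each stage is reached, for
#: a univoltine calendar: eggs laid in summer, hatching ~1 month later, L1
#: overwintering until spring bud burst, later instars/pupa through late
#: spring, adults ~1 year after oviposition.
DEFAULT_STAGE_AGES: tuple[float, ...] = (0.0, 1 / 12, 0.75, 0.83, 0.92, 1.0)

__all__ = [
    "STAGES",
    "TRANSITIONS",
    "DEFAULT_STAGE_AGES",
    "StageProfile",
    "SurvivalSchedule",
    "PopulationParameters",
    "stage_profile",
    "stage_profiles",
    "mean_development_stage",
    "transition_survivals",
    "build_life_table",
    "population_parameters",
    "params_from_growth_rate",
    "classify_trend",
]


@dataclass(frozen=True)
class StageProfile:
    """Per-bud stage composition of one (locality, cohort, sampling date).

    ``mean_per_bud[s]`` is the total count of stage *s* divided by the number
    of dissected buds; ``relative_abundance`` is each stage's share of the
    grand total (all zeros, with ``undefined=True``, when no individuals were
    found).
    """

    locality_id: str
    cohort_year: int
    sampling_date: datetime.date
    mean_per_bud: tuple[float, ...]
    relative_abundance: tuple[float, ...]
    n_buds: int
    undefined: bool = False

    @property
    def grand_total_per_bud(self) -> float:
        return float(sum(self.mean_per_bud))


@dataclass(frozen=True)
class SurvivalSchedule:
    """Per-transition survival probabilities and total egg-to-adult survival.

    ``capped`` flags transitions whose raw peak ratio exceeded 1 (sampling
    noise) and was truncated to 1.
    """

    transitions: tuple[float, ...]
    total: float
    capped: tuple[bool, ...] = (False,) * 5

    def __post_init__(self) -> None:
        if len(self.transitions) != len(TRANSITIONS):
            raise SchemaError(
                f"expected {len(TRANSITIONS)} transition survivals, "
                f"got {len(self.transitions)}"
            )
        for name, p in zip(TRANSITIONS, self.transitions):
            if not (0.0 <= p <= 1.0):
                raise DomainError(f"survival {name}={p} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        d = dict(zip(TRANSITIONS, self.transitions))
        d["egg_to_adult"] = self.total
        return d


@dataclass(frozen=True)
class PopulationParameters:
    """Life-table population parameters and the implied trend."""

    R0: float
    T: float
    r: float
    lam: float
    trend: str
    N_t: float | None = None
    N_t1: float | None = None
    degenerate: bool = False

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Reporting convention: two decimals."""
        return {
            "R0": round(self.R0, ndigits),
            "T": round(self.T, ndigits) if math.isfinite(self.T) else self.T,
            "r": round(self.r, ndigits),
            "lambda": round(self.lam, ndigits),
        }


_REQUIRED_COLS = ("locality", "cohort", "date", "bud_id") + STAGES


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in records.columns]
    if missing:
        raise SchemaError(f"dissection records missing columns: {missing}")
    counts = records[list(STAGES)].to_numpy()
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise SchemaError("stage counts must be non-negative integers")
    return records


def stage_profile(
    records: pd.DataFrame,
    locality: str,
    cohort: int,
    date: datetime.date,
) -> StageProfile:
    """Stage profile for one (locality, cohort, sampling date) key.

    Raises :class:`~gallwasp.errors.LookupError_` when the key selects no
    records.  A grand total of zero individuals yields all-zero relative
    abundances with ``undefined=True``.
    """
    records = _validate_records(records)
    date = pd.Timestamp(date).date()
    sel = records[
        (records["locality"] == locality)
        & (records["cohort"] == cohort)
        & (pd.to_datetime(records["date"]).dt.date == date)
    ]
    if sel.empty:
        raise LookupError_(f"no dissection records for ({locality}, {cohort}, {date})")
    n_buds = sel["bud_id"].nunique()
    totals = sel[list(STAGES)].sum().to_numpy(dtype=float)
    mean_per_bud = totals / n_buds
    grand = totals.sum()
    if grand > 0:
        rel = totals / grand
        undefined = False
    else:
        rel = np.zeros(len(STAGES))
        undefined = True
    return StageProfile(
        locality_id=locality,
        cohort_year=int(cohort),
        sampling_date=date,
        mean_per_bud=tuple(mean_per_bud),
        relative_abundance=tuple(rel),
        n_buds=int(n_buds),
        undefined=undefined,
    )


def stage_profiles(
    records: pd.DataFrame, locality: str, cohort: int
) -> list[StageProfile]:
    """All per-date stage profiles of one locality-cohort, date-ordered."""
    records = _validate_records(records)
    sel = records[(records["locality"] == locality) & (records["cohort"] == cohort)]
    if sel.empty:
        raise LookupError_(f"no dissection records for ({locality}, {cohort})")
    dates = sorted(pd.to_datetime(sel["date"]).dt.date.unique())
    return [stage_profile(records, locality, cohort, d) for d in dates]


def mean_development_stage(profile: StageProfile) -> float:
    """Abundance-weighted mean stage index (egg=0 ... adult=5)."""
    if profile.undefined or profile.grand_total_per_bud == 0:
        raise DomainError(
            f"mean development stage undefined for {profile.locality_id} "
            f"{profile.sampling_date}: no individuals observed"
        )
    idx = np.arange(len(STAGES), dtype=float)
    return float(idx @ np.asarray(profile.relative_abundance))


def transition_survivals(profiles: Sequence[StageProfile]) -> SurvivalSchedule:
    """Estimate per-transition survivals from a date-ordered profile sequence.

    The survival of transition s→s+1 is the ratio of the across-date peak
    per-bud density of stage s+1 to that of stage s.  Ratios above 1
    (sampling noise) are capped at 1 and flagged.  The total egg-to-adult
    survival is the product of the five transition survivals.
    """
    if len(profiles) < 2:
        raise DomainError("need stage profiles from at least two sampling dates")
    peaks = np.max(
        [np.asarray(p.mean_per_bud, dtype=float) for p in profiles], axis=0
    )
    if peaks[0] <= 0:
        raise DomainError("egg stage never observed: survival schedule undefined")
    survivals: list[float] = []
    capped: list[bool] = []
    for s in range(len(STAGES) - 1):
        if peaks[s] == 0:
            # earlier stage never observed: downstream survival unidentifiable
            survivals.append(0.0)
            capped.append(False)
            logger.warning(
                "stage %s never observed for %s cohort %s; transition %s set to 0",
                STAGES[s],
                profiles[0].locality_id,
                profiles[0].cohort_year,
                TRANSITIONS[s],
            )
            continue
        ratio = peaks[s + 1] / peaks[s]
        if ratio > 1.0:
            logger.warning(
                "raw survival ratio %.3f > 1 for %s; capped at 1",
                ratio,
                TRANSITIONS[s],
            )
            survivals.append(1.0)
            capped.append(True)
        else:
            survivals.append(float(ratio))
            capped.append(False)
    total = float(np.prod(survivals))
    return SurvivalSchedule(
        transitions=tuple(survivals), total=total, capped=tuple(capped)
    )


def build_life_table(
    schedule: SurvivalSchedule,
    fecundity: float,
    stage_ages: Sequence[float] = DEFAULT_STAGE_AGES,
) -> pd.DataFrame:
    """Age-specific life table from a survival schedule and adult fecundity.

    Returns a frame with one row per stage: ``x`` (stage index), ``stage``,
    ``age`` (years since oviposition), ``lx`` (cumulative survivorship,
    l_0 = 1) and ``bx`` (offspring per individual; concentrated at the adult
    stage of this parthenogenetic univoltine species).
    """
    if fecundity < 0:
        raise DomainError(f"fecundity {fecundity} must be >= 0")
    ages = np.asarray(list(stage_ages), dtype=float)
    if len(ages) != len(STAGES):
        raise SchemaError(f"expected {len(STAGES)} stage ages, got {len(ages)}")
    if np.any(np.diff(ages) < 0):
        raise DomainError("stage ages must be non-decreasing")
    lx = np.concatenate([[1.0], np.cumprod(schedule.transitions)])
    bx = np.zeros(len(STAGES))
    bx[-1] = fecundity
    return pd.DataFrame(
        {
            "x": np.arange(len(STAGES)),
            "stage": STAGES,
            "age": ages,
            "lx": lx,
            "bx": bx,
        }
    )


def classify_trend(R0: float, tol: float = 0.0) -> str:
    """Population trend from the net reproduction rate."""
    if R0 > 1.0 + tol:
        return "increasing"
    if R0 < 1.0 - tol:
        return "declining"
    return "stationary"


def population_parameters(
    table: pd.DataFrame,
    N_t: float | None = None,
    N_t1: float | None = None,
    delta_t: float = 1.0,
) -> PopulationParameters:
    """Population parameters (R0, T, r, λ) from a life table.

    Two derivation chains are supported:

    * **census chain** (both ``N_t`` and ``N_t1`` given, eggs per bud at
      successive annual censuses): λ = N_{t+1}/N_t, r = ln λ / Δt, and the
      generation time is recovered as T = ln R0 / r.
    * **life-table chain** (censuses absent): T = Σ x·l_x·b_x / Σ l_x·b_x
      (ages in years), r = ln R0 / T, λ = e^{rΔt}.

    Either way R0 = Σ l_x·b_x, and the trend is classified by R0 against 1.
    A cohort with R0 = 0 is returned as degenerate (r = −inf, λ = 0,
    T undefined).
    """
    for col in ("age", "lx", "bx"):
        if col not in table.columns:
            raise SchemaError(f"life table missing column {col!r}")
    lx = table["lx"].to_numpy(dtype=float)
    bx = table["bx"].to_numpy(dtype=float)
    ages = table["age"].to_numpy(dtype=float)
    if np.any((lx < 0) | (lx > 1)) or np.any(np.diff(lx) > 1e-12):
        raise DomainError("lx must be non-increasing within [0, 1]")
    if np.any(bx < 0):
        raise DomainError("bx must be non-negative")

    R0 = float(lx @ bx)
    if R0 == 0.0:
        logger.warning("R0 = 0: degenerate cohort, population parameters limiting")
        return PopulationParameters(
            R0=0.0,
            T=math.nan,
            r=-math.inf,
            lam=0.0,
            trend="declining",
            N_t=N_t,
            N_t1=N_t1,
            degenerate=True,
        )

    if N_t is not None and N_t1 is not None:
        if N_t <= 0:
            raise DomainError(f"census density N_t={N_t} must be > 0")
        lam = N_t1 / N_t
        if lam <= 0:
            raise DomainError(f"census ratio lambda={lam} must be > 0")
        r = math.log(lam) / delta_t
        T = math.log(R0) / r if r != 0.0 else math.nan
    else:
        T = float((ages * lx * bx).sum() / R0)
        if T <= 0:
            raise DomainError(f"generation time T={T} must be > 0")
        r = math.log(R0) / T
        lam = math.exp(r * delta_t)

    return PopulationParameters(
        R0=R0, T=T, r=r, lam=lam, trend=classify_trend(R0), N_t=N_t, N_t1=N_t1
    )


def params_from_growth_rate(
    r: float, R0: float | None = None, delta_t: float = 1.0
) -> PopulationParameters:
    """Population parameters implied by an intrinsic rate of increase.

    Useful for desk calculations from published point values: λ = e^{rΔt};
    if R0 is supplied, the generation time follows as T = ln R0 / r
    (undefined when r = 0, where R0 must equal 1).
    """
    lam = math.exp(r * delta_t)
    if R0 is None:
        # with T unknown only the sign of r classifies the trend
        R0_implied = math.nan
        T = math.nan
        trend = "increasing" if r > 0 else ("declining" if r < 0 else "stationary")
        return PopulationParameters(R0=R0_implied, T=T, r=r, lam=lam, trend=trend)
    if R0 <= 0:
        raise DomainError(f"R0={R0} must be > 0")
    T = math.log(R0) / r if r != 0.0 else math.nan
    return PopulationParameters(R0=R0, T=T, r=r, lam=lam, trend=classify_trend(R0))


def census_density(
    records: pd.DataFrame, locality: str, cohort: int
) -> float:
    """Cohort census density N_t: eggs per bud at the cohort's first sampling.

    Eggs are the cohort's birth class, so the first sampling's egg density is
    the natural census for the finite-rate chain λ = N_{t+1}/N_t.
    """
    profiles = stage_profiles(records, locality, cohort)
    return profiles[0].mean_per_bud[0]
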