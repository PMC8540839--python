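"""Seeded synthetic field data with the structure the analysis assumes.

No raw field data are distributed with the study this pipeline serves, so
every input is emulated here with the generating process the analysis
presumes:

* **reference temperatures** — a sinusoidal annual cycle plus Gaussian
  day-to-day noise at a reference station; locality series follow by the
  monthly-delta downscaling of :mod:`gallwasp.thermal`;
* **bud dissections** — a univoltine cohort whose individuals advance one
  stage whenever cumulative °C since oviposition crosses the next threshold,
  surviving each transition with a configured Bernoulli probability;
  fortnightly destructive samplings slice the latent cohort into observed
  per-bud stage counts;
* **trap catches** — adult emergence centred on the day cumulative °C (from
  the previous season's anchor) crosses an emergence threshold, with a
  Gaussian day-spread, observed through alternating 3/4-day trap exposures
  as Poisson counts;
* **sprout damage** — per-tree sprout counts with a locality×year
  infestation probability and overdispersed extra galls on infested sprouts.

A single master seed deterministically spawns per-generator,
per-locality-year substreams, so outputs are byte-identical under a fixed
seed and adding one generator never perturbs another.  Every dataset is
accompanied by a latent-truth manifest (true survivals, emergence modes,
infestation matrix) enabling parameter-recovery tests.

The default parameter set is the "malaga-like" profile: the six study
localities with their historical annual means, a mid-June–July emergence
window, and sprout infestation declining from ~0.7 (first damage year) to
~0.35 two years later with a rebound in the fourth.
"""

from __future__ import annotations

import datetime
import importlib.resources
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError
from .thermal import DailySeries, LocalityNormals, downscale_daily, monthly_anomalies
from .lifetables import STAGES

__all__ = [
    "SimConfig",
    "SimResult",
    "load_locality_table",
    "seasonal_normals",
    "default_localities",
    "reference_station",
    "default_infestation_matrix",
    "gen_reference_temps",
    "gen_cohort",
    "gen_traps",
    "gen_damage",
    "simulate",
]

# substream codes: fixed per generator so adding one never shifts another
_STREAM_TEMPS = 0
_STREAM_COHORT = 1
_STREAM_TRAPS = 2
_STREAM_DAMAGE = 3


def load_locality_table() -> pd.DataFrame:
    """The packaged six-locality study table (coordinates, elevation,
    historical annual mean temperature, and which analyses sampled each)."""
    with importlib.resources.files("gallwasp.data").joinpath("localities.csv").open() as fh:
        return pd.read_csv(fh)


def seasonal_normals(annual_mean: float, amplitude: float = 8.0) -> tuple[float, ...]:
    """Monthly normals from an annual mean: sinusoidal cycle, July peak.

    The cycle averages to zero over the twelve months, so the implied annual
    mean equals ``annual_mean`` exactly.
    """
    months = np.arange(12)
    cycle = -amplitude * np.cos(2 * np.pi * months / 12.0)
    return tuple(float(annual_mean + c) for c in cycle)


def default_localities(amplitude: float = 8.0) -> tuple[LocalityNormals, ...]:
    """Study localities as normals (annual means from the packaged table)."""
    tab = load_locality_table()
    return tuple(
        LocalityNormals(
            locality_id=row.locality,
            monthly_mean=seasonal_normals(row.annual_mean_c, amplitude),
            annual_mean=float(row.annual_mean_c),
        )
        for row in tab.itertuples()
    )


def reference_station(amplitude: float = 8.0) -> LocalityNormals:
    """Synthetic reference weather station (Ronda-like, annual mean 15 °C)."""
    return LocalityNormals(
        locality_id="Ronda-ref",
        monthly_mean=seasonal_normals(15.0, amplitude),
        annual_mean=15.0,
    )


def default_infestation_matrix(
    localities: tuple[str, ...], years: tuple[int, ...]
) -> dict[tuple[str, int], float]:
    """Locality×year sprout-infestation probabilities, malaga-like profile:
    ~0.7 in the first damage year, declining to ~0.35 by the third, with a
    partial rebound in the fourth; small fixed locality offsets."""
    year_level = {0: 0.70, 1: 0.55, 2: 0.35, 3: 0.50}
    offsets = [0.05, -0.03, 0.08, -0.08, 0.0, 0.02]
    out: dict[tuple[str, int], float] = {}
    for i, loc in enumerate(localities):
        for j, yr in enumerate(years):
            level = year_level.get(j, 0.45) + offsets[i % len(offsets)]
            out[(loc, yr)] = float(min(max(level, 0.02), 0.98))
    return out


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic study.

    Defaults are the "malaga-like" profile: six localities with their
    historical annual means, 2015–2020 temperature coverage, the 2016 and
    2017 dissection cohorts, 2017–2020 trap and damage campaigns.
    """

    seed: int = 42
    localities: tuple[LocalityNormals, ...] = field(default_factory=default_localities)
    reference: LocalityNormals = field(default_factory=reference_station)
    years: tuple[int, int] = (2015, 2020)

    # reference temperature series
    temp_amplitude: float = 8.0
    temp_noise_sd: float = 1.5
    temp_phase_doy: int = 105  # sin peak at doy 196 (mid-July)

    # bud-dissection cohorts
    cohort_localities: tuple[str, ...] = ("Igualeja", "Juzcar", "Ojen", "Yunquera")
    cohort_years: tuple[int, ...] = (2016, 2017)
    n_buds_per_sampling: int = 23
    sampling_interval_days: int = 14  # fortnightly from March (monthly before)
    sampling_span_days: int = 385
    eggs_per_bud_mean: float = 6.0
    eggs_dispersion: float = 10.0  # negative-binomial size k (larger = less clumped)
    oviposition_doy: int = 180  # late-June egg laying
    stage_thresholds: tuple[float, ...] = (700.0, 3400.0, 4000.0, 4450.0, 4900.0)
    threshold_jitter_sd: float = 30.0
    transition_survivals: tuple[float, ...] = (0.9, 0.85, 0.8, 0.75, 0.9)
    adult_residence_degc: float = 500.0  # adults stay in galls this long before emerging
    fecundity: float = 3.0  # effective offspring (next-season eggs in sampled buds) per adult

    # trap campaign
    flight_localities: tuple[str, ...] = (
        "Igualeja", "Jubrique", "Juzcar", "Ojen", "Parauta", "Yunquera",
    )
    flight_years: tuple[int, ...] = (2017, 2018, 2019, 2020)
    emergence_threshold: float = 5050.0  # cumulative °C from the season anchor
    emergence_spread_days: float = 6.0
    trap_rate_scale: float = 40.0  # expected individuals per trap per season
    n_trees_traps: int = 5
    traps_per_tree: int = 2
    trap_anchor_month_day: tuple[int, int] = (7, 1)  # fallback anchor: 1 July, prior year
    trap_season: tuple[tuple[int, int], tuple[int, int]] = ((6, 1), (8, 31))

    # sprout damage
    damage_localities: tuple[str, ...] = ("Igualeja", "Juzcar", "Ojen", "Yunquera")
    damage_years: tuple[int, ...] = (2017, 2018, 2019, 2020)
    n_trees_damage: int = 10
    sprouts_per_tree_mean: float = 15.5
    infestation_prob: dict[tuple[str, int], float] | None = None
    extra_galls_mean: float = 1.2
    galls_dispersion: float = 1.0  # negative-binomial size k; 0 = Poisson extras

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.transition_survivals):
            raise DomainError("transition survivals must lie in [0, 1]")
        thr = np.asarray(self.stage_thresholds, dtype=float)
        if len(thr) != len(STAGES) - 1 or np.any(np.diff(thr) <= 0):
            raise DomainError("stage thresholds must be 5 strictly increasing values")
        if self.infestation_prob is not None:
            bad = {k: v for k, v in self.infestation_prob.items() if not 0.0 <= v <= 1.0}
            if bad:
                raise DomainError(f"infestation probabilities outside [0, 1]: {bad}")

    def infestation_matrix(self) -> dict[tuple[str, int], float]:
        if self.infestation_prob is not None:
            return dict(self.infestation_prob)
        return default_infestation_matrix(self.damage_localities, self.damage_years)

    def rng(self, *key: int) -> np.random.Generator:
        """Deterministic substream for (generator code, locality idx, year...)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))

    def locality(self, name: str) -> LocalityNormals:
        for loc in self.localities:
            if loc.locality_id == name:
                return loc
        raise SchemaError(f"unknown locality {name!r}")

    def locality_index(self, name: str) -> int:
        for i, loc in enumerate(self.localities):
            if loc.locality_id == name:
                return i
        raise SchemaError(f"unknown locality {name!r}")


@dataclass
class SimResult:
    """All generated inputs plus the latent-truth manifest."""

    config: SimConfig
    normals: pd.DataFrame
    reference_series: DailySeries
    locality_series: dict[str, DailySeries]
    dissections: pd.DataFrame
    traps: pd.DataFrame
    sprouts: pd.DataFrame
    truth: dict


def _negbin(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    """Overdispersed counts: NB(k, mean) for k>0, Poisson for k==0, 0 for mean==0."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if k <= 0:
        return rng.poisson(mean, size)
    return rng.negative_binomial(k, k / (k + mean), size)


def gen_reference_temps(config: SimConfig) -> DailySeries:
    """Daily reference-station means: base + seasonal sinusoid + noise.

    Covers 1 January of the year before ``config.years[0]`` (so that
    previous-season anchors always fall inside the series) through
    31 December of ``config.years[1]``.
    """
    y0, y1 = config.years
    idx = pd.date_range(
        datetime.date(y0 - 1, 1, 1), datetime.date(y1, 12, 31), freq="D"
    )
    doy = idx.dayofyear.to_numpy(dtype=float)
    seasonal = config.temp_amplitude * np.sin(
        2 * np.pi * (doy - config.temp_phase_doy) / 365.0
    )
    rng = config.rng(_STREAM_TEMPS)
    noise = (
        rng.normal(0.0, config.temp_noise_sd, len(idx))
        if config.temp_noise_sd > 0
        else np.zeros(len(idx))
    )
    vals = config.reference.annual_mean + seasonal + noise
    return DailySeries(
        locality_id=config.reference.locality_id, values=pd.Series(vals, index=idx)
    )


def _sampling_dates(config: SimConfig, cohort_year: int) -> list[datetime.date]:
    """Field-style schedule: monthly through the overwintering months, then
    every ``sampling_interval_days`` from 1 March until the span ends."""
    start = datetime.date(cohort_year, 1, 1) + datetime.timedelta(
        days=config.oviposition_doy - 1 + 10
    )
    stop = start + datetime.timedelta(days=config.sampling_span_days)
    spring = datetime.date(cohort_year + 1, 3, 1)
    dates, cur = [], start
    while cur < min(spring, stop):
        dates.append(cur)
        cur += datetime.timedelta(days=28)
    cur = max(spring, start)
    while cur < stop:
        dates.append(cur)
        cur += datetime.timedelta(days=config.sampling_interval_days)
    return dates


def gen_cohort(
    config: SimConfig,
    locality_series: DailySeries,
    cohort_year: int,
    n_buds: int | None = None,
) -> pd.DataFrame:
    """Bud-dissection records for one locality-cohort.

    Each sampling destructively collects ``n_buds`` fresh buds.  A bud's egg
    load is negative-binomial; its individuals advance a stage whenever the
    locality's cumulative °C since oviposition crosses the bud's (slightly
    jittered) next threshold, and survive each transition as a binomial
    thinning with the configured probability.  Adults leave the gall after
    ``adult_residence_degc`` additional cumulative °C, after which the bud
    reads all-zero ("all adults had already emerged").
    """
    n_buds = config.n_buds_per_sampling if n_buds is None else n_buds
    loc_idx = config.locality_index(locality_series.locality_id)
    rng = config.rng(_STREAM_COHORT, loc_idx, cohort_year)

    ovi = datetime.date(cohort_year, 1, 1) + datetime.timedelta(
        days=config.oviposition_doy - 1
    )
    cum = locality_series.values.loc[pd.Timestamp(ovi) + pd.Timedelta(days=1):].cumsum()
    thresholds = np.asarray(config.stage_thresholds, dtype=float)
    survs = np.asarray(config.transition_survivals, dtype=float)
    departure = thresholds[-1] + config.adult_residence_degc

    rows: list[dict] = []
    for date in _sampling_dates(config, cohort_year):
        c = float(cum.loc[:pd.Timestamp(date)].iloc[-1]) if date > ovi else 0.0
        n0 = _negbin(rng, config.eggs_per_bud_mean, config.eggs_dispersion, n_buds)
        jit = rng.normal(0.0, config.threshold_jitter_sd, (n_buds, len(thresholds)))
        thr_b = np.sort(thresholds[None, :] + jit, axis=1)
        stage = (c > thr_b).sum(axis=1)  # 0..5 thresholds crossed
        alive = n0.copy()
        for j in range(len(thresholds)):
            adv = stage > j
            alive[adv] = rng.binomial(alive[adv], survs[j])
        departed = (stage == len(STAGES) - 1) & (c > departure)
        counts = np.zeros((n_buds, len(STAGES)), dtype=int)
        keep = ~departed
        counts[np.flatnonzero(keep), stage[keep]] = alive[keep]
        for b in range(n_buds):
            rec = {
                "locality": locality_series.locality_id,
                "cohort": cohort_year,
                "date": date.isoformat(),
                "bud_id": f"{date.isoformat()}-b{b + 1:03d}",
            }
            rec.update({s: int(counts[b, k]) for k, s in enumerate(STAGES)})
            rows.append(rec)
    return pd.DataFrame(rows)


def _trap_intervals(config: SimConfig, year: int) -> list[tuple[datetime.date, datetime.date]]:
    (m0, d0), (m1, d1) = config.trap_season
    start, stop = datetime.date(year, m0, d0), datetime.date(year, m1, d1)
    out, cur, k = [], start, 0
    while cur < stop:
        exposure = 3 if k % 2 == 0 else 4
        nxt = min(cur + datetime.timedelta(days=exposure), stop)
        out.append((cur, nxt))
        cur, k = nxt, k + 1
    return out


def emergence_mode(
    config: SimConfig, locality_series: DailySeries, year: int
) -> datetime.date | None:
    """Day the locality's cumulative °C (from the season anchor) crosses the
    emergence threshold; None if never crossed within the series."""
    anchor = datetime.date(year - 1, *config.trap_anchor_month_day)
    cum = locality_series.values.loc[pd.Timestamp(anchor) + pd.Timedelta(days=1):].cumsum()
    crossed = cum[cum >= config.emergence_threshold]
    if crossed.empty:
        return None
    return crossed.index[0].date()


def gen_traps(
    config: SimConfig, locality_series: DailySeries, year: int
) -> tuple[pd.DataFrame, datetime.date | None]:
    """Trap records for one locality-year, plus the true emergence mode.

    Interval counts are Poisson with mean ``trap_rate_scale`` × the Gaussian
    emergence mass (mode at the threshold-crossing day, sd
    ``emergence_spread_days``) falling inside the exposure interval.
    """
    loc_idx = config.locality_index(locality_series.locality_id)
    rng = config.rng(_STREAM_TRAPS, loc_idx, year)
    mode = emergence_mode(config, locality_series, year)
    intervals = _trap_intervals(config, year)

    rows: list[dict] = []
    for dep, col in intervals:
        if mode is None or config.trap_rate_scale <= 0:
            lam = 0.0
        else:
            a = (dep - mode).days
            b = (col - mode).days
            sd = max(config.emergence_spread_days, 1e-9)
            mass = _norm_cdf(b / sd) - _norm_cdf(a / sd)
            lam = config.trap_rate_scale * mass
        for tree in range(1, config.n_trees_traps + 1):
            for trap in range(1, config.traps_per_tree + 1):
                rows.append(
                    {
                        "locality": locality_series.locality_id,
                        "year": year,
                        "tree": f"T{tree}",
                        "trap": f"t{trap}",
                        "deploy_date": dep.isoformat(),
                        "collect_date": col.isoformat(),
                        "count": int(rng.poisson(lam)),
                    }
                )
    return pd.DataFrame(rows), mode


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def gen_damage(config: SimConfig) -> pd.DataFrame:
    """Sprout-damage records over all damage localities and years."""
    probs = config.infestation_matrix()
    rows: list[dict] = []
    for loc in config.damage_localities:
        loc_idx = config.locality_index(loc)
        for year in config.damage_years:
            p = probs[(loc, year)]
            rng = config.rng(_STREAM_DAMAGE, loc_idx, year)
            for tree in range(1, config.n_trees_damage + 1):
                n_sprouts = 1 + rng.poisson(max(config.sprouts_per_tree_mean - 1, 0.0))
                infested = rng.random(n_sprouts) < p
                extras = _negbin(
                    rng, config.extra_galls_mean, config.galls_dispersion, n_sprouts
                )
                galls = np.where(infested, 1 + extras, 0)
                for s in range(n_sprouts):
                    rows.append(
                        {
                            "locality": loc,
                            "year": year,
                            "tree": f"T{tree}",
                            "sprout": f"s{s + 1:03d}",
                            "galls": int(galls[s]),
                        }
                    )
    return pd.DataFrame(rows)


def simulate(config: SimConfig | None = None, outdir: str | Path | None = None) -> SimResult:
    """Generate the full synthetic study; optionally write the five CSVs plus
    the ``truth.json`` manifest to ``outdir``."""
    config = SimConfig() if config is None else config

    reference = gen_reference_temps(config)
    locality_series = {
        loc.locality_id: downscale_daily(reference, monthly_anomalies(loc, config.reference))
        for loc in config.localities
    }

    normals = pd.DataFrame(
        [
            {
                "locality": loc.locality_id,
                **{f"month_{m + 1:02d}": loc.monthly_mean[m] for m in range(12)},
                "annual_mean": loc.annual_mean,
            }
            for loc in (config.reference,) + tuple(config.localities)
        ]
    )

    dissections = pd.concat(
        [
            gen_cohort(config, locality_series[loc], yr)
            for loc in config.cohort_localities
            for yr in config.cohort_years
        ],
        ignore_index=True,
    )

    trap_frames, modes = [], {}
    for loc in config.flight_localities:
        for yr in config.flight_years:
            frame, mode = gen_traps(config, locality_series[loc], yr)
            trap_frames.append(frame)
            modes[f"{loc}:{yr}"] = None if mode is None else mode.isoformat()
    traps = pd.concat(trap_frames, ignore_index=True)

    sprouts = gen_damage(config)

    truth = {
        "seed": config.seed,
        "transition_survivals": list(config.transition_survivals),
        "eggs_per_bud_mean": config.eggs_per_bud_mean,
        "stage_thresholds": list(config.stage_thresholds),
        "fecundity": config.fecundity,
        "emergence_threshold": config.emergence_threshold,
        "emergence_modes": modes,
        "infestation_prob": {
            f"{loc}:{yr}": p for (loc, yr), p in sorted(config.infestation_matrix().items())
        },
    }

    result = SimResult(
        config=config,
        normals=normals,
        reference_series=reference,
        locality_series=locality_series,
        dissections=dissections,
        traps=traps,
        sprouts=sprouts,
        truth=truth,
    )
    if outdir is not None:
        _write(result, Path(outdir))
    return result


def _write(result: SimResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.normals.to_csv(outdir / "localities.csv", index=False)
    ref = result.reference_series.to_frame().drop(columns="locality")
    ref.to_csv(outdir / "reference_daily.csv", index=False)
    result.dissections.to_csv(outdir / "dissections.csv", index=False)
    result.traps.to_csv(outdir / "traps.csv", index=False)
    result.sprouts.to_csv(outdir / "sprouts.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(result.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
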