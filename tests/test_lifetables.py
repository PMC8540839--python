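import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gallwasp.errors import DomainError, LookupError_
from gallwasp import lifetables as lt
from gallwasp.lifetables import (
    STAGES,
    SurvivalSchedule,
    build_life_table,
    classify_trend,
    mean_development_stage,
    params_from_growth_rate,
    population_parameters,
    stage_profile,
    transition_survivals,
)


def profile_from(mean_per_bud, locality="A", cohort=2016, date="2016-07-01"):
    mean_per_bud = tuple(float(v) for v in mean_per_bud)
    total = sum(mean_per_bud)
    rel = tuple(v / total for v in mean_per_bud) if total else (0.0,) * 6
    return lt.StageProfile(
        locality_id=locality,
        cohort_year=cohort,
        sampling_date=pd.Timestamp(date).date(),
        mean_per_bud=mean_per_bud,
        relative_abundance=rel,
        n_buds=10,
        undefined=total == 0,
    )


class TestStageProfile:
    def test_symmetric_two_bud_split(self, dissection_frame):
        frame = dissection_frame(
            [("b1", (2, 0, 0, 0, 0, 0)), ("b2", (0, 2, 0, 0, 0, 0))]
        )
        p = stage_profile(frame, "A", 2016, pd.Timestamp("2016-07-01").date())
        assert p.mean_per_bud == (1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        assert p.relative_abundance == (0.5, 0.5, 0.0, 0.0, 0.0, 0.0)
        assert p.n_buds == 2

    def test_all_zero_bud_flags_undefined(self, dissection_frame):
        frame = dissection_frame([("b1", (0,) * 6)])
        p = stage_profile(frame, "A", 2016, pd.Timestamp("2016-07-01").date())
        assert p.undefined
        assert p.mean_per_bud == (0.0,) * 6
        assert p.relative_abundance == (0.0,) * 6

    def test_random_buds_match_tally_oracle(self, dissection_frame):
        rng = np.random.default_rng(5)
        rows = [(f"b{i}", tuple(rng.integers(0, 9, 6))) for i in range(50)]
        frame = dissection_frame(rows)
        p = stage_profile(frame, "A", 2016, pd.Timestamp("2016-07-01").date())
        totals = [0] * 6  # per-stage loop accumulation
        for _, counts in rows:
            for s in range(6):
                totals[s] += counts[s]
        assert np.allclose(p.mean_per_bud, [t / 50 for t in totals])
        assert np.allclose(p.relative_abundance, [t / sum(totals) for t in totals])

    def test_empty_key_raises_lookup_error(self, dissection_frame):
        frame = dissection_frame([("b1", (1, 0, 0, 0, 0, 0))])
        with pytest.raises(LookupError_):
            stage_profile(frame, "nowhere", 2016, pd.Timestamp("2016-07-01").date())


class TestMeanDevelopmentStage:
    def test_all_eggs_is_zero(self):
        assert mean_development_stage(profile_from((3, 0, 0, 0, 0, 0))) == 0.0

    def test_half_eggs_half_l1(self):
        assert mean_development_stage(profile_from((2, 2, 0, 0, 0, 0))) == 0.5

    def test_random_profile_matches_dot_product_oracle(self):
        rng = np.random.default_rng(9)
        mpb = tuple(rng.uniform(0, 5, 6))
        p = profile_from(mpb)
        expected = sum(i * rel for i, rel in enumerate(p.relative_abundance))
        assert mean_development_stage(p) == pytest.approx(expected, abs=1e-12)

    def test_zero_individuals_is_domain_error(self):
        with pytest.raises(DomainError):
            mean_development_stage(profile_from((0,) * 6))


class TestTransitionSurvivals:
    def test_peak_ratio(self):
        profiles = [
            profile_from((10, 0, 0, 0, 0, 0), date="2016-07-01"),
            profile_from((2, 8, 0, 0, 0, 0), date="2016-08-01"),
        ]
        sched = transition_survivals(profiles)
        assert sched.transitions[0] == pytest.approx(0.8)

    def test_ratio_above_one_capped_and_flagged(self, caplog):
        profiles = [
            profile_from((10, 0, 0, 0, 0, 0), date="2016-07-01"),
            profile_from((0, 6, 0, 0, 0, 0), date="2016-08-01"),
            profile_from((0, 0, 7, 0, 0, 0), date="2016-09-01"),
        ]
        with caplog.at_level("WARNING", logger="gallwasp.lifetables"):
            sched = transition_survivals(profiles)
        assert sched.transitions[1] == 1.0
        assert sched.capped[1]
        assert "capped" in caplog.text

    def test_total_is_product_of_transitions(self):
        profiles = [
            profile_from((10, 0, 0, 0, 0, 0), date="2016-07-01"),
            profile_from((0, 8, 0, 0, 0, 0), date="2016-09-01"),
            profile_from((0, 0, 6, 0, 0, 0), date="2016-11-01"),
            profile_from((0, 0, 0, 5, 0, 0), date="2017-01-01"),
            profile_from((0, 0, 0, 0, 4, 0), date="2017-03-01"),
            profile_from((0, 0, 0, 0, 0, 3), date="2017-05-01"),
        ]
        sched = transition_survivals(profiles)
        assert sched.total == pytest.approx(np.prod(sched.transitions), abs=1e-12)
        assert sched.total == pytest.approx(0.3)

    def test_zero_egg_peak_is_undefined(self):
        profiles = [profile_from((0, 1, 0, 0, 0, 0))] * 2
        with pytest.raises(DomainError):
            transition_survivals(profiles)


class TestBuildLifeTable:
    def test_lossless_cohort(self):
        sched = SurvivalSchedule(transitions=(1.0,) * 5, total=1.0)
        table = build_life_table(sched, fecundity=2.0)
        assert (table["lx"] == 1.0).all()
        assert population_parameters(table).R0 == pytest.approx(2.0)

    def test_single_loss_cohort(self):
        sched = SurvivalSchedule(transitions=(0.5, 1, 1, 1, 1), total=0.5)
        table = build_life_table(sched, fecundity=4.0)
        assert table["lx"].iloc[-1] == pytest.approx(0.5)

    def test_lx_matches_cumulative_product_loop(self):
        rng = np.random.default_rng(2)
        survs = tuple(rng.uniform(0.2, 1.0, 5))
        sched = SurvivalSchedule(transitions=survs, total=float(np.prod(survs)))
        table = build_life_table(sched, fecundity=3.0)
        expected, acc = [1.0], 1.0  # independent cumulative-product loop
        for p in survs:
            acc *= p
            expected.append(acc)
        assert np.allclose(table["lx"], expected, atol=1e-15)

    def test_survival_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            SurvivalSchedule(transitions=(1.2, 1, 1, 1, 1), total=1.2)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5))
    def test_lx_non_increasing_within_unit_interval(self, survs):
        sched = SurvivalSchedule(tuple(survs), total=float(np.prod(survs)))
        table = build_life_table(sched, fecundity=1.0)
        lx = table["lx"].to_numpy()
        assert lx[0] == 1.0
        assert np.all(np.diff(lx) <= 1e-15)
        assert np.all((lx >= 0) & (lx <= 1))


class TestPopulationParameters:
    def table(self, survs=(0.9, 0.85, 0.8, 0.75, 0.9), b=3.0):
        sched = SurvivalSchedule(tuple(survs), total=float(np.prod(survs)))
        return build_life_table(sched, fecundity=b)

    def test_stationary_population(self):
        # choose fecundity so that R0 = 1 exactly
        survs = (0.5, 1.0, 1.0, 1.0, 1.0)
        table = self.table(survs, b=2.0)
        p = population_parameters(table)
        assert p.R0 == pytest.approx(1.0)
        assert p.r == pytest.approx(0.0, abs=1e-12)
        assert p.lam == pytest.approx(1.0, abs=1e-12)
        assert p.trend == "stationary"

    def test_census_chain(self):
        table = self.table()
        p = population_parameters(table, N_t=5.0, N_t1=6.0)
        assert p.lam == pytest.approx(1.2)
        assert p.r == pytest.approx(math.log(1.2))
        assert p.T == pytest.approx(math.log(p.R0) / p.r)

    def test_chain_consistency_both_branches(self):
        table = self.table()
        for p in (
            population_parameters(table),
            population_parameters(table, N_t=4.0, N_t1=7.0),
        ):
            assert math.exp(p.r) == pytest.approx(p.lam, abs=1e-12)
            assert p.R0 == pytest.approx(p.lam**p.T, rel=1e-12)

    def test_trend_agrees_across_criteria(self):
        for b in (0.5, 2.3, 8.0):
            p = population_parameters(self.table(b=b))
            by_r = "increasing" if p.r > 0 else ("declining" if p.r < 0 else "stationary")
            by_lam = "increasing" if p.lam > 1 else ("declining" if p.lam < 1 else "stationary")
            assert p.trend == by_r == by_lam == classify_trend(p.R0)

    def test_degenerate_cohort(self):
        p = population_parameters(self.table(survs=(0.0, 1, 1, 1, 1)))
        assert p.degenerate
        assert p.R0 == 0.0
        assert p.trend == "declining"

    def test_bad_census_rejected(self):
        with pytest.raises(DomainError):
            population_parameters(self.table(), N_t=0.0, N_t1=1.0)


class TestGrowthRateAnchors:
    def test_declining_cohort_point_values(self):
        p = params_from_growth_rate(r=-0.09, R0=0.81)
        assert round(p.lam, 2) == 0.91
        assert p.trend == "declining"

    def test_increasing_cohort_point_values(self):
        p = params_from_growth_rate(r=0.35, R0=2.22)
        assert p.lam == pytest.approx(math.exp(0.35))
        assert abs(p.lam - 1.41) < 0.01
        assert p.trend == "increasing"
        # generation time from inverting r = ln R0 / T
        assert p.T == pytest.approx(math.log(2.22) / 0.35, abs=1e-12)
        assert p.T == pytest.approx(2.28, abs=0.005)
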