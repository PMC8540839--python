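import numpy as np
import pandas as pd
import pytest
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from gallwasp.errors import DomainError, SchemaError
from gallwasp.inference import ModelSpec, fit_anova, fit_multiresponse, tukey_hsd


def one_way(seed=0, k=3, n=10, effects=None, sd=1.0):
    rng = np.random.default_rng(seed)
    effects = [0.0] * k if effects is None else effects
    rows = []
    for g in range(k):
        for v in rng.normal(effects[g], sd, n):
            rows.append({"g": f"g{g}", "y": v})
    return pd.DataFrame(rows)


def two_way(seed=0, n=10, loc_eff=(0, 0, 0), yr_eff=(0, 0), sd=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, loc in enumerate(("L1", "L2", "L3")[: len(loc_eff)]):
        for j, yr in enumerate(("2017", "2018")[: len(yr_eff)]):
            for v in rng.normal(loc_eff[i] + yr_eff[j], sd, n):
                rows.append({"locality": loc, "year": yr, "y": v})
    return pd.DataFrame(rows)


class TestModelSpec:
    def test_collinear_covariates_rejected(self):
        with pytest.raises(SchemaError, match="collinear"):
            ModelSpec(
                responses=("y",),
                terms=("date", "locality", "cum_degc:locality"),
                factors=("locality",),
            )

    def test_formula_wraps_factors(self):
        spec = ModelSpec(
            responses=("y",), terms=("locality", "year", "locality:year"),
            factors=("locality", "year"),
        )
        assert spec.formula() == "y ~ 1 + C(locality) + C(year) + C(locality):C(year)"


class TestFitAnova:
    def test_two_group_f_equals_squared_pooled_t(self):
        data = one_way(seed=1, k=2, n=8, effects=[0.0, 0.7])
        res = fit_anova(ModelSpec(("y",), ("g",), factors=("g",)), data)
        t, _ = stats.ttest_ind(
            data[data.g == "g0"]["y"], data[data.g == "g1"]["y"], equal_var=True
        )
        assert res.table.loc[0, "F"] == pytest.approx(t**2, rel=1e-10)

    def test_constant_response_gives_zero_f_and_r2(self):
        data = one_way(seed=2).assign(y=3.5)
        res = fit_anova(ModelSpec(("y",), ("g",), factors=("g",)), data)
        assert (res.table["F"] == 0).all()
        assert (res.table["p"] == 1).all()
        assert res.r_squared == 0.0

    def test_one_way_matches_brute_force_ss_decomposition(self):
        data = one_way(seed=3, k=3, n=10, effects=[0, 0.5, 1.0])
        res = fit_anova(ModelSpec(("y",), ("g",), factors=("g",)), data)
        # independent oracle: explicit group means and residuals
        y = data["y"].to_numpy()
        grand = y.mean()
        ss_between = 0.0
        ss_within = 0.0
        for g in data["g"].unique():
            vals = data[data.g == g]["y"].to_numpy()
            ss_between += len(vals) * (vals.mean() - grand) ** 2
            ss_within += ((vals - vals.mean()) ** 2).sum()
        f_oracle = (ss_between / 2) / (ss_within / (len(y) - 3))
        assert res.table.loc[0, "F"] == pytest.approx(f_oracle, rel=1e-10)
        assert res.table.loc[0, "df_num"] == 2
        assert res.table.loc[0, "df_den"] == len(y) - 3

    def test_sequential_ss_matches_statsmodels_typ1(self):
        data = two_way(seed=4, loc_eff=(0, 0.8, 0.2), yr_eff=(0, 0.5))
        spec = ModelSpec(
            ("y",), ("locality", "year", "locality:year"), factors=("locality", "year")
        )
        res = fit_anova(spec, data)
        sm_fit = smf.ols("y ~ C(locality) + C(year) + C(locality):C(year)", data).fit()
        sm_tab = anova_lm(sm_fit, typ=1)
        assert np.allclose(res.table["sum_sq"], sm_tab["sum_sq"].iloc[:-1], rtol=1e-9)
        assert np.allclose(res.table["F"], sm_tab["F"].iloc[:-1], rtol=1e-9)
        assert res.r_squared == pytest.approx(sm_fit.rsquared, rel=1e-12)

    def test_sequential_ss_conservation(self):
        data = two_way(seed=5, loc_eff=(0, 1, 2), yr_eff=(0, 1))
        spec = ModelSpec(
            ("y",), ("locality", "year", "locality:year"), factors=("locality", "year")
        )
        res = fit_anova(spec, data)
        total = res.table["sum_sq"].sum() + res.ss_resid
        assert total == pytest.approx(res.ss_total, rel=1e-9)

    def test_affine_response_rescaling_leaves_f_p_r2(self):
        data = two_way(seed=6, loc_eff=(0, 0.6, 0.1), yr_eff=(0, 0.3))
        spec = ModelSpec(("y",), ("locality", "year"), factors=("locality", "year"))
        res1 = fit_anova(spec, data)
        res2 = fit_anova(spec, data.assign(y=5.0 * data["y"] - 11.0))
        assert np.allclose(res1.table["F"], res2.table["F"], rtol=1e-9)
        assert np.allclose(res1.table["p"], res2.table["p"], rtol=1e-9)
        assert res1.r_squared == pytest.approx(res2.r_squared, rel=1e-9)

    def test_row_permutation_invariance(self):
        data = two_way(seed=7, loc_eff=(0, 0.5, 1.0), yr_eff=(0, 0.4))
        spec = ModelSpec(("y",), ("locality", "year"), factors=("locality", "year"))
        res1 = fit_anova(spec, data)
        res2 = fit_anova(spec, data.sample(frac=1.0, random_state=9).reset_index(drop=True))
        assert np.allclose(res1.table["F"], res2.table["F"], rtol=1e-9)

    def test_saturated_model_names_offending_interaction(self):
        data = two_way(seed=8, n=1)  # one observation per cell
        spec = ModelSpec(
            ("y",), ("locality", "year", "locality:year"), factors=("locality", "year")
        )
        with pytest.raises(DomainError, match="locality:year"):
            fit_anova(spec, data)


class TestFitMultiresponse:
    def test_single_response_reduces_to_univariate_f(self):
        data = two_way(seed=10, loc_eff=(0, 0.7, 0.2), yr_eff=(0, 0.4))
        spec_u = ModelSpec(("y",), ("locality", "year"), factors=("locality", "year"))
        spec_m = ModelSpec(("y",), ("locality", "year"), factors=("locality", "year"))
        uni = fit_anova(spec_u, data)
        multi = fit_multiresponse(spec_m, data)
        assert np.allclose(multi.table["F"], uni.table["F"], rtol=1e-9)
        assert np.allclose(multi.table["p"], uni.table["p"], rtol=1e-9)

    def test_identical_response_copies_match_univariate(self):
        data = two_way(seed=11, loc_eff=(0, 0.9, 0.3), yr_eff=(0, 0.2))
        wide = data.assign(y1=data["y"], y2=data["y"], y3=data["y"])
        uni = fit_anova(
            ModelSpec(("y",), ("locality", "year"), factors=("locality", "year")), data
        )
        multi = fit_multiresponse(
            ModelSpec(("y1", "y2", "y3"), ("locality", "year"), factors=("locality", "year")),
            wide,
        )
        assert multi.n_responses_effective == 1
        assert np.allclose(multi.table["F"], uni.table["F"], rtol=1e-6)

    def test_signal_on_one_of_six_responses_detected(self):
        rng = np.random.default_rng(12)
        n = 12
        rows = []
        for i, loc in enumerate(("L1", "L2", "L3")):
            for _ in range(n):
                resp = {f"y{j}": rng.normal() for j in range(6)}
                resp["y2"] += 1.5 * i  # effect on one response only
                rows.append({"locality": loc, **resp})
        data = pd.DataFrame(rows)
        res = fit_multiresponse(
            ModelSpec(tuple(f"y{j}" for j in range(6)), ("locality",), factors=("locality",)),
            data,
        )
        assert res.table.loc[0, "p"] < 0.05

    def test_more_responses_than_residual_df_rejected(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame(
            {
                "g": ["a", "a", "b", "b", "a", "b"],
                **{f"y{j}": rng.normal(size=6) for j in range(5)},
            }
        )
        spec = ModelSpec(tuple(f"y{j}" for j in range(5)), ("g",), factors=("g",))
        with pytest.raises(DomainError):
            fit_multiresponse(spec, data)


class TestTukeyHSD:
    def test_two_levels_equal_unadjusted_p(self):
        data = one_way(seed=14, k=2, n=9, effects=[0, 0.8])
        res = fit_anova(ModelSpec(("y",), ("g",), factors=("g",)), data)
        tab = tukey_hsd(res, "g")
        assert len(tab) == 1
        assert tab.loc[0, "p_adj"] == pytest.approx(tab.loc[0, "p_unadj"], rel=1e-6)

    def test_identical_level_means_give_p_near_one(self):
        data = one_way(seed=15, k=3, n=6)
        data["y"] = np.tile(np.arange(6.0), 3)  # same values in every level
        res = fit_anova(ModelSpec(("y",), ("g",), factors=("g",)), data)
        tab = tukey_hsd(res, "g")
        assert (tab["p_adj"] > 0.999).all()

    def test_adjusted_p_never_below_unadjusted(self):
        for seed in range(5):
            data = one_way(seed=seed, k=4, n=7, effects=[0, 0.3, 0.6, 1.0])
            res = fit_anova(ModelSpec(("y",), ("g",), factors=("g",)), data)
            tab = tukey_hsd(res, "g")
            assert (tab["p_adj"] >= tab["p_unadj"] - 1e-12).all()

    def test_matches_statsmodels_pairwise_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = one_way(seed=16, k=3, n=10, effects=[0, 0.5, 1.2])
        res = fit_anova(ModelSpec(("y",), ("g",), factors=("g",)), data)
        tab = tukey_hsd(res, "g")
        sm = pairwise_tukeyhsd(data["y"], data["g"])
        assert np.allclose(tab["p_adj"], sm.pvalues, atol=1e-6)

    def test_empty_level_rejected(self):
        data = one_way(seed=17, k=2, n=5)
        data["g"] = pd.Categorical(data["g"], categories=["g0", "g1", "g2"])
        res = fit_anova(ModelSpec(("y",), ("g",), factors=("g",)), data)
        with pytest.raises(DomainError, match="empty"):
            tukey_hsd(res, "g")
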