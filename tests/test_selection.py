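import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from matesel import selection
from matesel.selection import (
    MatedPair,
    assortative_model,
    fit_selection_models,
    janzen_stern_gradient,
    mean_standardized_gradient,
    pair_size_gap,
    pairs_frame,
    residual_claw,
    selection_differential,
    standardize,
)


def test_standardize_basic_and_grouped():
    assert standardize([1.0, 2.0, 3.0]) == pytest.approx([-1.0, 0.0, 1.0])
    z = standardize([1, 2, 3, 10, 20, 30], group=["a"] * 3 + ["b"] * 3)
    assert z[:3] == pytest.approx([-1.0, 0.0, 1.0])
    assert z[3:] == pytest.approx([-1.0, 0.0, 1.0])
    with pytest.raises(ValueError):
        standardize([5.0, 5.0, 5.0])


def test_selection_differential_hand_example():
    z = np.array([-1.0, 0.0, 1.0])
    s, p = selection_differential(z, [False, False, True])
    assert s == pytest.approx(1.0)  # mean of successful (1) minus mean of all (0)
    assert np.isnan(p)  # a single successful male: no Welch test
    s, p = selection_differential(z, [False, False, False])
    assert np.isnan(s) and np.isnan(p)
    # with groups of >= 2 the p-value matches scipy's Welch test
    from scipy import stats

    z = np.array([-1.5, -0.5, 0.2, 0.4, 1.1, 1.6])
    success = np.array([False, False, False, True, True, True])
    s, p = selection_differential(z, success)
    t_ref, p_ref = stats.ttest_ind(z[success], z[~success], equal_var=False)
    assert p == pytest.approx(p_ref)
    with pytest.raises(ValueError):
        selection_differential(z, success[:-1])


def test_residual_claw_orthogonality():
    rng = np.random.default_rng(0)
    cl = rng.uniform(80, 120, 100)
    cw = -27 + 0.82 * cl + rng.normal(0, 6, 100)
    res = residual_claw(cw, cl)
    assert abs(res.mean()) < 1e-9
    assert abs(np.corrcoef(res, cl)[0, 1]) < 1e-9
    with pytest.raises(ValueError):
        residual_claw([1.0, 2.0], [1.0, 2.0])


def test_aicc_formula():
    class Fake:
        df_model = 2
        aic = 100.0

    # p = 3 parameters, n = 20: penalty 2*3*4/16 = 1.5
    assert selection._aicc(Fake(), 20) == pytest.approx(101.5)
    # n too small for the correction: infinite
    assert selection._aicc(Fake(), 4) == float("inf")


def _males_frame(seed=0, n=400, b_cl=1.0, b_cwres=0.0, area_effect=0.0):
    rng = np.random.default_rng(seed)
    area = np.where(rng.random(n) < 0.5, "reserve", "fished")
    z_cl = rng.normal(0, 1, n)
    z_cw = 0.8 * z_cl + 0.6 * rng.normal(0, 1, n)
    z_cwres = rng.normal(0, 1, n)
    eta = -1.0 + b_cl * z_cl + b_cwres * z_cwres + area_effect * (area == "reserve")
    success = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {"area": area, "z_cl": z_cl, "z_cw": z_cw, "z_cwres": z_cwres,
         "success": success}
    )


def test_fit_selection_models_ranking():
    df = _males_frame(seed=1, b_cl=1.2)
    ranking, fits = fit_selection_models(df)
    # 9 structures + 2 quadratic
    assert len(ranking) == 11
    assert ranking["delta_aicc"].min() == 0.0
    assert ranking["aicc"].is_monotonic_increasing
    # with a strong CL effect the null model cannot win
    assert ranking.iloc[0]["model"] != "Null"
    null_rank = ranking.index[ranking["model"] == "Null"][0]
    assert null_rank > 3
    # the winning CL coefficient is near the generating 1.2
    fit = fits["CL"]
    assert abs(fit.params[1] - 1.2) < 3 * fit.bse[1]


def test_fit_selection_models_single_area_drops_area_terms():
    df = _males_frame(seed=2)
    df["area"] = "reserve"
    ranking, _ = fit_selection_models(df, include_quadratic=False)
    assert not ranking["model"].str.contains("Area").any()
    assert len(ranking) == 5


def test_janzen_stern_matches_ols_in_weak_selection_limit():
    # with weak selection and success near 1/2, the transformed logistic
    # coefficient approximates the OLS gradient of relative fitness
    rng = np.random.default_rng(4)
    n = 40000
    z = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(0.0 + 0.05 * z)))
    y = (rng.random(n) < p).astype(float)
    fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
    grad = janzen_stern_gradient(fit, coef_index=0)
    w_rel = y / y.mean()
    ols = sm.OLS(w_rel, sm.add_constant(z)).fit().params[1]
    assert grad == pytest.approx(ols, rel=0.15, abs=0.01)


def test_janzen_stern_definition():
    df = _males_frame(seed=5, b_cl=0.8)
    _, fits = fit_selection_models(df, include_quadratic=False)
    fit = fits["CL"]
    w_hat = fit.predict()
    expected = fit.params[1] * np.mean(w_hat * (1 - w_hat)) / df["success"].mean()
    assert janzen_stern_gradient(fit, coef_index=0) == pytest.approx(expected)


def test_mean_standardized_gradient():
    assert mean_standardized_gradient(0.5, 99.0, 14.0) == pytest.approx(0.5 * 99 / 14)
    with pytest.raises(ValueError):
        mean_standardized_gradient(0.5, 99.0, 14.0, trait="CW_res")
    with pytest.raises(ValueError):
        mean_standardized_gradient(0.5, 99.0, 0.0)


def _pairs(seed=0, n_per_area=40, slope=0.8, area_effect=15.0,
           slope_reserve_extra=0.0, noise=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for area in ("reserve", "fished"):
        f = rng.uniform(80, 110, n_per_area)
        b = slope + (slope_reserve_extra if area == "reserve" else 0.0)
        m = 10 + b * f + area_effect * (area == "reserve")
        m = m + rng.normal(0, noise, n_per_area)
        for i in range(n_per_area):
            rows.append(
                MatedPair(
                    mother_id=f"f{area}{i}", father_id=f"m{area}{i}",
                    female_cl=float(f[i]), male_cl_adjusted=float(m[i]),
                    male_cw=None, female_area=area, male_area=area,
                    year=2011,
                )
            )
    return pairs_frame(rows)


def test_pairs_frame_drops_interarea():
    p = MatedPair("f1", "m1", 90.0, 100.0, None, "reserve", "fished", 2011)
    q = MatedPair("f2", "m2", 90.0, 100.0, None, "reserve", "reserve", 2011)
    df = pairs_frame([p, q])
    assert list(df["mother_id"]) == ["f2"]
    df_all = pairs_frame([p, q], drop_interarea=False)
    assert len(df_all) == 2 and df_all["interarea"].tolist() == [True, False]


def test_assortative_model_recovers_additive_structure():
    df = _pairs(seed=1)
    fit = assortative_model(df)
    assert fit.slope == pytest.approx(0.8, abs=3 * fit.slope_se)
    assert fit.area_effect == pytest.approx(15.0, abs=1.0)
    assert fit.r_squared > 0.9
    assert fit.lrt_p > 0.05 and fit.additive_supported


def test_assortative_model_detects_interaction():
    df = _pairs(seed=2, slope_reserve_extra=1.0)
    fit = assortative_model(df)
    assert fit.lrt_p < 0.01 and not fit.additive_supported


def test_assortative_model_single_area_and_guards():
    df = _pairs(seed=3)
    res = assortative_model(df[df["area"] == "reserve"])
    assert res.area_effect is None and res.lrt_p is None
    with pytest.raises(ValueError):
        assortative_model(df.iloc[:2])


@pytest.mark.filterwarnings("ignore")  # near-identical values upset the t-test
def test_pair_size_gap_frozen_example():
    rows = [
        MatedPair("f1", "m1", 100.0, 110.0, None, "reserve", "reserve", 2011),
        MatedPair("f2", "m2", 100.0, 105.0, None, "reserve", "reserve", 2011),
    ]
    df = pairs_frame(rows)
    gap, t, p = pair_size_gap(df, "reserve")
    assert gap == pytest.approx(7.5)
    assert np.isfinite(t) and 0 <= p <= 1
    with pytest.raises(ValueError):
        pair_size_gap(df.iloc[:1])
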