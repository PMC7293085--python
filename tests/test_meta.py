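"""Cross-city inference: type-III ANOVA, AICc averaging, slope model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cyanocline.clines import aicc
from cyanocline.meta import (
    dredge_average,
    pooled_anova,
    power_analysis,
    slope_environment_model,
)


def _balanced_two_city(slope_a=0.3, slope_b=0.3, mean_a=0.3, mean_b=0.3,
                       noise=0.0, rng=None, shared_noise=False):
    d = np.linspace(0, 1, 10)
    eps = rng.normal(0, noise, len(d)) if (noise and rng is not None) else 0.0
    rows = []
    for city, slope, mean in [("A", slope_a, mean_a), ("B", slope_b, mean_b)]:
        y = mean + slope * (d - 0.5)
        if noise and rng is not None:
            y = y + (eps if shared_noise else rng.normal(0, noise, len(d)))
        rows.append(pd.DataFrame({"city": city, "distance_std": d, "hcn_freq": y}))
    return pd.concat(rows, ignore_index=True)


def test_anova_city_effect_vanishes_for_identical_cities(rng):
    """Cities with literally identical frequency profiles contribute zero
    city and interaction sums of squares."""
    df = _balanced_two_city(noise=0.05, rng=rng, shared_noise=True)
    res = pooled_anova(df)
    assert res.f("city") == pytest.approx(0.0, abs=1e-6)
    assert res.f("city:distance") == pytest.approx(0.0, abs=1e-6)
    assert res.f("distance") > 1.0


def test_anova_detects_city_and_interaction(rng):
    df = _balanced_two_city(slope_a=0.0, slope_b=0.5, mean_a=0.2, mean_b=0.6,
                            noise=0.02, rng=rng)
    res = pooled_anova(df)
    assert res.p("city") < 0.001
    assert res.p("city:distance") < 0.001


def test_anova_invariant_to_city_label_order(rng):
    df = _balanced_two_city(slope_a=0.1, slope_b=0.4, noise=0.03, rng=rng)
    res1 = pooled_anova(df)
    relabeled = df.assign(city=df["city"].map({"A": "Z", "B": "B"}))
    res2 = pooled_anova(relabeled)
    assert res1.f("city:distance") == pytest.approx(res2.f("city:distance"))
    assert res1.f("distance") == pytest.approx(res2.f("distance"))


def test_anova_single_city_is_an_error():
    df = _balanced_two_city().query("city == 'A'")
    with pytest.raises(ValueError, match="per-city"):
        pooled_anova(df)


def test_aicc_converges_to_aic_for_large_n():
    llf, k = -123.4, 4
    aic = -2 * llf + 2 * k
    assert abs(aicc(llf, k, 20_000) - aic) < 0.01
    assert aicc(llf, k, 10) > aic  # penalty is positive at small n


def test_dredge_single_candidate_equals_plain_ols(rng):
    x = rng.normal(size=30)
    y = 1.0 + 0.5 * x + rng.normal(0, 0.2, 30)
    X = pd.DataFrame({"x": x})
    ms = dredge_average(pd.Series(y), X, delta_threshold=np.inf)
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    # retained set = {intercept-only, full}; force the one-model case
    single = dredge_average(pd.Series(y), X, delta_threshold=0.0)
    assert single.n_retained == 1
    assert single.averaged.loc["x", "coef"] == pytest.approx(ols.params[1])
    assert single.averaged.loc["x", "se"] == pytest.approx(ols.bse[1])
    assert ms.models.shape[0] == 2


def test_dredge_enumerates_all_subsets_and_weights_sum_to_one(rng):
    X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
    y = X["a"] * 0.8 + rng.normal(0, 0.3, 40)
    ms = dredge_average(y, X)
    assert ms.models.shape[0] == 16  # all subsets incl. intercept-only
    assert ms.models["weight"].sum() == pytest.approx(1.0)
    assert ms.models["delta_aicc"].min() == 0.0


def test_dredge_weights_invariant_to_aicc_shift(rng):
    X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
    y = X["a"] + rng.normal(0, 0.3, 40)
    ms = dredge_average(y, X)
    shifted = ms.models["aicc"] + 1234.5
    delta = shifted - shifted.min()
    rel = np.exp(-0.5 * delta)
    w = np.where(ms.models["delta_aicc"] <= 2, rel, 0)
    np.testing.assert_allclose(ms.models["weight"], w / w.sum(), atol=1e-12)


def test_dredge_shrinks_noise_predictor(rng):
    """Signal recovered, noise predictor averaged toward zero."""
    n = 200
    X = pd.DataFrame({"signal": rng.normal(size=n), "noise": rng.normal(size=n)})
    y = 2.0 * X["signal"] + rng.normal(0, 1.0, n)
    ms = dredge_average(y, X)
    sig = ms.averaged.loc["signal"]
    assert sig["coef"] == pytest.approx(2.0, abs=3 * sig["se"])
    assert abs(ms.averaged.loc["noise", "coef"]) < abs(sig["coef"]) / 10


def test_dredge_small_n_is_an_error(rng):
    X = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
    with pytest.raises(ValueError, match="too small"):
        dredge_average(pd.Series(rng.normal(size=6)), X)


def test_slope_model_exact_linear_relationship():
    pc1 = pd.Series(np.linspace(-2, 2, 10), index=[f"c{i}" for i in range(10)])
    betas = 0.2 - 0.05 * pc1
    res = slope_environment_model(betas, pc1)
    assert res.coef == pytest.approx(-0.05)
    assert res.r_squared == pytest.approx(1.0)
    assert res.n_cities == 10


def test_slope_model_exclusions_and_minimum_cities():
    pc1 = pd.Series(np.linspace(-1, 1, 5), index=list("abcde"))
    betas = pc1 * 0.1
    res = slope_environment_model(betas, pc1, exclude=["e"])
    assert res.n_cities == 4
    with pytest.raises(ValueError, match=">= 4"):
        slope_environment_model(betas, pc1, exclude=["c", "d", "e"])


def test_richness_f_equals_t_squared(rng):
    """Two-group one-way ANOVA F is the square of the pooled t statistic."""
    a = rng.normal(2.0, 0.5, 7)
    b = rng.normal(1.6, 0.5, 7)
    f, pf = stats.f_oneway(a, b)
    t, pt = stats.ttest_ind(a, b)
    assert f == pytest.approx(t**2)
    assert pf == pytest.approx(pt)


def test_power_saturates_for_a_very_large_slope():
    res = power_analysis(
        n_populations=40, plants_options=(15,), true_slope=0.5,
        baseline_freq=0.2, replicates=100, seed=3,
    )
    assert res[0].power > 0.99
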