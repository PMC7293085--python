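"""Ground-truth properties of the synthetic study generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyanocline.clines import fit_linear_cline, standardize_distance
from cyanocline.genetics import expected_hcn_freq
from cyanocline.simulate import (
    CityScenario,
    ClimateParams,
    default_scenarios,
    generate_city,
    generate_haplotype_panel,
    generate_multi_city_study,
    generate_weather,
    true_linear_slope,
)
from cyanocline.environment import filter_weather, frost_exposure


def test_same_seed_reproduces_identical_tables():
    s = CityScenario(city_id="A", n_populations=5, plants_per_population=10)
    p1, pop1 = generate_city(s, 42)
    p2, pop2 = generate_city(s, 42)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(pop1, pop2)
    assert p1.to_csv() == p2.to_csv()


def test_flat_cline_yields_zero_slope():
    """With zero logit slopes at both loci the fitted cline is within 2 SE
    of zero at a large design."""
    s = CityScenario(
        city_id="flat", n_populations=200, plants_per_population=1000,
        cline_ac=(0.0, 0.0), cline_li=(2.0, 0.0), follow_up_assays=False,
    )
    plants, pops = generate_city(s, 7)
    freqs = (
        plants.assign(pos=plants["feigl_anger"] == "pos")
        .groupby("population_id", sort=True)["pos"].mean()
    )
    d = pops.set_index("population_id").loc[freqs.index, "distance_std"]
    fit = fit_linear_cline(freqs.to_numpy(), d.to_numpy())
    assert abs(fit.beta) < 2 * fit.se_beta


def test_positive_logit_slope_raises_hcn_and_ac_with_distance():
    s = CityScenario(
        city_id="up", n_populations=40, plants_per_population=500,
        cline_ac=(0.0, 1.0), cline_li=(6.0, 0.0),
    )
    plants, pops = generate_city(s, 3)
    # ground truth from expected_hcn_freq applied to the logit curves
    truth = [
        expected_hcn_freq(pa, pl)
        for pa, pl in zip(pops["true_p_ac"], pops["true_p_li"])
    ]
    assert np.all(np.diff(truth) > 0)
    freqs = (
        plants.assign(pos=plants["feigl_anger"] == "pos")
        .groupby("population_id", sort=True)["pos"].mean()
    )
    d = pops.set_index("population_id").loc[freqs.index, "distance_std"]
    fit = fit_linear_cline(freqs.to_numpy(), d.to_numpy())
    assert fit.beta > 0 and fit.p_value < 0.01


def test_generated_genotypes_follow_hwe():
    """Chi-square goodness of fit of recessive counts to q^2 does not
    reject at ~alpha across replicates."""
    rng = np.random.default_rng(5)
    rejections = 0
    n_rep, n_plants, q = 100, 2000, 0.45
    for _ in range(n_rep):
        rec = (rng.random(n_plants) < q * q).sum()
        chi2 = (rec - n_plants * q * q) ** 2 / (n_plants * q * q * (1 - q * q))
        if stats.chi2.sf(chi2, df=1) < 0.05:
            rejections += 1
    assert rejections <= 12  # >= 94% non-rejection within binomial noise


def test_weather_frost_metric_trivial_cases():
    warm = ClimateParams(mean_winter_tmin=15.0, sd_winter_tmin=1.0,
                         snowfall_scale=0.0, years=2)
    w = generate_weather(warm, 1)
    assert frost_exposure(filter_weather(w).retained) == 0.0

    # permanent snow cover blocks frost exposure despite freezing days
    cold = ClimateParams(mean_winter_tmin=-10.0, snow_persistence=1.0,
                         snowfall_scale=3.0, years=2)
    w2 = generate_weather(cold, 2)
    ret = filter_weather(w2).retained
    covered = ret[ret["snowdepth_cm"] > 0]
    frosty_uncovered = ((ret["tmin_c"] < 0) & (ret["snowdepth_cm"] == 0)).sum()
    assert len(covered) > 0
    # once cover exists it never disappears within a winter
    first_cover = ret.groupby(pd.to_datetime(ret["date"]).dt.year)[
        "snowdepth_cm"
    ].transform(lambda s: s.gt(0).cummax())
    assert not ((first_cover == 1) & (ret["snowdepth_cm"] == 0)).any()


def test_frost_metric_equals_brute_force_scan():
    c = ClimateParams(mean_winter_tmin=-5.0, snowfall_scale=0.0, years=3)
    w = generate_weather(c, 11)
    ret = filter_weather(w).retained
    years = pd.to_datetime(ret["date"]).dt.year
    brute = np.mean(
        [((g["tmin_c"] < 0) & (g["snowdepth_cm"] == 0)).sum()
         for _, g in ret.groupby(years)]
    )
    assert frost_exposure(ret) == pytest.approx(brute)


def test_multi_city_manifest_round_trip():
    scen = default_scenarios(n_cities=4, n_populations=8,
                             plants_per_population=10, years=2)
    b1 = generate_multi_city_study(scen, -1.0, seed=9)
    b2 = generate_multi_city_study(scen, -1.0, seed=9)
    assert b1.manifest == b2.manifest
    pd.testing.assert_frame_equal(b1.plants, b2.plants)
    pd.testing.assert_frame_equal(b1.weather, b2.weather)
    # manifest is sufficient for recovery tests: per-city truth is recorded
    for cid, info in b1.manifest["cities"].items():
        assert {"cline_ac", "true_linear_slope_hcn", "cold_axis"} <= info.keys()


def test_true_linear_slope_matches_independent_ols_on_truth_curve():
    s = CityScenario(city_id="t", n_populations=25, cline_ac=(0.2, 1.3),
                     cline_li=(0.5, 0.7))
    d = s.distances_km()
    d_std = standardize_distance(d)
    f = s.expected_hcn(d_std)
    slope = np.polyfit(d_std, f, 1)[0]
    assert true_linear_slope(s) == pytest.approx(slope)


def test_negative_coupling_gives_negative_slope_climate_relation():
    """Recovered at large per-city sample sizes (parameter recovery)."""
    scen = default_scenarios(n_cities=8, n_populations=30,
                             plants_per_population=300, years=2)
    b = generate_multi_city_study(scen, -2.0, seed=21, slope_noise_sd=0.0)
    truths = {c: v["true_linear_slope_hcn"] for c, v in b.manifest["cities"].items()}
    colds = {c: v["cold_axis"] for c, v in b.manifest["cities"].items()}
    cities = sorted(truths)
    r = np.corrcoef([colds[c] for c in cities], [truths[c] for c in cities])[0, 1]
    assert r < -0.9


def test_haplotype_panel_masking_and_richness_bounds():
    pool = {
        "Ac": {"ac_del1": 0.5, "ac_del2": 0.5},
        "Li": {k: 0.25 for k in ("li_del1", "li_del2", "li_del3", "li_del4")},
    }
    panel = generate_haplotype_panel(10, pool, seed=4, cities=("c1", "c2"))
    from cyanocline.haplotypes import DEFAULT_PATTERN_TABLE as T

    for row in panel.itertuples():
        expected = T.larger(row.locus, row.true_hap1, row.true_hap2)
        assert row.true_shown == expected
        assert (row.pp1, row.pp2, row.pp3) == T.pattern(row.locus, expected)

    # a single-class Ac pool gives richness 1 everywhere
    single = generate_haplotype_panel(
        10, {"Ac": {"ac_del2": 1.0}}, seed=5, cities=("c1",)
    )
    assert set(single["true_shown"]) == {"ac_del2"}


def test_equal_frequency_li_pool_has_near_full_expected_richness():
    """P(missing a class in 20 draws) = (3/4)^20, so expected richness is
    4 - 4 (3/4)^20 ~ 3.987; the mean over panels should be close."""
    pool = {"Li": {k: 0.25 for k in ("li_del1", "li_del2", "li_del3", "li_del4")}}
    rng = np.random.default_rng(6)
    rich = []
    for _ in range(200):
        panel = generate_haplotype_panel(10, pool, seed=rng, cities=("x",))
        urban = panel[panel["habitat"] == "urban"]
        carried = set(urban["true_hap1"]) | set(urban["true_hap2"])
        rich.append(len(carried))
    expected = 4 - 4 * (3 / 4) ** 20
    assert np.mean(rich) == pytest.approx(expected, abs=0.05)
    assert max(rich) <= 4
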