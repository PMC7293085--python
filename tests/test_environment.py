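"""Weather filtering, frost exposure, SMD, aggregation, PCA composites."""

import numpy as np
import pandas as pd
import pytest

from cyanocline import environment as env
from cyanocline.simulate import ClimateParams, generate_weather


def _weather(rows):
    return pd.DataFrame(
        rows, columns=["station_id", "date", "tmin_c", "tmax_c",
                       "snowfall_cm", "snowdepth_cm"]
    )


def _jan_feb_complete(year=2001, station="S"):
    rows = []
    for m, nd in [(1, 31), (2, 28)]:
        for d in range(1, nd + 1):
            rows.append((station, f"{year}-{m:02d}-{d:02d}", -1.0, 5.0, 0.0, 0.0))
    return _weather(rows)


def test_filter_keeps_complete_winter_and_drops_march():
    df = _jan_feb_complete()
    march = _weather([("S", "2001-03-01", -5.0, 0.0, 0.0, 0.0)])
    res = env.filter_weather(pd.concat([df, march], ignore_index=True))
    assert res.n_retained == len(df)  # every complete Jan-Feb day is kept
    assert res.audit["dropped_off_month"] == 1


def test_filter_drops_short_months_and_missing_days():
    df = _jan_feb_complete()
    # a second year with only 9 January days and a missing-tmin February day
    short = _weather(
        [("S", f"2002-01-{d:02d}", -2.0, 1.0, 0.0, 0.0) for d in range(1, 10)]
        + [("S", "2002-02-01", np.nan, 1.0, 0.0, 0.0)]
    )
    res = env.filter_weather(pd.concat([df, short], ignore_index=True))
    assert res.audit["dropped_short_month"] == 9
    assert res.audit["dropped_missing"] == 1
    assert res.n_retained == len(df)
    # audit counts are conserved
    a = res.audit
    assert a["input"] == a["retained"] + a["dropped_off_month"] + a[
        "dropped_missing"] + a["dropped_short_month"]


def test_filter_is_idempotent():
    c = ClimateParams(years=3)
    w = generate_weather(c, 8, off_target_months=(3,), missing_day_rate=0.1)
    once = env.filter_weather(w)
    twice = env.filter_weather(once.retained)
    assert twice.n_retained == once.n_retained
    assert twice.audit["dropped_off_month"] == 0


def test_filter_all_dropped_is_an_error():
    march = _weather([("S", "2001-03-01", -5.0, 0.0, 0.0, 0.0)])
    with pytest.raises(ValueError):
        env.filter_weather(march)


def test_frost_exposure_counts_and_means():
    rows = []
    for d in range(1, 11):
        rows.append(("S", f"2001-01-{d:02d}", -3.0, 1.0, 0.0, 0.0))
    for d in range(11, 21):
        rows.append(("S", f"2001-01-{d:02d}", -3.0, 1.0, 0.0, 4.0))
    df = _weather(rows)
    assert env.frost_exposure(df) == 10.0

    # mean across two years of counts 8 and 12
    rows = [("S", f"2001-01-{d:02d}", -3.0, 1.0, 0.0, 0.0) for d in range(1, 9)]
    rows += [("S", f"2001-01-{d:02d}", 3.0, 6.0, 0.0, 0.0) for d in range(9, 21)]
    rows += [("S", f"2002-01-{d:02d}", -3.0, 1.0, 0.0, 0.0) for d in range(1, 13)]
    assert env.frost_exposure(_weather(rows)) == pytest.approx(10.0)


def test_frost_exposure_monotone_in_snow_cover():
    """Adding cover to any day can only reduce the metric (snow buffering)."""
    df = _jan_feb_complete()
    base = env.frost_exposure(df)
    covered = df.copy()
    covered.loc[covered.index[:10], "snowdepth_cm"] = 5.0
    assert env.frost_exposure(covered) <= base


def test_soil_moisture_deficit():
    months = dict.fromkeys(range(1, 13))
    precip = {m: 100.0 for m in months}
    pet = {m: 100.0 for m in months}
    assert env.soil_moisture_deficit(precip, pet) == 0.0
    pet2 = {m: 60.0 for m in months}
    assert env.soil_moisture_deficit(precip, pet2) == pytest.approx(40.0)
    # asymmetric toy equals the hand-computed mean of May-September diffs
    precip3 = {m: 10.0 * m for m in months}
    pet3 = {m: 100.0 - 5.0 * m for m in months}
    hand = np.mean([10 * m - (100 - 5 * m) for m in (5, 6, 7, 8, 9)])
    assert env.soil_moisture_deficit(precip3, pet3) == pytest.approx(hand)
    with pytest.raises(ValueError, match="month 7"):
        env.soil_moisture_deficit({m: 1.0 for m in (5, 6, 8, 9)}, pet)


def _env_table(cities):
    rows = []
    for city, mwt in cities:
        for i in range(3):
            row = {"city": city, "population_id": f"{city}{i}",
                   "mwt_c": mwt + i * 0.1, "mst_c": 25.0, "ai": 1.0,
                   "apet_mm": 800.0}
            for m in range(1, 13):
                row[f"precip_mm_{m:02d}"] = 80.0
                row[f"pet_mm_{m:02d}"] = 70.0
            rows.append(row)
    return pd.DataFrame(rows)


def test_aggregate_city_is_columnwise_mean():
    table = _env_table([("A", -5.0), ("B", -7.0)])
    out = env.aggregate_city(table).set_index("city")
    assert out.loc["A", "mwt_c"] == pytest.approx(-4.9)
    assert out.loc["B", "mwt_c"] == pytest.approx(-6.9)
    assert out.loc["A", "smd_mm"] == pytest.approx(10.0)
    # independent column-mean oracle on a larger table
    big = _env_table([(f"C{i}", -float(i)) for i in range(10)])
    got = env.aggregate_city(big).set_index("city")["mwt_c"]
    oracle = big.groupby("city")["mwt_c"].mean()
    pd.testing.assert_series_equal(got.sort_index(), oracle.sort_index(),
                                   check_names=False)


def test_pca_two_correlated_variables_explain_everything(rng):
    x = rng.normal(size=16)
    df = pd.DataFrame({"a": x, "b": 3 * x + 1, "snowfall_cm_mean": x})
    scores, explained, loadings = env.pca_composite(
        df, ["a", "b", "snowfall_cm_mean"]
    )
    assert explained == pytest.approx(1.0)
    assert loadings["snowfall_cm_mean"] > 0


def test_pca_matches_independent_eigendecomposition(rng):
    X = pd.DataFrame(rng.normal(size=(16, 5)),
                     columns=["v1", "v2", "v3", "v4", "snowfall_cm_mean"])
    scores, explained, _ = env.pca_composite(X, list(X.columns))
    corr = np.corrcoef(
        ((X - X.mean()) / X.std(ddof=1)).to_numpy(), rowvar=False
    )
    evals, evecs = np.linalg.eigh(corr)
    v1 = evecs[:, -1]
    oracle = ((X - X.mean()) / X.std(ddof=1)).to_numpy() @ v1
    # equal up to sign; variance share from the eigenvalues
    r = np.corrcoef(scores, oracle)[0, 1]
    assert abs(r) == pytest.approx(1.0)
    assert explained == pytest.approx(evals[-1] / evals.sum())


def test_pca_scores_invariant_to_units(rng):
    X = pd.DataFrame(rng.normal(size=(12, 3)),
                     columns=["t_c", "depth_cm", "snowfall_cm_mean"])
    s1, e1, _ = env.pca_composite(X, list(X.columns))
    X2 = X.copy()
    X2["t_c"] = X2["t_c"] * 9 / 5 + 32  # to Fahrenheit
    X2["depth_cm"] = X2["depth_cm"] / 2.54  # to inches
    s2, e2, _ = env.pca_composite(X2, list(X2.columns))
    np.testing.assert_allclose(s1, s2, atol=1e-10)
    assert e1 == pytest.approx(e2)


def test_pca_constant_variable_is_an_error(rng):
    X = pd.DataFrame({"a": rng.normal(size=5), "snowfall_cm_mean": np.ones(5)})
    with pytest.raises(ValueError, match="constant"):
        env.pca_composite(X, list(X.columns))


def test_pc1_slope_tracks_latent_cold_axis(small_bundle):
    """On the synthetic bundle the composite axis recovers the generator's
    latent climate axis almost perfectly."""
    ce = env.build_city_environment(small_bundle.weather,
                                    small_bundle.environment)
    cold = pd.Series(
        {c: v["cold_axis"] for c, v in small_bundle.manifest["cities"].items()}
    )
    merged = ce.set_index("city").join(cold.rename("cold"))
    r = np.corrcoef(merged["pc1_slope_score"], merged["cold"])[0, 1]
    assert abs(r) > 0.9
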