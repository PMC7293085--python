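"""City-level climate features and composite PCA axes.

Raw station-day weather records (GHCN-Daily-like) are filtered to the
coldest winter months, then summarized into a frost-exposure metric — the
mean annual count of sub-zero days with no snow cover, the quantity snow
buffering protects plants from — together with mean snowfall and snow
depth.  Per-population raster-extracted variables (minimum winter
temperature MWT, maximum summer temperature MST, monthly precipitation and
potential evapotranspiration, aridity index AI) are averaged to the city
level, a growing-season soil moisture deficit (SMD = precipitation - PET)
is derived, and composite climate axes are built by PCA on the correlation
matrix:

* ``pc1_hcn``   from MST, MWT, summer precipitation, annual PET, snowfall;
* ``pc1_slope`` from snow depth, snowfall, MWT, MST.

Both axes are sign-oriented so snowfall loads positively: low scores mean
warm, low-snow cities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_weather",
    "frost_exposure",
    "snow_summaries",
    "soil_moisture_deficit",
    "aggregate_city",
    "pca_composite",
    "build_city_environment",
    "WeatherFilterResult",
    "GROWING_SEASON",
]

GROWING_SEASON = (5, 6, 7, 8, 9)

PC1_HCN_VARS = ["mst_c", "mwt_c", "summer_precip_mm", "apet_mm", "snowfall_cm_mean"]
PC1_SLOPE_VARS = ["snowdepth_cm_mean", "snowfall_cm_mean", "mwt_c", "mst_c"]


@dataclass
class WeatherFilterResult:
    retained: pd.DataFrame
    audit: dict

    @property
    def n_retained(self) -> int:
        return int(len(self.retained))


def filter_weather(
    records: pd.DataFrame,
    months: tuple = (1, 2),
    min_days_per_month: int = 10,
) -> WeatherFilterResult:
    """Filter station-day records for the winter frost metrics.

    Keeps only records from the requested months (January and February by
    default, the coldest months in eastern North America) with non-missing
    tmin and snow depth; drops any station-year-month with fewer than
    ``min_days_per_month`` retained days; a station-year survives if at
    least one of its months does.  Audit counts attribute every dropped
    record to exactly one rule.
    """
    df = records.copy()
    n_in = len(df)
    date = pd.to_datetime(df["date"])
    df["_year"] = date.dt.year
    df["_month"] = date.dt.month

    off_month = ~df["_month"].isin(months)
    n_off = int(off_month.sum())
    df = df[~off_month]

    missing = df["tmin_c"].isna() | df["snowdepth_cm"].isna()
    n_missing = int(missing.sum())
    df = df[~missing]

    grp = df.groupby(["station_id", "_year", "_month"])["date"].transform("size")
    short = grp < min_days_per_month
    n_short = int(short.sum())
    df = df[~short]
    # year-level rule is implied: a year with no qualifying month has no
    # rows left, so no separate drop is needed.

    audit = {
        "input": n_in,
        "dropped_off_month": n_off,
        "dropped_missing": n_missing,
        "dropped_short_month": n_short,
        "retained": int(len(df)),
    }
    if len(df) == 0:
        raise ValueError(
            "no weather records survive filtering; frost metric undefined"
        )
    return WeatherFilterResult(retained=df.reset_index(drop=True), audit=audit)


def frost_exposure(retained: pd.DataFrame, freeze_on: str = "tmin") -> float:
    """Mean annual count of freezing days with no snow cover.

    Per station-year, counts days with ``tmin_c < 0`` (or ``tmax_c`` with
    ``freeze_on='tmax'``) and snow depth exactly 0 cm, then averages the
    counts across years.  Input must already be filtered.
    """
    col = {"tmin": "tmin_c", "tmax": "tmax_c"}[freeze_on]
    df = retained
    if "_year" not in df.columns:
        df = df.assign(_year=pd.to_datetime(df["date"]).dt.year)
    frost = (df[col] < 0) & (df["snowdepth_cm"] == 0)
    per_year = frost.groupby([df["station_id"], df["_year"]]).sum()
    return float(per_year.mean())


def snow_summaries(retained: pd.DataFrame) -> tuple[float, float]:
    """Mean daily snowfall and snow depth (cm) over retained records."""
    return (
        float(retained["snowfall_cm"].mean()),
        float(retained["snowdepth_cm"].mean()),
    )


def soil_moisture_deficit(
    precip_monthly: dict | pd.Series,
    pet_monthly: dict | pd.Series,
    months: tuple = GROWING_SEASON,
) -> float:
    """Growing-season soil moisture deficit (mm).

    Water supply minus water demand, SMD_m = Precip_m - PET_m, averaged
    over May-September.  Unlike the aridity index (a ratio), SMD stays
    stable when monthly values are small.
    """
    precip = dict(precip_monthly)
    pet = dict(pet_monthly)
    diffs = []
    for m in months:
        if m not in precip or precip[m] is None or pd.isna(precip[m]):
            raise ValueError(f"missing precipitation for month {m}")
        if m not in pet or pet[m] is None or pd.isna(pet[m]):
            raise ValueError(f"missing PET for month {m}")
        diffs.append(precip[m] - pet[m])
    return float(np.mean(diffs))


def aggregate_city(env: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-city means of the per-population environment table.

    Returns one row per city with mwt_c, mst_c, ai, apet_mm, growing-season
    summer precipitation, and smd_mm (SMD computed per population, then
    averaged across populations).
    """
    if len(env) == 0:
        raise ValueError("empty environment table")
    precip_cols = [f"precip_mm_{m:02d}" for m in GROWING_SEASON]
    pet_cols = [f"pet_mm_{m:02d}" for m in GROWING_SEASON]
    work = env.copy()
    work["summer_precip_mm"] = work[precip_cols].mean(axis=1)
    work["smd_mm"] = work[precip_cols].to_numpy().mean(axis=1) - work[
        pet_cols
    ].to_numpy().mean(axis=1)
    out = (
        work.groupby("city")[
            ["mwt_c", "mst_c", "ai", "apet_mm", "summer_precip_mm", "smd_mm"]
        ]
        .mean()
        .reset_index()
    )
    return out


def pca_composite(
    matrix: pd.DataFrame,
    variables: list[str],
    anchor: str = "snowfall_cm_mean",
) -> tuple[pd.Series, float, pd.Series]:
    """First principal component of a city x variable matrix.

    Variables are centered and scaled to unit variance (PCA on the
    correlation matrix) since they carry incommensurate units; this also
    makes the scores invariant to unit changes.  The axis sign is fixed so
    the anchor variable loads positively: with snowfall as the anchor, low
    scores are warm, low-snow cities.

    Returns (scores indexed like ``matrix``, proportion of variance
    explained by the first axis, loadings).
    """
    X = matrix[variables].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cities for a composite axis")
    if np.isnan(X).any():
        raise ValueError("missing cells in PCA input")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant variable(s) {bad}: scaling undefined")
    Z = (X - X.mean(axis=0)) / sd
    # SVD of the scaled matrix == eigendecomposition of the correlation matrix
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    if loadings[variables.index(anchor)] < 0:
        loadings = -loadings
    scores = Z @ loadings
    explained = float(s[0] ** 2 / np.sum(s**2))
    return (
        pd.Series(scores, index=matrix.index, name="pc1"),
        explained,
        pd.Series(loadings, index=variables),
    )


def build_city_environment(
    weather: pd.DataFrame,
    env: pd.DataFrame,
    months: tuple = (1, 2),
    min_days_per_month: int = 10,
    freeze_on: str = "tmin",
) -> pd.DataFrame:
    """Full city-environment table with composite axes.

    Weather is grouped by station (one station per city; station_id is the
    city key), filtered, and summarized; the per-population table is
    aggregated; PC1_HCN and PC1_slope scores are appended.
    """
    rows = []
    for station, sub in weather.groupby("station_id"):
        res = filter_weather(sub, months=months, min_days_per_month=min_days_per_month)
        snowfall, snowdepth = snow_summaries(res.retained)
        rows.append(
            {
                "city": station,
                "frost_days_no_snow": frost_exposure(res.retained, freeze_on),
                "snowfall_cm_mean": snowfall,
                "snowdepth_cm_mean": snowdepth,
                "n_weather_obs": res.n_retained,
            }
        )
    frost_df = pd.DataFrame(rows)
    city_env = aggregate_city(env).merge(frost_df, on="city", how="inner")
    city_env = city_env.set_index("city")

    hcn_scores, hcn_var, _ = pca_composite(city_env, PC1_HCN_VARS)
    slope_scores, slope_var, _ = pca_composite(city_env, PC1_SLOPE_VARS)
    city_env["pc1_hcn_score"] = hcn_scores
    city_env["pc1_slope_score"] = slope_scores
    city_env.attrs["pc1_hcn_explained"] = hcn_var
    city_env.attrs["pc1_slope_explained"] = slope_var
    return city_env.reset_index()
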