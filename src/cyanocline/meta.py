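"""Cross-city models: pooled ANOVA, AICc model averaging, cline-strength
regression, and the sampling-design power analysis.

The pooled model is ``freq ~ city + distance_std + city:distance_std`` with
sum-to-zero contrasts and type-III (marginal) F-tests: a significant city
term means cities differ in mean frequency, a significant distance term
means an average urban-rural cline, and a significant interaction means
cline strength varies among cities — the trigger for per-city analysis.

Environmental models of mean HCN frequency enumerate every subset of the
candidate predictors, rank them by AICc, and average all models within a
delta-AICc threshold (2 by default) with Akaike weights, using "full"
averaging (a predictor absent from a model contributes a zero
coefficient).  Cline strength itself is regressed on the PC1_slope
composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .clines import aicc, fit_linear_cline
from .simulate import CityScenario, generate_city, true_linear_slope

__all__ = [
    "AnovaResult",
    "ModelSet",
    "pooled_anova",
    "dredge_average",
    "slope_environment_model",
    "power_analysis",
    "PowerResult",
]


@dataclass
class AnovaResult:
    """Type-III F-tests for city, distance and their interaction."""

    terms: pd.DataFrame  # index: term; columns: F, df_num, df_den, p_value

    def f(self, term: str) -> float:
        return float(self.terms.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p_value"])


def pooled_anova(populations: pd.DataFrame) -> AnovaResult:
    """Pooled ANOVA of population frequencies across cities.

    ``populations`` needs columns ``hcn_freq``, ``city``, ``distance_std``.
    Type-III marginal tests require sum-to-zero contrasts on city; each
    term's F comes from a full-vs-reduced model comparison, which is the
    standard construction compatible with an interaction model.
    """
    df = populations.dropna(subset=["hcn_freq"]).copy()
    if df["city"].nunique() < 2:
        raise ValueError("pooled ANOVA needs >= 2 cities; fit a per-city cline instead")
    model = smf.ols(
        "hcn_freq ~ C(city, Sum) * distance_std", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(
        index={
            "C(city, Sum)": "city",
            "distance_std": "distance",
            "C(city, Sum):distance_std": "city:distance",
        }
    )
    out = pd.DataFrame(
        {
            "F": table["F"],
            "df_num": table["df"],
            "df_den": float(model.df_resid),
            "p_value": table["PR(>F)"],
        }
    ).loc[["city", "distance", "city:distance"]]
    return AnovaResult(terms=out)


@dataclass
class ModelSet:
    """Result of exhaustive AICc model selection and averaging."""

    response: str
    candidates: list
    models: pd.DataFrame  # one row per model: predictors, aicc, delta, weight
    averaged: pd.DataFrame  # index predictor: coef, se, z, p_value
    delta_threshold: float
    n_retained: int = 0
    retained_weights_sum: float = field(default=1.0)


def _fit_subset(y, X, subset):
    cols = list(subset)
    design = sm.add_constant(X[cols]) if cols else pd.DataFrame(
        {"const": np.ones(len(y))}, index=X.index
    )
    res = sm.OLS(y, design).fit()
    k = len(cols) + 2  # intercept + slopes + residual variance
    return res, aicc(res.llf, k, len(y))


def dredge_average(
    response: pd.Series,
    predictors: pd.DataFrame,
    delta_threshold: float = 2.0,
    response_name: str = "response",
) -> ModelSet:
    """Exhaustive subset regression with AICc ranking and model averaging.

    Fits OLS for every subset of the candidate predictors, including the
    intercept-only model; ranks by AICc; retains models within
    ``delta_threshold`` AICc units of the best; renormalizes Akaike weights
    over the retained set and averages coefficients with "full" (zero
    substitution) averaging.  Averaged standard errors include
    between-model variance: se = sum_i w_i sqrt(var_i + (b_i - b_bar)^2).
    """
    y = pd.Series(response).astype(float)
    X = predictors.astype(float)
    names = list(X.columns)
    n = len(y)
    k_max = len(names) + 2
    if n <= k_max + 1:
        raise ValueError(
            f"n = {n} too small for AICc with the largest candidate model "
            f"({len(names)} predictors)"
        )

    rows = []
    fits = []
    for r in range(len(names) + 1):
        for subset in combinations(names, r):
            res, ic = _fit_subset(y, X, subset)
            rows.append({"predictors": subset, "aicc": ic})
            fits.append(res)
    models = pd.DataFrame(rows)
    models["delta_aicc"] = models["aicc"] - models["aicc"].min()
    rel = np.exp(-0.5 * models["delta_aicc"])
    models["weight_all"] = rel / rel.sum()
    retained_mask = models["delta_aicc"] <= delta_threshold
    w = np.where(retained_mask, rel, 0.0)
    models["weight"] = w / w.sum()

    averaged_rows = []
    for name in names:
        coefs = np.zeros(len(fits))
        variances = np.zeros(len(fits))
        for i, res in enumerate(fits):
            if name in res.params.index:
                coefs[i] = res.params[name]
                variances[i] = res.bse[name] ** 2
        wv = models["weight"].to_numpy()
        b_bar = float(np.dot(wv, coefs))
        se = float(np.dot(wv, np.sqrt(variances + (coefs - b_bar) ** 2)))
        z = abs(b_bar) / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(z) if np.isfinite(z) else np.nan
        averaged_rows.append(
            {"predictor": name, "coef": b_bar, "se": se, "z": z, "p_value": p}
        )
    averaged = pd.DataFrame(averaged_rows).set_index("predictor")

    return ModelSet(
        response=response_name,
        candidates=names,
        models=models.sort_values("aicc").reset_index(drop=True),
        averaged=averaged,
        delta_threshold=delta_threshold,
        n_retained=int(retained_mask.sum()),
        retained_weights_sum=float(models["weight"].sum()),
    )


@dataclass
class SlopeModelResult:
    coef: float
    se: float
    t: float
    p_value: float
    r_squared: float
    n_cities: int
    intercept: float


def slope_environment_model(
    betas: pd.Series,
    pc1_slope: pd.Series,
    exclude: list | None = None,
) -> SlopeModelResult:
    """Regress per-city linear-cline strength on the PC1_slope composite.

    ``betas`` and ``pc1_slope`` are aligned by city index; cities in
    ``exclude`` (e.g. effectively fixed for the phenotype) are dropped
    first.  A negative coefficient means weaker clines in colder, snowier
    cities.
    """
    df = pd.DataFrame({"beta": betas, "pc1": pc1_slope}).dropna()
    if exclude:
        df = df[~df.index.isin(exclude)]
    if len(df) < 4:
        raise ValueError(f"only {len(df)} cities after exclusions; need >= 4")
    res = sm.OLS(df["beta"], sm.add_constant(df["pc1"])).fit()
    return SlopeModelResult(
        coef=float(res.params["pc1"]),
        se=float(res.bse["pc1"]),
        t=float(res.tvalues["pc1"]),
        p_value=float(res.pvalues["pc1"]),
        r_squared=float(res.rsquared),
        n_cities=int(len(df)),
        intercept=float(res.params["const"]),
    )


@dataclass
class PowerResult:
    """Simulated power of the per-city linear cline test for one design."""

    plants_per_population: int
    n_populations: int
    true_freq_slope: float
    power: float
    ci_low: float
    ci_high: float
    replicates: int


def _scenario_for_slope(
    true_slope: float, baseline_freq: float, n_populations: int, plants: int
) -> CityScenario:
    """Scenario whose expected HCN frequency runs from baseline to
    baseline + true_slope across the transect.

    Per-locus frequencies are set equal at both loci and logit-linear in
    distance, pinned so the HCN frequency hits the two endpoints exactly.
    """

    def p_for_f(f):
        # invert f = (1 - (1-p)^2)^2 for p at a single locus (both equal)
        f = min(max(f, 1e-6), 1 - 1e-6)
        return 1.0 - np.sqrt(1.0 - np.sqrt(f))

    p0 = p_for_f(baseline_freq)
    p1 = p_for_f(baseline_freq + true_slope)
    a0 = float(np.log(p0 / (1 - p0)))
    a1 = float(np.log(p1 / (1 - p1)) - a0)
    return CityScenario(
        city_id="power",
        n_populations=n_populations,
        plants_per_population=plants,
        cline_ac=(a0, a1),
        cline_li=(a0, a1),
        follow_up_assays=False,
    )


def power_analysis(
    n_populations: int = 40,
    plants_options: tuple = (15, 20),
    true_slope: float = 0.15,
    baseline_freq: float = 0.3,
    replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[PowerResult]:
    """Simulated power of the linear cline test at alternative sampling depths.

    For each design, replicate cities are generated at the stated true
    frequency change over the transect, the per-population HCN frequencies
    are fitted against standardized distance, and power is the fraction of
    replicates rejecting at ``alpha``, with a 95% Wilson binomial CI.
    Designs with similar power have overlapping CIs.
    """
    if replicates < 100:
        raise ValueError("use at least 100 replicates for a stable power estimate")
    rng = np.random.default_rng(seed)
    results = []
    for plants in plants_options:
        scenario = _scenario_for_slope(
            true_slope, baseline_freq, n_populations, plants
        )
        truth = true_linear_slope(scenario)
        hits = 0
        for _ in range(replicates):
            plants_df, pops = generate_city(scenario, rng)
            freqs = (
                plants_df.assign(pos=plants_df["feigl_anger"] == "pos")
                .groupby("population_id", sort=True)["pos"]
                .mean()
            )
            d_std = pops.set_index("population_id").loc[freqs.index, "distance_std"]
            fit = fit_linear_cline(freqs.to_numpy(), d_std.to_numpy())
            if fit.p_value < alpha:
                hits += 1
        lo, hi = proportion_confint(hits, replicates, method="wilson")
        results.append(
            PowerResult(
                plants_per_population=plants,
                n_populations=n_populations,
                true_freq_slope=truth,
                power=hits / replicates,
                ci_low=float(lo),
                ci_high=float(hi),
                replicates=replicates,
            )
        )
    return results
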