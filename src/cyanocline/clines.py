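"""Per-city cline fitting against standardized urban-rural distance.

Within each city, transect distance is rescaled to [0, 1] (0 = most urban,
1 = most rural) so cline slopes are comparable across cities with transects
of different lengths.  Three model families are supported:

* ``linear_popfreq`` — OLS of per-population phenotype or allele frequency
  on standardized distance (the headline cline strength, beta);
* ``logistic_individual`` — maximum-likelihood logistic regression on
  individual 0/1 plant phenotypes (beta is a change in log-odds);
* ``quadratic_popfreq`` — OLS with distance and distance^2, compared to the
  linear family by small-sample-corrected AIC (AICc, smaller wins, ties go
  to linear).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genetics import PopulationSummary

__all__ = [
    "ClineFit",
    "DegenerateDataError",
    "standardize_distance",
    "add_standardized_distance",
    "fit_linear_cline",
    "fit_logistic_cline",
    "fit_quadratic_cline",
    "select_family",
    "significance_stars",
    "city_summary_table",
    "aicc",
]

#: Mean-frequency band outside of which a city is treated as effectively
#: fixed for the phenotype and excluded from slope meta-analysis.
FIXED_THRESHOLD = 0.98


class DegenerateDataError(ValueError):
    """Raised when data cannot identify a cline (degenerate transect,
    single phenotype class, separation, or too few populations)."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``k`` counts every estimated parameter, including the residual variance
    for Gaussian models.  Requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _aicc_or_nan(loglik: float, k: int, n: int) -> float:
    """AICc, or NaN when the small-sample correction is undefined."""
    try:
        return aicc(loglik, k, n)
    except ValueError:
        return float("nan")


def standardize_distance(distances_km: Sequence[float]) -> np.ndarray:
    """Rescale within-city distances to [0, 1] by an affine map.

    0 is the most urban population and 1 the most rural; ordering is
    preserved.  Raises :class:`DegenerateDataError` when all distances
    coincide.
    """
    d = np.asarray(distances_km, dtype=float)
    if len(d) < 2 or d.max() == d.min():
        raise DegenerateDataError("transect needs at least 2 distinct distances")
    return (d - d.min()) / (d.max() - d.min())


def add_standardized_distance(
    df: pd.DataFrame, city_col: str = "city", dist_col: str = "distance_km"
) -> pd.DataFrame:
    """Return a copy with a per-city ``distance_std`` column."""
    out = df.copy()
    out["distance_std"] = (
        df.groupby(city_col, group_keys=False)[dist_col]
        .apply(lambda s: pd.Series(standardize_distance(s.to_numpy()), index=s.index))
    )
    return out


@dataclass
class ClineFit:
    """One fitted cline for one city and one response."""

    city_id: str
    response: str  # hcn | ac | li | trait
    family: str  # linear_popfreq | logistic_individual | quadratic_popfreq
    beta: float
    se_beta: float
    p_value: float
    n_units: int
    aicc: float
    intercept: float
    r_squared: float | None = None
    quadratic_term: float | None = None
    quadratic_p: float | None = None


def fit_linear_cline(
    pop_freqs: Sequence[float],
    distance_std: Sequence[float],
    city_id: str = "",
    response: str = "hcn",
) -> ClineFit:
    """OLS of population frequencies on standardized distance.

    Populations carry equal weight (no variance weighting); beta is the
    frequency change over the full transect, with a two-sided t-test.
    """
    y = np.asarray(pop_freqs, dtype=float)
    x = np.asarray(distance_std, dtype=float)
    if len(y) < 3:
        raise DegenerateDataError(
            f"{city_id}: need >= 3 populations for a linear cline, got {len(y)}"
        )
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return ClineFit(
        city_id=city_id,
        response=response,
        family="linear_popfreq",
        beta=float(res.params[1]),
        se_beta=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n_units=len(y),
        aicc=_aicc_or_nan(res.llf, k=3, n=len(y)),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
    )


def fit_logistic_cline(
    phenotypes: Sequence[int],
    distance_std: Sequence[float],
    city_id: str = "",
    response: str = "hcn",
) -> ClineFit:
    """Logistic regression of individual plant phenotypes on distance.

    beta is the change in log-odds of being cyanogenic per unit
    standardized distance, with a Wald p-value.  Cities fixed (or
    effectively fixed) for the phenotype, and completely separated data,
    cannot identify the slope and raise :class:`DegenerateDataError`.
    """
    y = np.asarray(phenotypes, dtype=float)
    x = np.asarray(distance_std, dtype=float)
    if y.min() == y.max():
        raise DegenerateDataError(
            f"{city_id}: single phenotype class; logistic cline unidentifiable"
        )
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        raise DegenerateDataError(f"{city_id}: logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise DegenerateDataError(f"{city_id}: separation in logistic fit")
    return ClineFit(
        city_id=city_id,
        response=response,
        family="logistic_individual",
        beta=float(res.params[1]),
        se_beta=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n_units=len(y),
        aicc=_aicc_or_nan(res.llf, k=2, n=len(y)),
        intercept=float(res.params[0]),
    )


def fit_quadratic_cline(
    pop_freqs: Sequence[float],
    distance_std: Sequence[float],
    city_id: str = "",
    response: str = "hcn",
) -> ClineFit:
    """OLS with distance and distance-squared terms."""
    y = np.asarray(pop_freqs, dtype=float)
    x = np.asarray(distance_std, dtype=float)
    if len(y) < 4:
        raise DegenerateDataError(
            f"{city_id}: need >= 4 populations for a quadratic cline"
        )
    X = sm.add_constant(np.column_stack([x, x**2]))
    res = sm.OLS(y, X).fit()
    return ClineFit(
        city_id=city_id,
        response=response,
        family="quadratic_popfreq",
        beta=float(res.params[1]),
        se_beta=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n_units=len(y),
        aicc=_aicc_or_nan(res.llf, k=4, n=len(y)),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        quadratic_term=float(res.params[2]),
        quadratic_p=float(res.pvalues[2]),
    )


def select_family(linear: ClineFit, quadratic: ClineFit) -> str:
    """Pick the model family by lower AICc; ties go to linear."""
    return "quadratic_popfreq" if quadratic.aicc < linear.aicc else "linear_popfreq"


def significance_stars(p: float) -> str:
    """Conventional significance flags: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def city_summary_table(
    fits: Sequence[ClineFit],
    summaries: Sequence[PopulationSummary],
    fixed_threshold: float = FIXED_THRESHOLD,
) -> pd.DataFrame:
    """Assemble a per-city summary of counts, mean HCN frequency, and betas.

    One row per city: population and plant counts, the unweighted mean of
    population HCN frequencies, linear-cline betas for HCN / Ac / Li with
    significance flags, and a ``fixed_excluded`` flag marking cities whose
    mean frequency lies outside ``(1 - fixed_threshold, fixed_threshold)``
    — effectively fixed for the phenotype and excluded from slope
    meta-analysis.
    """
    by_city: dict[str, dict] = {}
    for s in summaries:
        row = by_city.setdefault(
            s.city,
            {"n_populations": 0, "n_plants": 0, "freqs": []},
        )
        if not s.excluded:
            row["n_populations"] += 1
            row["n_plants"] += s.n_records
            row["freqs"].append(s.hcn_freq)

    rows = []
    for city, agg in by_city.items():
        mean_freq = float(np.mean(agg["freqs"])) if agg["freqs"] else np.nan
        row = {
            "city": city,
            "n_populations": agg["n_populations"],
            "n_plants": agg["n_plants"],
            "mean_hcn_freq": mean_freq,
            "fixed_excluded": bool(
                mean_freq > fixed_threshold or mean_freq < 1 - fixed_threshold
            ),
        }
        for resp in ("hcn", "ac", "li"):
            fit = next(
                (
                    f
                    for f in fits
                    if f.city_id == city
                    and f.response == resp
                    and f.family == "linear_popfreq"
                ),
                None,
            )
            row[f"beta_{resp}"] = fit.beta if fit else np.nan
            row[f"p_{resp}"] = fit.p_value if fit else np.nan
            row[f"stars_{resp}"] = significance_stars(fit.p_value) if fit else ""
        rows.append(row)
    return pd.DataFrame(rows).sort_values("city").reset_index(drop=True)
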