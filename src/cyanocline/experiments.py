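"""Parameter-recovery and calibration experiments.

Because the pipeline is validated against synthetic data with known ground
truth, its verification takes the form of simulation experiments: does the
cyanotype-classification + Hardy-Weinberg path recover allele frequencies;
is the fitted linear cline unbiased for the slope implied by the truth
curve; do the cross-city tests hold their nominal size when the truth has
no climate coupling; how does power depend on sampling depth.  Each
experiment is a pure function of its parameters and a seed, and returns
plain dictionaries so callers (tests, the acceptance script, notebooks)
can assert or report as needed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import logit

from . import environment as envmod
from .clines import fit_linear_cline, fit_logistic_cline, standardize_distance
from .genetics import classify_table, infer_allele_freq_dominant
from .meta import pooled_anova, slope_environment_model
from .simulate import (
    CityScenario,
    default_scenarios,
    generate_city,
    generate_multi_city_study,
)

__all__ = [
    "hwe_grid_recovery",
    "cline_recovery",
    "slope_model_test_size",
    "interaction_test_size",
]


def _hcn_freqs_by_population(plants: pd.DataFrame) -> pd.DataFrame:
    """Per-population HCN frequency from Feigl-Anger outcomes."""
    work = plants[plants["feigl_anger"] != "NA"]
    out = (
        work.assign(pos=(work["feigl_anger"] == "pos"))
        .groupby(["city", "population_id"], sort=True)
        .agg(hcn_freq=("pos", "mean"), distance_km=("distance_km", "first"))
        .reset_index()
    )
    return out


def hwe_grid_recovery(
    grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9),
    n_plants: int = 100_000,
    seed: int = 0,
) -> dict:
    """Round-trip allele-frequency recovery over a (p_ac, p_li) grid.

    For each grid point, simulates ``n_plants`` under HWE with flat clines,
    runs the full assay-classification path, pools homozygous-recessive
    counts, and checks that the dominant-marker estimate of each allele
    frequency falls within 3 binomial (delta-method) standard errors of
    the truth.  Returns the fraction of grid points where both loci pass.
    """
    rng = np.random.default_rng(seed)
    passed = 0
    points = [(pa, pl) for pa in grid for pl in grid]
    for p_ac, p_li in points:
        scenario = CityScenario(
            city_id="hwe",
            n_populations=2,
            plants_per_population=n_plants // 2,
            cline_ac=(float(logit(p_ac)), 0.0),
            cline_li=(float(logit(p_li)), 0.0),
        )
        plants, _ = generate_city(scenario, rng)
        cy = classify_table(plants)
        counts = cy.value_counts()
        n = int(counts.reindex(
            ["Ac-Li-", "Ac-lili", "acacLi-", "acaclili"], fill_value=0
        ).sum())
        n_acac = int(counts.get("acacLi-", 0) + counts.get("acaclili", 0))
        n_lili = int(counts.get("Ac-lili", 0) + counts.get("acaclili", 0))
        ok = True
        for n_rec, p_true, locus in ((n_acac, p_ac, "Ac"), (n_lili, p_li, "Li")):
            est = infer_allele_freq_dominant(n_rec, n, locus)
            q_true = 1.0 - p_true
            se = math.sqrt(q_true**2 * (1 - q_true**2) / n) / (2 * q_true)
            ok &= abs(est.q_hat - q_true) <= 3 * se
        passed += ok
    return {
        "n_points": len(points),
        "n_plants": n_plants,
        "fraction_recovered": passed / len(points),
    }


def cline_recovery(
    replicates: int = 500,
    n_populations: int = 40,
    plants_per_population: int = 15,
    cline_ac: tuple = (-0.2, 1.0),
    cline_li: tuple = (0.5, 0.8),
    seed: int = 0,
) -> dict:
    """Bias of the fitted linear cline and linear/logistic sign agreement.

    The estimand is the least-squares slope of the ground-truth population
    frequency curve at the design points (``true_linear_slope``); the
    linear fit on observed frequencies is unbiased for it, so the mean
    fitted beta over replicates should sit within Monte-Carlo error of the
    truth, and the logistic slope on individual plants should agree in
    sign essentially always for a truth this far from zero.
    """
    from .simulate import true_linear_slope

    scenario = CityScenario(
        city_id="rec",
        n_populations=n_populations,
        plants_per_population=plants_per_population,
        cline_ac=cline_ac,
        cline_li=cline_li,
        follow_up_assays=False,
    )
    truth = true_linear_slope(scenario)
    rng = np.random.default_rng(seed)
    betas = np.empty(replicates)
    agree = 0
    for r in range(replicates):
        plants, pops = generate_city(scenario, rng)
        freqs = _hcn_freqs_by_population(plants)
        d_std = standardize_distance(freqs["distance_km"].to_numpy())
        lin = fit_linear_cline(freqs["hcn_freq"].to_numpy(), d_std)
        betas[r] = lin.beta
        d_plants = standardize_distance(plants["distance_km"].to_numpy())
        logi = fit_logistic_cline(
            (plants["feigl_anger"] == "pos").to_numpy(int), d_plants
        )
        agree += np.sign(lin.beta) == np.sign(logi.beta)
    mc_se = betas.std(ddof=1) / math.sqrt(replicates)
    return {
        "replicates": replicates,
        "true_slope": truth,
        "mean_beta": float(betas.mean()),
        "bias": float(betas.mean() - truth),
        "mc_se": float(mc_se),
        "sign_agreement": agree / replicates,
    }


def slope_model_test_size(
    replicates: int = 200,
    n_cities: int = 15,
    n_populations: int = 15,
    plants_per_population: int = 15,
    years: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the cline-strength ~ PC1_slope regression.

    With zero slope-climate coupling, per-city true slopes vary (noise)
    but are independent of climate, so the regression should reject at
    about the nominal rate.
    """
    rng = np.random.default_rng(seed)
    scenarios = default_scenarios(
        n_cities=n_cities,
        n_populations=n_populations,
        plants_per_population=plants_per_population,
        years=years,
    )
    rejections = 0
    for _ in range(replicates):
        bundle = generate_multi_city_study(
            scenarios, slope_climate_coupling=0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        freqs = _hcn_freqs_by_population(bundle.plants)
        betas = {}
        for city, sub in freqs.groupby("city"):
            d = standardize_distance(sub["distance_km"].to_numpy())
            betas[city] = fit_linear_cline(sub["hcn_freq"].to_numpy(), d).beta
        city_env = envmod.build_city_environment(
            bundle.weather, bundle.environment
        ).set_index("city")
        res = slope_environment_model(
            pd.Series(betas), city_env["pc1_slope_score"]
        )
        rejections += res.p_value < alpha
    return {
        "replicates": replicates,
        "alpha": alpha,
        "rejection_rate": rejections / replicates,
    }


def interaction_test_size(
    replicates: int = 200,
    n_cities: int = 15,
    n_populations: int = 15,
    plants_per_population: int = 15,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the pooled-ANOVA city x distance interaction.

    The null is identical true clines in every city: coupling and
    between-city slope noise both zero.
    """
    rng = np.random.default_rng(seed)
    scenarios = default_scenarios(
        n_cities=n_cities,
        n_populations=n_populations,
        plants_per_population=plants_per_population,
        years=1,
    )
    rejections = 0
    for _ in range(replicates):
        bundle = generate_multi_city_study(
            scenarios, slope_climate_coupling=0.0, slope_noise_sd=0.0,
            seed=int(rng.integers(2**31 - 1)), include_weather=False,
        )
        freqs = _hcn_freqs_by_population(bundle.plants)
        freqs["distance_std"] = (
            freqs.groupby("city", group_keys=False)["distance_km"].apply(
                lambda s: pd.Series(standardize_distance(s.to_numpy()),
                                    index=s.index)
            )
        )
        res = pooled_anova(freqs)
        rejections += res.p("city:distance") < alpha
    return {
        "replicates": replicates,
        "alpha": alpha,
        "rejection_rate": rejections / replicates,
    }
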