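"""Synthetic study generator with known ground truth.

Emulates a multi-city urban-rural sampling design for the cyanogenesis
polymorphism: populations spaced along a transect from the urban center,
per-locus allele frequencies following logit-linear clines in standardized
distance, plants drawn under Hardy-Weinberg equilibrium, assay outcomes
corrupted by configurable error rates, GHCN-Daily-like winter weather per
city, per-population environmental values, and primer-pattern panels for
deletion-haplotype analysis.

Every generator is a pure function of (parameters, seed).  A ground-truth
manifest records the parameters each downstream recovery test needs, so
tests never reach into generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .haplotypes import DEFAULT_PATTERN_TABLE, PatternTable

__all__ = [
    "ClimateParams",
    "CityScenario",
    "StudyBundle",
    "generate_city",
    "generate_weather",
    "generate_environment",
    "generate_multi_city_study",
    "generate_haplotype_panel",
    "default_scenarios",
    "true_linear_slope",
]

#: Growing-season months used for the soil-moisture-deficit default.
GROWING_SEASON = (5, 6, 7, 8, 9)


@dataclass(frozen=True)
class ClimateParams:
    """City-level climate ground truth.

    ``mean_winter_tmin`` / ``sd_winter_tmin`` drive the simulated daily
    January-February minimum temperatures (degrees C).  ``snowfall_scale``
    is the mean snowfall (cm) on a snow day; ``snow_persistence`` is the
    per-warm-day probability that existing cover survives (1 = permanent
    cover).  ``mwt``/``mst`` are the BioClim-style minimum-winter and
    maximum-summer temperatures, ``monthly_precip``/``monthly_pet`` are
    12-month series (mm), ``ai`` the annual aridity index, ``years`` the
    number of simulated winters.
    """

    mean_winter_tmin: float = -5.0
    sd_winter_tmin: float = 4.0
    snowfall_scale: float = 2.0
    snow_persistence: float = 0.8
    mwt: float = -10.0
    mst: float = 28.0
    monthly_precip: tuple = tuple([80.0] * 12)
    monthly_pet: tuple = tuple([70.0] * 12)
    ai: float = 1.0
    years: int = 10

    def __post_init__(self):
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if len(self.monthly_precip) != 12 or len(self.monthly_pet) != 12:
            raise ValueError("monthly series must have 12 values")
        if min(self.monthly_precip) < 0 or min(self.monthly_pet) < 0:
            raise ValueError("precip and PET must be non-negative")


@dataclass(frozen=True)
class CityScenario:
    """Ground truth for one simulated city.

    ``cline_ac`` and ``cline_li`` are (intercept, slope) pairs on the logit
    scale for the dominant-allele frequency as a function of standardized
    distance (0 = urban center, 1 = rural end), so frequencies stay in
    (0, 1) and population clines are smoothly sigmoidal.
    """

    city_id: str
    n_populations: int = 40
    transect_length_km: float = 40.0
    cline_ac: tuple[float, float] = (0.0, 0.5)
    cline_li: tuple[float, float] = (0.0, 0.5)
    plants_per_population: int = 15
    assay_false_negative_rate: float = 0.0
    assay_false_positive_rate: float = 0.0
    follow_up_assays: bool = True
    inbreeding_f: float = 0.0
    climate: ClimateParams = field(default_factory=ClimateParams)

    def __post_init__(self):
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations")
        if self.plants_per_population < 1:
            raise ValueError("need at least 1 plant per population")
        for r in (self.assay_false_negative_rate, self.assay_false_positive_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("assay error rates must be probabilities")

    def distances_km(self) -> np.ndarray:
        """Population positions: uniform spacing spanning the transect."""
        return np.linspace(0.0, self.transect_length_km, self.n_populations)

    def allele_freqs(self, d_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth dominant-allele frequencies at standardized distances."""
        d_std = np.asarray(d_std, dtype=float)
        p_ac = expit(self.cline_ac[0] + self.cline_ac[1] * d_std)
        p_li = expit(self.cline_li[0] + self.cline_li[1] * d_std)
        return p_ac, p_li

    def expected_hcn(self, d_std: np.ndarray) -> np.ndarray:
        p_ac, p_li = self.allele_freqs(d_std)
        return (1 - (1 - p_ac) ** 2) * (1 - (1 - p_li) ** 2)


def true_linear_slope(scenario: CityScenario) -> float:
    """Linear-cline slope implied by a scenario's ground truth.

    The population-frequency curve is sigmoidal; the quantity a linear
    cline fit estimates is the least-squares slope of that curve evaluated
    at the design's population positions.  Computed in closed form from the
    noiseless expected frequencies.
    """
    d = scenario.distances_km()
    d_std = (d - d.min()) / (d.max() - d.min())
    f = scenario.expected_hcn(d_std)
    x = d_std - d_std.mean()
    return float(np.dot(x, f - f.mean()) / np.dot(x, x))


def _draw_recessive(rng, q, size, f_inbreeding=0.0):
    """Bernoulli draw of homozygous-recessive state, allowing inbreeding F."""
    q2 = q * q * (1 - f_inbreeding) + q * f_inbreeding
    return rng.random(size) < q2


def generate_city(
    scenario: CityScenario, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one city's plant-record table.

    Returns ``(plants, populations)``.  ``plants`` follows the plant-record
    CSV schema (city, population_id, latitude, longitude, distance_km,
    feigl_anger, plus_linamarin, plus_linamarase) plus hidden truth columns
    ``true_ac_recessive``, ``true_li_recessive``, ``true_hcn``.
    ``populations`` carries per-population coordinates and ground-truth
    frequencies.
    """
    rng = np.random.default_rng(seed)
    d = scenario.distances_km()
    d_std = (d - d.min()) / (d.max() - d.min())
    p_ac, p_li = scenario.allele_freqs(d_std)
    q_ac, q_li = 1 - p_ac, 1 - p_li
    npp = scenario.plants_per_population

    rows = []
    # Transect laid out along a bearing from a city-specific origin; the
    # coordinates are carried for schema completeness, not computation.
    lat0 = 40.0 + (hash(scenario.city_id) % 1000) / 1000.0
    for i in range(scenario.n_populations):
        ac_rec = _draw_recessive(rng, q_ac[i], npp, scenario.inbreeding_f)
        li_rec = _draw_recessive(rng, q_li[i], npp, scenario.inbreeding_f)
        hcn = ~ac_rec & ~li_rec

        fa_pos = np.where(
            hcn,
            rng.random(npp) >= scenario.assay_false_negative_rate,
            rng.random(npp) < scenario.assay_false_positive_rate,
        )
        fa = np.where(fa_pos, "pos", "neg")

        lin = np.full(npp, "NA", dtype=object)   # + linamarin: tests Li function
        lase = np.full(npp, "NA", dtype=object)  # + linamarase: tests Ac function
        if scenario.follow_up_assays:
            neg = ~fa_pos
            fn, fp = scenario.assay_false_negative_rate, scenario.assay_false_positive_rate
            li_dom = ~li_rec
            ac_dom = ~ac_rec
            lin_pos = np.where(
                li_dom, rng.random(npp) >= fn, rng.random(npp) < fp
            )
            lase_pos = np.where(
                ac_dom, rng.random(npp) >= fn, rng.random(npp) < fp
            )
            lin[neg] = np.where(lin_pos[neg], "pos", "neg")
            lase[neg] = np.where(lase_pos[neg], "pos", "neg")

        rows.append(
            pd.DataFrame(
                {
                    "city": scenario.city_id,
                    "population_id": f"{scenario.city_id}_P{i:03d}",
                    "latitude": round(lat0 + d[i] / 111.0, 6),
                    "longitude": -80.0,
                    "distance_km": d[i],
                    "feigl_anger": fa,
                    "plus_linamarin": lin,
                    "plus_linamarase": lase,
                    "true_ac_recessive": ac_rec,
                    "true_li_recessive": li_rec,
                    "true_hcn": hcn,
                }
            )
        )
    plants = pd.concat(rows, ignore_index=True)
    populations = pd.DataFrame(
        {
            "city": scenario.city_id,
            "population_id": [f"{scenario.city_id}_P{i:03d}" for i in range(len(d))],
            "distance_km": d,
            "distance_std": d_std,
            "true_p_ac": p_ac,
            "true_p_li": p_li,
            "true_hcn_freq": scenario.expected_hcn(d_std),
        }
    )
    return plants, populations


def generate_weather(
    climate: ClimateParams,
    seed: int | np.random.Generator,
    station_id: str = "STN",
    months: Sequence[int] = (1, 2),
    off_target_months: Sequence[int] = (),
    missing_day_rate: float = 0.0,
    start_year: int = 2000,
) -> pd.DataFrame:
    """Simulate a GHCN-Daily-like station record for ``climate.years`` winters.

    Daily tmin is Gaussian around ``mean_winter_tmin``; snowfall occurs on
    sub-zero days at mean ``snowfall_scale`` cm; snow depth follows a simple
    accumulate/decay process in which cover survives a warm day with
    probability ``snow_persistence`` (cold days never melt).  Off-target
    months and randomly missing days can be injected to exercise the
    filtering rules downstream.
    """
    rng = np.random.default_rng(seed)
    days_in = {1: 31, 2: 28, 3: 31, 4: 30, 5: 31, 6: 30, 7: 31, 8: 31,
               9: 30, 10: 31, 11: 30, 12: 31}
    all_months = list(months) + list(off_target_months)
    rows = []
    for y in range(climate.years):
        year = start_year + y
        depth = 0.0
        for m in sorted(all_months):
            for day in range(1, days_in[m] + 1):
                tmin = rng.normal(climate.mean_winter_tmin, climate.sd_winter_tmin)
                tmax = tmin + abs(rng.normal(6.0, 2.0))
                if tmin < 0 and climate.snowfall_scale > 0:
                    snow = rng.exponential(climate.snowfall_scale) * (
                        rng.random() < 0.5
                    )
                else:
                    snow = 0.0
                if tmin > 0 and depth > 0:
                    if rng.random() >= climate.snow_persistence:
                        depth = 0.0
                depth += snow
                if missing_day_rate and rng.random() < missing_day_rate:
                    tmin_out = np.nan
                    depth_out = np.nan
                else:
                    tmin_out = tmin
                    depth_out = depth
                rows.append(
                    (station_id, f"{year:04d}-{m:02d}-{day:02d}",
                     tmin_out, tmax, snow, depth_out)
                )
    return pd.DataFrame(
        rows,
        columns=["station_id", "date", "tmin_c", "tmax_c",
                 "snowfall_cm", "snowdepth_cm"],
    ).round({"tmin_c": 3, "tmax_c": 3, "snowfall_cm": 3, "snowdepth_cm": 3})


def generate_environment(
    scenario: CityScenario,
    seed: int | np.random.Generator,
    population_noise_sd: float = 0.2,
) -> pd.DataFrame:
    """Per-population environmental values (BioClim/CGIAR-style extractions).

    Each population's value is the city-level climate truth plus small
    spatial noise, emulating 1-km^2 raster extraction along a transect.
    """
    rng = np.random.default_rng(seed)
    n = scenario.n_populations
    c = scenario.climate
    df = pd.DataFrame(
        {
            "city": scenario.city_id,
            "population_id": [f"{scenario.city_id}_P{i:03d}" for i in range(n)],
            "mwt_c": c.mwt + rng.normal(0, population_noise_sd, n),
            "mst_c": c.mst + rng.normal(0, population_noise_sd, n),
            "apet_mm": 12 * float(np.mean(c.monthly_pet))
            + rng.normal(0, 5 * population_noise_sd, n),
            "ai": np.clip(c.ai + rng.normal(0, 0.01 * population_noise_sd, n), 0, None),
        }
    )
    for m in range(1, 13):
        df[f"precip_mm_{m:02d}"] = np.clip(
            c.monthly_precip[m - 1] + rng.normal(0, population_noise_sd, n), 0, None
        )
        df[f"pet_mm_{m:02d}"] = np.clip(
            c.monthly_pet[m - 1] + rng.normal(0, population_noise_sd, n), 0, None
        )
    return df.round(4)


def default_scenarios(
    n_cities: int = 16,
    n_populations: int = 40,
    plants_per_population: int = 15,
    years: int = 10,
    transect_length_km: float = 40.0,
) -> list[CityScenario]:
    """Scenario set emulating a latitudinal transect of eastern cities.

    Cities are placed along a cold axis ``c`` in [0, 1] (0 = warmest,
    1 = coldest): winter temperatures fall, and snowfall rises, with ``c``,
    mirroring a north-south gradient where southern cities have little snow
    and warm winters.  The default design (16 cities, 40 populations of 15
    plants) matches the sampling scale of the field study this emulates.
    """
    scenarios = []
    cold = np.linspace(0.0, 1.0, n_cities)
    for i, c in enumerate(cold):
        precip = tuple(
            np.round(70 + 40 * np.sin((m - 3) * np.pi / 6) * (1 - 0.3 * c), 1)
            for m in range(1, 13)
        )
        pet = tuple(
            np.round(max(5.0, 60 + 55 * np.sin((m - 3.5) * np.pi / 6)) * (1 - 0.25 * c), 1)
            for m in range(1, 13)
        )
        climate = ClimateParams(
            mean_winter_tmin=float(8.0 - 18.0 * c),
            sd_winter_tmin=4.0,
            snowfall_scale=float(3.0 * c),
            snow_persistence=float(0.5 + 0.4 * c),
            mwt=float(5.0 - 20.0 * c),
            mst=float(33.0 - 10.0 * c),
            monthly_precip=tuple(float(p) for p in precip),
            monthly_pet=tuple(float(p) for p in pet),
            ai=float(0.84 + 0.38 * c),
            years=years,
        )
        scenarios.append(
            CityScenario(
                city_id=f"city{i:02d}",
                n_populations=n_populations,
                transect_length_km=transect_length_km,
                plants_per_population=plants_per_population,
                climate=climate,
            )
        )
    return scenarios


@dataclass
class StudyBundle:
    """Full synthetic study: inputs plus the ground-truth manifest."""

    plants: pd.DataFrame
    populations: pd.DataFrame
    weather: pd.DataFrame
    environment: pd.DataFrame
    manifest: dict


def generate_multi_city_study(
    scenarios: Sequence[CityScenario],
    slope_climate_coupling: float,
    seed: int,
    base_slope_logit: float = 1.5,
    slope_noise_sd: float = 0.5,
    intercept_logit: float = -0.2,
    include_weather: bool = True,
) -> StudyBundle:
    """Generate a full multi-city study with climate-coupled cline slopes.

    Each city's ground-truth logit cline slope (applied identically at both
    loci) is drawn as::

        slope_i = base_slope_logit + slope_climate_coupling * c_i + eps_i

    where ``c_i`` is the city's latent cold axis (min-max standardized
    ``-mean_winter_tmin`` over the scenario set) and ``eps_i`` is Gaussian
    with sd ``slope_noise_sd``.  A negative coupling makes clines weakest in
    the coldest, snowiest cities.  Setting both coupling and noise to zero
    gives identical slopes in every city (the null for interaction tests).
    """
    if len(scenarios) < 3:
        raise ValueError("need at least 3 city scenarios")
    rng = np.random.default_rng(seed)
    tmins = np.array([s.climate.mean_winter_tmin for s in scenarios])
    cold = (tmins.max() - tmins) / (tmins.max() - tmins.min())
    eps = rng.normal(0.0, slope_noise_sd, len(scenarios))
    slopes = base_slope_logit + slope_climate_coupling * cold + eps

    plants_all, pops_all, weather_all, env_all = [], [], [], []
    manifest_cities = {}
    for s, c_i, slope in zip(scenarios, cold, slopes):
        s2 = CityScenario(
            **{
                **asdict(s),
                "climate": s.climate,
                "cline_ac": (intercept_logit, float(slope)),
                "cline_li": (intercept_logit, float(slope)),
            }
        )
        plants, pops = generate_city(s2, rng)
        if include_weather:
            weather_all.append(
                generate_weather(s2.climate, rng, station_id=s2.city_id)
            )
        env_all.append(generate_environment(s2, rng))
        plants_all.append(plants)
        pops_all.append(pops)
        manifest_cities[s2.city_id] = {
            "cold_axis": float(c_i),
            "cline_ac": list(s2.cline_ac),
            "cline_li": list(s2.cline_li),
            "true_linear_slope_hcn": true_linear_slope(s2),
            "n_populations": int(s2.n_populations),
            "plants_per_population": int(s2.plants_per_population),
            "mean_winter_tmin": float(s2.climate.mean_winter_tmin),
            "snowfall_scale": float(s2.climate.snowfall_scale),
        }
    manifest = {
        "seed": int(seed),
        "slope_climate_coupling": float(slope_climate_coupling),
        "base_slope_logit": float(base_slope_logit),
        "slope_noise_sd": float(slope_noise_sd),
        "intercept_logit": float(intercept_logit),
        "cities": manifest_cities,
    }
    return StudyBundle(
        plants=pd.concat(plants_all, ignore_index=True),
        populations=pd.concat(pops_all, ignore_index=True),
        weather=(
            pd.concat(weather_all, ignore_index=True)
            if weather_all
            else pd.DataFrame()
        ),
        environment=pd.concat(env_all, ignore_index=True),
        manifest=manifest,
    )


def generate_haplotype_panel(
    n_plants_per_habitat: int,
    pool_frequencies: dict[str, dict[str, float]],
    seed: int | np.random.Generator,
    cities: Sequence[str] = ("cityA",),
    pattern_table: PatternTable | None = None,
) -> pd.DataFrame:
    """Simulate primer-pair amplification patterns for acyanogenic plants.

    Each plant (double homozygous recessive by construction) carries two
    deletion haplotypes per locus drawn from the habitat-shared pool; the
    emitted 3-bit gel pattern is that of the *larger* deletion alone,
    because larger deletions mask smaller ones on a gel.

    ``pool_frequencies`` maps locus ('Ac', 'Li') to {haplotype_class:
    frequency}; frequencies must sum to 1 per locus.
    """
    table = pattern_table or DEFAULT_PATTERN_TABLE
    rng = np.random.default_rng(seed)
    rows = []
    for city in cities:
        for habitat in ("urban", "rural"):
            for j in range(n_plants_per_habitat):
                plant_id = f"{city}_{habitat}_{j:03d}"
                for locus, freqs in pool_frequencies.items():
                    classes = list(freqs)
                    p = np.array([freqs[k] for k in classes], dtype=float)
                    if abs(p.sum() - 1.0) > 1e-9:
                        raise ValueError(f"{locus} pool frequencies must sum to 1")
                    h1, h2 = rng.choice(classes, size=2, p=p)
                    shown = table.larger(locus, h1, h2)
                    pat = table.pattern(locus, shown)
                    rows.append(
                        (plant_id, city, habitat, locus, h1, h2, shown, *pat)
                    )
    return pd.DataFrame(
        rows,
        columns=["plant_id", "city", "habitat", "locus",
                 "true_hap1", "true_hap2", "true_shown",
                 "pp1", "pp2", "pp3"],
    )
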