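"""Glue between the plant-record table and the per-city cline fits."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clines import (
    ClineFit,
    DegenerateDataError,
    fit_linear_cline,
    fit_logistic_cline,
    standardize_distance,
)
from .genetics import PopulationSummary, classify_table, population_summary

__all__ = ["summarize_populations", "population_frame", "fit_city_clines"]


def summarize_populations(plants: pd.DataFrame) -> list[PopulationSummary]:
    """Classify cyanotypes and aggregate every population in a plant table."""
    work = plants.copy()
    if "cyanotype" not in work.columns:
        work["cyanotype"] = classify_table(work)
    return [
        population_summary(group)
        for _, group in work.groupby(["city", "population_id"], sort=True)
    ]


def population_frame(summaries: list[PopulationSummary]) -> pd.DataFrame:
    """Per-population frame (with standardized distance) for cline fitting."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "city": s.city,
                "population_id": s.population_id,
                "distance_km": s.distance_km,
                "n_plants": s.n_records,
                "hcn_freq": s.hcn_freq,
                "p_ac": s.ac.p_hat if s.ac else np.nan,
                "p_li": s.li.p_hat if s.li else np.nan,
                "excluded": s.excluded,
            }
        )
    df = pd.DataFrame(rows)
    df = df[~df["excluded"]].copy()
    df["distance_std"] = df.groupby("city", group_keys=False)["distance_km"].apply(
        lambda s: pd.Series(standardize_distance(s.to_numpy()), index=s.index)
    )
    return df.reset_index(drop=True)


_RESPONSE_COL = {"hcn": "hcn_freq", "ac": "p_ac", "li": "p_li"}


def fit_city_clines(
    pops: pd.DataFrame,
    responses: tuple = ("hcn", "ac", "li"),
    plants: pd.DataFrame | None = None,
) -> tuple[list[ClineFit], list[dict]]:
    """Fit per-city linear clines (and logistic, when plants are supplied).

    Returns the fits plus a list of skipped (city, response, reason)
    records for cities where a response was unavailable or degenerate.
    """
    fits: list[ClineFit] = []
    skipped: list[dict] = []
    for city, sub in pops.groupby("city", sort=True):
        for resp in responses:
            col = _RESPONSE_COL[resp]
            y = sub[col].dropna()
            if len(y) < 3:
                skipped.append(
                    {"city": city, "response": resp, "reason": "insufficient data"}
                )
                continue
            x = sub.loc[y.index, "distance_std"]
            try:
                fits.append(
                    fit_linear_cline(y.to_numpy(), x.to_numpy(), city, resp)
                )
            except DegenerateDataError as exc:
                skipped.append({"city": city, "response": resp, "reason": str(exc)})
    if plants is not None:
        work = plants.copy()
        if "cyanotype" not in work.columns:
            work["cyanotype"] = classify_table(work)
        work = work[work["feigl_anger"] != "NA"]
        work["y"] = (work["feigl_anger"] == "pos").astype(int)
        for city, sub in work.groupby("city", sort=True):
            d_std = standardize_distance(sub["distance_km"].to_numpy())
            try:
                fits.append(
                    fit_logistic_cline(sub["y"].to_numpy(), d_std, city, "hcn")
                )
            except DegenerateDataError as exc:
                skipped.append(
                    {"city": city, "response": "hcn_logistic", "reason": str(exc)}
                )
    return fits, skipped
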