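"""Published city-level survey summary and its bookkeeping checks.

The package ships the city-level summary of the 16-city eastern North
American field survey of urban-rural cyanogenesis clines: per-city
population and plant counts, mean HCN frequency, and linear-cline slopes
for HCN and (where genotyped) the Ac and Li loci, with significance flags.
Twelve cities were newly surveyed in one season; four northern cities come
from an earlier survey with equivalent methods.  ``survey_summary``
recomputes the study-wide totals from the per-city rows.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_city_survey", "survey_summary"]


def load_city_survey() -> pd.DataFrame:
    """Per-city summary table of the 16-city survey."""
    with resources.files("cyanocline.data").joinpath("city_survey.csv").open() as fh:
        return pd.read_csv(fh, na_values=["NA"])


def survey_summary(df: pd.DataFrame) -> dict:
    """Study-wide bookkeeping derived from the per-city survey rows.

    Totals, the single-season (new-survey) subtotals, the extreme city mean
    HCN frequencies (as percentages), and the share of non-fixed cities
    with a significant linear HCN cline.
    """
    new = df[df["new_survey"] == 1]
    nonfixed = df[df["fixed_excluded"] == 0]
    n_sig = int(df["sig_hcn"].sum())
    return {
        "n_cities": int(len(df)),
        "total_populations": int(df["n_populations"].sum()),
        "total_plants": int(df["n_plants"].sum()),
        "new_survey_cities": int(len(new)),
        "new_survey_populations": int(new["n_populations"].sum()),
        "new_survey_plants": int(new["n_plants"].sum()),
        "mean_populations_per_new_city": float(
            new["n_populations"].mean()
        ),
        "min_mean_hcn_pct": float(np.round(df["mean_hcn_freq"].min() * 100)),
        "max_mean_hcn_pct": float(np.round(df["mean_hcn_freq"].max() * 100)),
        "n_significant_hcn_clines": n_sig,
        "pct_nonfixed_cities_with_cline": float(
            100.0 * df.loc[df["fixed_excluded"] == 0, "sig_hcn"].sum() / len(nonfixed)
        ),
    }
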