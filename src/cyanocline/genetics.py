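"""Two-locus epistatic genetics of the cyanogenesis polymorphism.

Hydrogen cyanide (HCN) release in white clover requires at least one
dominant allele at each of two unlinked loci: *Ac* (CYP79D15, synthesis of
the cyanogenic glucosides linamarin/lotaustralin) and *Li* (linamarase, the
hydrolyzing enzyme).  Only the cyanotype ``Ac-Li-`` is cyanogenic; the three
other classes (``Ac-lili``, ``acacLi-``, ``acaclili``) are acyanogenic.

Phenotyping proceeds by a Feigl-Anger colorimetric assay on intact leaf
tissue, followed, for HCN-negative plants, by two complementation assays
(adding exogenous linamarin, or exogenous linamarase) that separate the
three acyanogenic cyanotypes.

Because both loss-of-function alleles are fully recessive, allele
frequencies are inferred from the frequency of homozygous-recessive
genotypes under Hardy-Weinberg equilibrium: q = sqrt(q2) with q2 the
observed homozygous-recessive fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CYANOTYPES",
    "INDETERMINATE",
    "CONTRADICTION",
    "AlleleFreqEstimate",
    "PopulationSummary",
    "classify_cyanotype",
    "classify_table",
    "hcn_positive",
    "infer_allele_freq_dominant",
    "expected_hcn_freq",
    "population_summary",
]

#: The four reachable cyanotype states.
CYANOTYPES = ("Ac-Li-", "Ac-lili", "acacLi-", "acaclili")

#: Sentinel returned when a required assay outcome is missing.
INDETERMINATE = "indeterminate"

#: Sentinel returned when both complementation assays are positive on the
#: same plant, which is biologically impossible and signals assay error.
CONTRADICTION = "contradiction"

_TRISTATE = frozenset({"pos", "neg", "NA"})


class AssayInvariantError(ValueError):
    """Raised when assay outcomes violate the assay-design invariants."""


def _check_tristate(value: str, name: str) -> None:
    if value not in _TRISTATE:
        raise AssayInvariantError(
            f"{name} must be one of 'pos', 'neg', 'NA'; got {value!r}"
        )


def classify_cyanotype(
    feigl_anger: str, plus_linamarin: str = "NA", plus_linamarase: str = "NA"
) -> str:
    """Classify a plant's cyanotype from its assay triple.

    Parameters
    ----------
    feigl_anger
        Outcome of the Feigl-Anger HCN assay: ``'pos'``, ``'neg'`` or ``'NA'``.
    plus_linamarin
        Outcome after adding exogenous linamarin (substrate).  Positive
        means the plant produces linamarase, i.e. ``acacLi-``.
    plus_linamarase
        Outcome after adding exogenous linamarase (enzyme).  Positive means
        the plant produces glucosides, i.e. ``Ac-lili``.

    Returns
    -------
    str
        One of the four cyanotypes, :data:`INDETERMINATE` when a required
        outcome is missing, or :data:`CONTRADICTION` when both follow-up
        assays are positive.  The decision is deterministic; no class is
        ever guessed.

    Raises
    ------
    AssayInvariantError
        If a follow-up outcome is recorded for a plant whose Feigl-Anger
        assay was not negative (follow-ups are run on HCN- plants only),
        or a value is not a valid tri-state.
    """
    _check_tristate(feigl_anger, "feigl_anger")
    _check_tristate(plus_linamarin, "plus_linamarin")
    _check_tristate(plus_linamarase, "plus_linamarase")

    if feigl_anger != "neg" and (plus_linamarin != "NA" or plus_linamarase != "NA"):
        raise AssayInvariantError(
            "follow-up assays may be recorded only for Feigl-Anger-negative plants"
        )
    if feigl_anger == "NA":
        return INDETERMINATE
    if feigl_anger == "pos":
        return "Ac-Li-"
    # HCN-negative: the two complementation assays separate the classes.
    if plus_linamarin == "pos" and plus_linamarase == "pos":
        return CONTRADICTION
    if plus_linamarin == "NA" or plus_linamarase == "NA":
        return INDETERMINATE
    if plus_linamarin == "pos":
        return "acacLi-"
    if plus_linamarase == "pos":
        return "Ac-lili"
    return "acaclili"


def hcn_positive(cyanotype: str) -> bool:
    """True iff the cyanotype carries a dominant allele at both loci."""
    return cyanotype == "Ac-Li-"


def classify_table(records: pd.DataFrame) -> pd.Series:
    """Vectorized cyanotype classification for a plant-record table.

    Expects columns ``feigl_anger``, ``plus_linamarin``, ``plus_linamarase``
    with values in {pos, neg, NA}; returns a ``cyanotype`` Series aligned to
    the input index.
    """
    fa = records["feigl_anger"].fillna("NA").to_numpy()
    lin = records["plus_linamarin"].fillna("NA").to_numpy()
    lase = records["plus_linamarase"].fillna("NA").to_numpy()

    bad = ~np.isin(fa, list(_TRISTATE)) | ~np.isin(lin, list(_TRISTATE)) | ~np.isin(
        lase, list(_TRISTATE)
    )
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise AssayInvariantError(
            f"invalid assay value in row {records.index[i]!r}"
        )
    followup_on_nonneg = (fa != "neg") & ((lin != "NA") | (lase != "NA"))
    if followup_on_nonneg.any():
        i = int(np.flatnonzero(followup_on_nonneg)[0])
        raise AssayInvariantError(
            "follow-up assay recorded for a non-HCN-negative plant "
            f"(row {records.index[i]!r})"
        )

    out = np.full(len(fa), INDETERMINATE, dtype=object)
    out[fa == "pos"] = "Ac-Li-"
    neg = fa == "neg"
    out[neg & (lin == "pos") & (lase == "pos")] = CONTRADICTION
    out[neg & (lin == "pos") & (lase == "neg")] = "acacLi-"
    out[neg & (lin == "neg") & (lase == "pos")] = "Ac-lili"
    out[neg & (lin == "neg") & (lase == "neg")] = "acaclili"
    return pd.Series(out, index=records.index, name="cyanotype")


@dataclass(frozen=True)
class AlleleFreqEstimate:
    """Dominant-marker allele-frequency estimate under Hardy-Weinberg.

    ``q_hat = sqrt(q2_obs)`` where ``q2_obs`` is the observed frequency of
    homozygous-recessive genotypes; ``p_hat = 1 - q_hat``.  The standard
    error of ``q2_obs`` is binomial and is propagated to ``q_hat`` by the
    delta method, ``SE(q) = SE(q2) / (2 q)``; it is undefined (None) when
    ``q_hat = 0``.
    """

    locus: str
    q2_obs: float
    q_hat: float
    p_hat: float
    n: int
    se_q2: float = 0.0
    se_q: float | None = None


def infer_allele_freq_dominant(
    n_recessive: int, n_total: int, locus: str
) -> AlleleFreqEstimate:
    """Infer allele frequencies at a fully dominant marker locus.

    Under HWE (p^2 + 2pq + q^2 = 1) only the homozygous recessive class is
    phenotypically distinguishable, so q is estimated as the square root of
    the observed homozygous-recessive fraction.

    Raises
    ------
    ValueError
        If ``n_total`` is zero (undefined estimate) or counts are invalid.
    """
    if n_total < 1:
        raise ValueError(f"cannot infer allele frequency at {locus}: no plants")
    if not 0 <= n_recessive <= n_total:
        raise ValueError(
            f"invalid counts for {locus}: {n_recessive} recessive of {n_total}"
        )
    q2 = n_recessive / n_total
    q = math.sqrt(q2)
    se_q2 = math.sqrt(q2 * (1.0 - q2) / n_total)
    se_q = se_q2 / (2.0 * q) if q > 0 else None
    return AlleleFreqEstimate(
        locus=locus, q2_obs=q2, q_hat=q, p_hat=1.0 - q, n=n_total,
        se_q2=se_q2, se_q=se_q,
    )


def expected_hcn_freq(p_ac: float, p_li: float) -> float:
    """Expected frequency of cyanogenic plants under HWE at both loci.

    A plant is cyanogenic iff it carries at least one dominant allele at
    each locus; with independent loci the probability is the product of the
    per-locus dominant-carrier probabilities::

        (1 - (1 - p_ac)^2) * (1 - (1 - p_li)^2)
    """
    if not (0.0 <= p_ac <= 1.0 and 0.0 <= p_li <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return (1.0 - (1.0 - p_ac) ** 2) * (1.0 - (1.0 - p_li) ** 2)


@dataclass
class PopulationSummary:
    """Per-population aggregate of plant assay records.

    ``hcn_freq`` is positives over non-missing Feigl-Anger outcomes.
    Allele-frequency estimates are present only when the complementation
    assays were run (some cyanotype fully resolved); their denominator is
    the count of fully classified plants.  Indeterminate and contradictory
    records are excluded from every frequency but carried as audit counts.
    """

    population_id: str
    city: str
    distance_km: float | None
    n_records: int
    n_phenotyped: int
    n_hcn_pos: int
    hcn_freq: float | None
    n_indeterminate: int
    n_contradiction: int
    cyanotype_counts: dict = field(default_factory=dict)
    ac: AlleleFreqEstimate | None = None
    li: AlleleFreqEstimate | None = None
    excluded: bool = False


def population_summary(records: pd.DataFrame) -> PopulationSummary:
    """Aggregate one population's plant records.

    All rows must share one ``population_id``.  A population with zero
    non-missing phenotypes is flagged ``excluded`` (no frequency defined).
    """
    pops = records["population_id"].unique()
    if len(pops) != 1:
        raise ValueError(f"records span {len(pops)} populations, expected 1")
    city = str(records["city"].iloc[0])
    dist = (
        float(records["distance_km"].iloc[0])
        if "distance_km" in records.columns
        else None
    )

    if "cyanotype" in records.columns:
        cy = records["cyanotype"]
    else:
        cy = classify_table(records)

    fa = records["feigl_anger"].fillna("NA")
    n_pheno = int((fa != "NA").sum())
    n_pos = int((fa == "pos").sum())
    counts = cy.value_counts().to_dict()
    n_ind = int(counts.pop(INDETERMINATE, 0))
    n_con = int(counts.pop(CONTRADICTION, 0))

    summary = PopulationSummary(
        population_id=str(pops[0]),
        city=city,
        distance_km=dist,
        n_records=int(len(records)),
        n_phenotyped=n_pheno,
        n_hcn_pos=n_pos,
        hcn_freq=(n_pos / n_pheno) if n_pheno else None,
        n_indeterminate=n_ind,
        n_contradiction=n_con,
        cyanotype_counts=counts,
        excluded=n_pheno == 0,
    )

    # Allele frequencies require the full cyanotype, i.e. follow-up assays.
    n_classified = sum(counts.values())
    followups_run = (records["plus_linamarin"].fillna("NA") != "NA").any() or (
        records["plus_linamarase"].fillna("NA") != "NA"
    ).any()
    has_neg = (fa == "neg").any()
    if n_classified > 0 and (followups_run or not has_neg):
        n_acac = counts.get("acacLi-", 0) + counts.get("acaclili", 0)
        n_lili = counts.get("Ac-lili", 0) + counts.get("acaclili", 0)
        summary.ac = infer_allele_freq_dominant(n_acac, n_classified, "Ac")
        summary.li = infer_allele_freq_dominant(n_lili, n_classified, "Li")
    return summary
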