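# Methods

## Genetic model and assay logic

A plant's cyanogenesis phenotype is determined by two unlinked diallelic
loci with complete dominance and duplicate-recessive epistasis: *Ac*
(glucoside synthesis) and *Li* (linamarase).  Under Hardy–Weinberg
equilibrium with dominant-allele frequencies p_ac and p_li, the expected
frequency of cyanogenic plants is

    f = (1 − (1 − p_ac)²) · (1 − (1 − p_li)²),

the product of the per-locus dominant-carrier probabilities.  The assay
decision table is deterministic: Feigl–Anger positive ⇒ *Ac–Li–*; negative
with the +linamarin assay positive ⇒ *acacLi–*; negative with the
+linamarase assay positive ⇒ *Ac–lili*; both follow-ups negative ⇒
*acaclili*.  A missing required outcome yields `indeterminate` (never a
guessed class) and both follow-ups positive yields `contradiction`; both
are excluded from every frequency and carried as audit counts — biologically
a contradiction is impossible, so it flags assay error.

Allele frequencies come from the homozygous-recessive fraction: q̂ = √q²
with q² the observed fraction among fully classified plants, p̂ = 1 − q̂.
We assume HWE exactly (no inbreeding coefficient in the estimator);
deviations from HWE perturb this estimator only mildly when dominant
homozygotes and heterozygotes are indistinguishable, and the generator
exposes an optional inbreeding F to probe that robustness.  A binomial
standard error on q² is propagated by the delta method,
SE(q̂) = SE(q²)/(2q̂), undefined (reported missing) at q̂ = 0.

## Synthetic study generator

The generator is the package's substitute for field data and defines the
conditions under which the pipeline is validated.  Defaults mirror the
published sampling design: 16 cities, 40 populations per city (the survey
mean was 38, range 15–45), 15 plants per population, populations uniformly
spaced along a 40 km transect (≥1 km apart).  Per-locus dominant-allele
frequencies follow logit-linear clines in standardized distance — keeping
frequencies in (0, 1) and giving the smooth sigmoidal population-frequency
curves such surveys report — and each plant's genotype is drawn
independently per locus under HWE at its population's frequencies.  Assay
error rates default to 0 (no published estimates exist for the
Feigl–Anger assay); false-negative/positive knobs exist on all three
assays.

Cities sit on a latent cold axis c ∈ [0, 1]: winter minimum temperature
8 → −10 °C, BioClim-style MWT 5 → −15 °C, MST 33 → 23 °C, snowfall scale
0 → 3 cm, aridity index 0.84 → 1.22 (the AI span of the real transect).
In multi-city studies the logit cline slope at both loci is

    slope_i = base + coupling · c_i + ε_i,  ε_i ~ N(0, sd),

so `coupling < 0` makes clines weakest in cold, snowy cities; `coupling =
0` with `sd = 0` is the sharp null (identical clines) used for
interaction-size experiments, and `coupling = 0` with `sd > 0` the null
for the cline-strength regression.  A ground-truth manifest records, per
city, the logit parameters, the latent axis, and the implied linear slope
(below); recovery tests read truth only from the manifest.

Daily winter weather is a simple process chosen to support exactly the
quantities the pipeline consumes: tmin Gaussian around the city's winter
mean; snowfall exponential on sub-zero days; snow depth accumulates and,
on days with tmin > 0, survives with probability `snow_persistence`
(cold days never melt).  This reproduces the snow-buffering direction —
colder, snowier cities have fewer frost-exposed days — but does not
attempt realistic storm structure, diurnal cycles, or multi-station
variation; conclusions about real weather data rest on the filtering and
counting rules, which are exercised by injected missing days and
off-target months, not on the weather model itself.

## Cline estimation

Distance is standardized within city to [0, 1] by an affine map, so every
fit is invariant to units and origin of the raw distances.  The headline
cline strength β is the OLS slope of per-population frequency on
standardized distance, populations unweighted (a variance-weighted option
exists but is off by default, matching the plain-regression convention for
these data).  The logistic family fits individual 0/1 phenotypes by
maximum likelihood; its β is a log-odds change over the transect.  Cities
fixed or effectively fixed for the phenotype cannot identify a slope:
fits raise a degenerate-data error, and cities with mean frequency outside
(0.02, 0.98) are flagged and excluded from the cross-city slope
regression.  The quadratic family adds a d² term; families are compared by
AICc (parameter count includes intercept and residual variance), smaller
wins, ties to linear.  When the design has too few populations for the
small-sample correction (n ≤ k + 1) the AICc is reported as NaN rather
than extrapolated.

Because the truth curve is sigmoidal while the fit is linear, the estimand
of the linear fit is defined as the least-squares slope of the noiseless
expected-frequency curve evaluated at the design points
(`simulate.true_linear_slope`).  The linear fit is exactly unbiased for
this quantity, which is what the recovery experiments check.

## Environmental features

Weather filtering keeps January–February records with non-missing tmin and
snow depth, drops any station-month with fewer than 10 retained days, and
(implicitly) drops years with no qualifying month; each dropped record is
attributed to exactly one rule and the audit counts sum to the input size.
Frost exposure is the mean across years of the per-year count of days with
tmin < 0 °C and snow depth exactly 0 cm.  "Freezing" is read on the daily
minimum by default (`freeze_on="tmax"` is available); zero depth is the
no-cover criterion because trace cover is reported as 0 in GHCN-Daily
exports.

Soil moisture deficit is Precip − PET per month, averaged over
May–September (the growing season); "summer precipitation" for the
composite axis uses the same months.  City-level values of MWT, MST, AI,
annual PET, SMD and summer precipitation are unweighted means over
populations.

Composite axes use PCA on the correlation matrix (variables carry
incommensurate units; scaling also makes scores unit-invariant), computed
by SVD of the centered/scaled matrix.  PC1_HCN summarizes MST, MWT, summer
precipitation, annual PET and snowfall; PC1_slope summarizes snow depth,
snowfall, MWT and MST.  The sign of each axis is fixed so snowfall loads
positively — low scores mean warm, low-snow cities — making regression
signs comparable across runs.

## Cross-city inference

The pooled model freq ~ city × distance uses sum-to-zero contrasts on city
and type-III marginal F-tests, computed as full-vs-reduced comparisons
(the only construction under which "type III" is meaningful with
interactions present).  On binomial per-population proportions at 15
plants the interaction F runs mildly conservative (empirical size ≈ 2–4%
at nominal 5%) because the response variance depends on the mean; the
calibration experiments quantify this, and it is a property of ANOVA on
proportions, not of the implementation (Gaussian-error simulations
reproduce the nominal 5%).

Model selection fits OLS for every subset of the candidate predictors
(intercept-only included), ranks by AICc with k counting intercept,
slopes, and residual variance, retains models within 2 AICc units of the
best, and renormalizes Akaike weights over the retained set.  Averaged
coefficients use "full" averaging: a predictor absent from a model
contributes 0.  Averaged standard errors use the unconditional formula
SE = Σᵢ wᵢ √(varᵢ + (bᵢ − b̄)²), with z = |b̄|/SE and a normal p-value;
the exact SE adjustment behind published z-statistics for averaged
coefficients is not standardized, so this widely used form is the
package's choice.  Conditional averaging is not implemented.

The cline-strength model is OLS of per-city linear β on PC1_slope after
dropping effectively fixed cities; it reports coefficient, SE, t, p, R².

The power analysis simulates replicate cities whose expected HCN frequency
runs from a baseline to baseline + slope across the transect (per-locus
frequencies equal at both loci and pinned to hit the endpoints), fits the
linear cline, and reports the rejection fraction with a Wilson 95% CI.
"Similar power" between sampling depths is read as overlapping CIs.

## Haplotype analysis

Only double-recessive (*acac lili*) plants are haplotyped, since only they
are guaranteed to carry deletions at both loci.  The pattern table mapping
3-bit primer-pair patterns to deletion classes is configuration: the
shipped default is a synthetic placeholder with 2 *Ac* and 4 *Li* classes
under a strict size order, chosen to match the published class counts
without asserting an unpublished mapping.  The generator applies the gel
rule — a diploid's emitted pattern is the larger deletion's pattern — so
the resolver only ever sees gel patterns, and true haplotype frequencies
are unobservable by construction; analyses therefore use presence/absence
only.  Richness is the count of distinct assigned classes per
city × habitat × locus (unassigned calls excluded), compared between
habitats by one-way ANOVA (equal to the pooled t-test squared for two
groups).

## Problem sizes and numerical choices

Validation experiments use: 25 grid points × 10⁵ plants for the HWE round
trip; 500 replicate cities at 40 × 15 for cline recovery; 200 replicate
15-city studies (15 populations × 15 plants, 2 simulated winters) for each
test-size experiment; 200 replicates per design for power.  These sizes
give Monte-Carlo standard errors comfortably inside the tolerances being
checked while keeping a full run to a few minutes.  All generators are
pure functions of (parameters, seed); study-level runs derive per-stage
seeds from one seed via a seed sequence.  Ties in AICc go to the simpler
model; PCA raises on constant variables rather than imputing; the
two-group richness F is defined as 0 when both groups are constant with
equal means.

## Limitations

The pipeline consumes already-extracted per-population environmental
values; raster/GIS extraction is out of scope.  One weather station per
city is assumed (station id doubles as the city key).  No spatial
autocorrelation or mixed-effects structure is modeled in the cline or
cross-city regressions.  The synthetic generator's parameter-recovery
results validate the estimators under its own assumptions (HWE, logit
clines, independent populations); they cannot certify behavior under
strong inbreeding, clonal resampling, or migration structure in real
transects.
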