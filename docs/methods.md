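# Methods

This note documents the models, parameter choices, and numerical decisions
behind each stage of the pipeline, and what the synthetic-world validation
does and does not establish about behaviour on real data.

## The synthetic world

**Truth model.** Cause-specific death rates follow a log-linear
epidemiological transition in SDI:

    log m(cause, age, sex, location, year)
        = α_group + leaf offset + β_group · SDI(location, year)
        + γ(age) + δ(sex) + u(location, cause)

with group slopes β on the log scale of −3.0 (CMNN), −0.4 (NCD), and −1.2
(injuries): communicable, maternal, neonatal and nutritional mortality falls
steeply with development, non-communicable mortality is nearly flat, and
injuries sit between — the qualitative ordering that defines the
epidemiological transition.  The age pattern γ is U-shaped (elevated
infancy, minimum in late childhood, Gompertz-like log-linear rise to the
terminal group); δ is ±0.15 by sex; u is Normal(0, 0.3²) location-cause
noise.  SDI trajectories are linear per location (default starting values
spread over 0.15–0.85, +0.005/year, clipped to [0, 1]).  Default scale is
20 locations × 1990–2016 × 23 age groups (three neonatal/post-neonatal
groups, 1–4, 5-year groups to 90–94, and 95+) × 2 sexes over a three-group,
nine-leaf cause tree.  The analysis drivers run 12 locations × 2000–2016;
these sizes keep every driver and the full test suite in seconds-to-minutes
on a single core while leaving all estimators comfortably identified.

**Observation model.** The simplest generative model consistent with count
data: cell counts are Poisson around true deaths, thinned Binomial(n, C)
for completeness C, then a Binomial share with age-dependent probability
g(a) = g_max · logistic(s·(a − a₀)) is moved onto garbage codes
(defaults g_max = 0.25, midpoint a₀ = 14 ≈ ages 60–64, steepness 0.25 per
age-group index; garbage coding must rise with age, the specific logistic is
a modelling choice).  Garbage deaths split across the garbage-code register
with weight 3:1 in favour of major codes.  VA-source strata additionally
pass cause-coded deaths through a row-stochastic misclassification matrix
(default: 0.70 on the diagonal, remainder uniform — chosen to sit near the
published 0.64 chance-corrected concordance of physician-certified VA; the
matrix form itself is a modelling choice, no published matrix exists).
Completeness defaults to clip(1.35·SDI − 0.08, 0, 1); source type defaults
to VR above SDI 0.5, VA in 0.25–0.5, and no registration below.

**What this emulates and what it does not.** The generator reproduces the
*structure* of real defects (incompleteness, age-linked garbage,
source-dependent cause detail, VA error) but not their empirical messiness:
no ICD-revision breaks, no age/sex-unknown deaths, no aggregate age groups,
no policy shocks or fatal discontinuities, and misclassification constant
over time.  Passing tests therefore establish correctness of the
*algorithms* under the stated defect model, not performance on any real
registry.

## Star rating

W = 100·C·(1−G)·D per location-year, where G is the major-garbage fraction
(deaths on codes that redistribute across hierarchy Levels 1–2 ÷ all
recorded deaths) and D the detailed-cause fraction.  D is defined as deaths
coded to Level-3/4 causes ÷ all recorded deaths (garbage excluded from the
numerator only); the denominator convention is a package decision.  VA is
multiplied by 0.64 and subnational VA by a further 0.10.  Star bins are
left-closed exactly as ordered: ≥85 → 5, [65, 85) → 4, [35, 65) → 3,
[10, 35) → 2, (0, 10) → 1, 0 → 0.

The full-period (1980–2016) W is the deaths-weighted mean of yearly values
(equal weights when no death weights exist); the aggregation is not
specified anywhere authoritative, and the packaged reference table carries
the printed full-period column directly, so validation against it is
insensitive to this choice.  Two reference rows are ambiguous at one-decimal
printing precision (a 0.0 that earns one star, a 65.0 that earns three);
`assign_stars` resolves any row whose printed value lies within half a
printing unit of the bin edge implied by its printed rating, and raises on
genuinely inconsistent ratings.

## Redistribution and completeness correction

Sources are excluded when VR completeness < 0.5 or when > 50% of a
location-year's deaths sit on major garbage codes; VR completeness in
[0.5, 0.7) is retained but flagged non-representative, which downstream
inflates observation variance (default ×2, configurable).

Garbage moves by one of three methods per code: *proportional* to observed
target-cause deaths within the same location-year-age-sex stratum (uniform
over the target set when all observed targets are zero — conserving mass
without borrowing across strata); *fixed* stated proportions (which also
covers fractional reassignment of multi-cause records); or *regression* —
log target share modelled linearly in age index, a male indicator, and an
optional covariate across strata, exponentiated and renormalised.  The
regression form is a single documented simplification of the family of
fitted redistribution models used at full scale.  Total deaths are conserved
per stratum to 1e-9 by construction, and redistribution uncertainty is not
propagated.

Completeness correction multiplies each cell's cause fractions by the
all-cause envelope, so cell totals equal the envelope exactly; it errors on
a zero envelope with positive recorded deaths rather than imputing.

## Ensemble estimation

The candidate pool is every non-empty covariate subset × two response
spaces (log death rate; logit cause fraction with a 1e-6 floor/ceiling),
optionally with a location random intercept (fitted by `MixedLM`; plain OLS
otherwise), capped with a deterministic order.  Candidates must carry the
expected sign and p < α (default α = 0.05, two-sided) on every constrained
coefficient in every training fold, else they are dropped and logged.

Out-of-sample scoring partitions location-years into k seeded folds
(default 5) and records level error (RMSE of held-out log rates) and trend
error (RMSE of held-out year-on-year first differences in log space).
Weights are rank-exponential: weight ∝ exp(−r̄/T) on the combined rank r̄
(mean of level and trend ranks; missing trend ranks worst), temperature
T = 1 by default — a monotone-in-rank, single-knob stand-in for the
unpublished production weighting.  Draws sample a model per draw by weight,
coefficients from the fitted multivariate-normal sampling distribution
(SVD-based sampling, so exactly-singular covariances from frozen fits are
valid), and add Normal observation noise at the fitted residual variance,
inflated for non-representative rows.  Spatial pooling is a location random
intercept only; there is no space-time residual smoothing.

Rare causes use an intercept-only NB2 negative-binomial regression on a
log-exposure offset; when the dispersion estimate collapses to the boundary
(< 1e-3) the fit degenerates to its Poisson limit, whose mean is exact.
All-zero series return zero draws with a warning rather than an error.

## Envelope rescaling and uncertainty

Within each location-year-age-sex cell and each draw index, every
most-detailed cause is multiplied by envelope/Σ causes; draw pairing is
positional (cause draw i with envelope draw i), the only coherent way to
propagate the correlation the draw representation implies.  A cell whose
cause models all predict zero against a positive envelope raises.  The
miscoding-aware variant that restricts rescaling within specific cause
pairs is not implemented; the generic proportional rescale stands in.
Point estimates are draw means; 95% uncertainty intervals are 2.5th/97.5th
percentiles with linear interpolation between order statistics (so an
independent sort-based oracle matches bit for bit).  Change over time is
significant when ≥95% of paired draws move in one direction (inclusive
boundary: 950/1000 counts, 949/1000 does not).

## Burden

YLL(a) = deaths(a) × SLE(a), draw-wise.  The packaged standard life table
and standard population are synthetic stand-ins satisfying the stated
anchors — SLE(birth) = 86.6 years, strictly decreasing
(SLE(x) = 86.6 − x + 0.00167·x² at age-group midpoints), weights
non-negative summing to 1 — and both are plain two-column CSVs so reference
tables can be dropped in.  Age standardisation is the weighted sum of
age-specific rates (pass rates per 100 000 to obtain the standardised rate
per 100 000).  The annualised rate of change is the log ratio per year,
ARC = 100·ln(v₂/v₁)/years, the natural annualisation; draws with a zero
baseline are excluded from change summaries and counted as missing.

## SDI and expected burden

SDI is the geometric mean of three indices rescaled to [0, 1]: log income
per capita (anchors 250–60 000), mean education years 15+ (0–17), and
inverted total fertility (1–8 births).  Anchors are configuration with the
stated defaults.  Quintile cut-points come from the reference-year SDI
distribution (20/40/60/80th percentiles); membership is time-invariant and
a value tying a cut-point falls in the lower quintile.  Expected curves are
GP regressions of log rate on SDI with an amplitude × squared-exponential
kernel plus a white-noise nugget, hyperparameters by marginal-likelihood
maximisation with two seeded restarts (deterministic given data and
configuration); rates are floored at 1e-12 before the log.  Expected burden
uses the point SDI of each location-year, not an integral over the SDI
path.  O/E ratios aggregate observed and expected over ages *before*
dividing and return a missing marker on a zero expectation.

## Validation experiments

`codkit.experiments` fixes the study conditions shared by the tests and the
analysis drivers.  The ensemble recovery panel is 20 locations × 10 years
(200 location-years) with truth from a known pool member
(log m = α + β·x1 plus Normal(0, 0.3) cell noise), Poisson observation at
population 10⁶, a noise covariate x2, 5 folds and 1000 draws; the
cause-fraction denominator is the *observed* total deaths (as in a real
database), and the rescaling envelope carries independent 5% lognormal draw
noise, emulating a separately estimated all-cause analysis.  Under these
conditions the corrected 95% intervals cover truth at their nominal rate
and the ensemble's held-out RMSE beats the pool median.  The GP experiment
uses 120 (SDI, rate) pairs with 0.3 log-scale noise and checks band
coverage of the generating line plus an O/E of 1 on data drawn from the
expected model.  The conservation cube (20 × 5 × 23 × 2 × 8 × 100 draws)
exercises the rescaling constraint at scale.

## Known limitations

Beyond the observation-model simplifications above: no ICD bridge coding or
age/sex splitting (records are generated already split); no shock/fatal-
discontinuity handling; no subnational hierarchies; redistribution
uncertainty is not propagated; covariate uncertainty is not propagated into
draws; and the GP curves condition on point SDI.  The star-count validation
rests on the printed reference table, not on re-deriving each country's
percent well certified from microdata.
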