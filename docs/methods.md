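# Methods

## The WISN model

WISN (Workload Indicators of Staffing Needs) expresses a cadre's required
staffing at a facility as the staff-time the observed workload would
consume, divided by the time one worker has available:

- **AWT** (available working time, h/year) = `[A − (B+C+D+E)] × F`, where
  `A` is working days per year, `B`–`E` annual/sick/public-holiday/other
  leave days, and `F` hours per working day. The default leave policy is
  `A=313, B=12, C=10, D=17, E=10, F=8` → **2112 h/year**, the allotment
  used by Indian public-sector WISN studies under a six-day week. This is
  an assumption, configurable via `LeavePolicy`; facility surveys rarely
  record local leave practice.
- **HSA requirement**: each health service contributes
  `annual volume / standard workload`, with standard workload
  `AWT / unit_time`; unit times are ingested in minutes per service unit
  and normalised to hours internally (the normalisation is exactly
  invertible, covered by a property test).
- **CAF** = `1/(1 − CAS/100)` multiplies the HSA requirement for support
  work done by all cadre members; CAS input is accepted either as a
  fraction of AWT or as annual hours (a `cas_units` column flag in the
  panel CSV disambiguates; hours are converted via AWT).
- **IAF** = `Σ (hours × staff involved) / AWT` adds absolute staff-time for
  additional activities done by select members.
- **WISN** = `HSA × CAF + IAF`, rounded to an integer. The default
  rounding is **half-up** (0.5 always rounds up, not banker's rounding); a
  ceiling rule is available because practice differs across WISN studies.

Exclusion filters, applied after rounding with a fixed precedence
(facility-level reasons dominate cadre-level ones):

1. `under_half_workweek` — average weekly hours < 24, i.e. below half the
   standard 48 h workweek; the facility operates partially.
2. `null_wisn` — rounded WISN = 0. "Null" is interpreted on the rounded
   value (configurable to raw = 0 by checking `wisn_raw` instead; the
   rounded reading is the stricter and is what the integer-count model
   consumes).
3. `null_iaf_nurse` — nurse cadres (PHC-nurses, CHC-nurses) with a zero
   individual-allowance component; for nurses the IAF is a substantial
   share of workload, so a missing component signals incomplete reporting
   rather than a true zero.

## National threshold model

Facility observations are repeated over years and clustered within states,
so a population-averaged model is used rather than a subject-specific one:

    log E[WISN_ij] = β0 + β1·State + β2·Year,

fitted by GEE with **facility as the cluster** and state/year as fixed
categorical covariates. The data are collected by state, but the repeated
measurements that induce within-cluster correlation are a facility's
yearly observations; facility-level clustering is the only choice
consistent with an AR(1)-over-years working structure, with state retained
as a covariate. Outcomes are the rounded WISN values (Poisson, log link);
a companion quasi-Poisson fit on the raw values supplies a raw mean and SE
on the same mean structure. Robust (sandwich) covariances are used
throughout; convergence tolerance 1e-8, at most 100 iterations,
non-convergence is flagged, never silently dropped.

Three working correlations are fitted (independence, exchangeable, AR(1)
on the within-facility year order) and selected by **QIC in Pan's (2001)
formulation**, computed in-package:

    QIC = −2·Q(β̂; independence) + 2·trace(Â_I · V̂_robust),

with `Q = Σ (y log μ − μ)` the Poisson quasi-likelihood at scale 1 and
`Â_I = X'diag(μ)X` the independence-model information. (The statsmodels
`qic()` penalty uses an unweighted `D'D` Gram matrix, which is not Pan's
`D'V⁻¹D`; the GEE fit and robust covariance still come from statsmodels.)
A known limitation, confirmed in simulation here: QIC discriminates
working-correlation structures weakly — on strongly exchangeable data it
usually still prefers independence, because its goodness-of-fit term is
evaluated under independence. Selection is therefore reported, determinate
and reproducible, but should be read as a tie-break between asymptotically
equivalent marginal fits, not as an inference about the true correlation.

The **national threshold** is the marginal mean of the selected fit,
averaged over the observed state × year design with **equal weight per
observed cell** (an estimate "averaged over states and years"; an
observation-weighted option exists and coincides on balanced panels — a
tested invariant). The 95% CI is delta-method on the log scale
(`exp(log μ̂ ± 1.96·se/μ̂)`), keeping the interval positive. The integer
threshold used downstream is the half-up-rounded marginal mean of the
count model. Reference categories are first state / earliest year; results
are invariant to relabeling (tested).

Across-state heterogeneity is assessed beforehand by a tie-corrected
Kruskal–Wallis test on the raw WISN values per combo (raw, because
rounding saturates small-valued cadres; nonparametric, because the
facility distributions are skewed).

## Projections and categories

For state or national staffing (`P` in-position, `S` sanctioned, `N`
functional centres) and threshold `WISN`:

    ratio          = P / (WISN·N)
    diff_per_centre = P/N − WISN        diff_overall = P − WISN·N
    sanct_diff_*    = same with S

Category rules: differences = 0 → balance/optimal, > 0 → surplus/over,
< 0 → shortage/under; ratio bins [0, 0.25) very high, [0.25, 0.5) high,
[0.5, 0.75) medium, [0.75, 1) low pressure, ≈1 normal, > 1 none. The
published bin edges overlap at 0.25/0.5/0.75; the half-open-left
convention is adopted, with a 1e-9 tolerance for the ratio = 1 and
difference = 0 cases — deterministic and immaterial at data scale. The
national row is computed from summed `P`, `S`, `N` over included states
(aggregation consistency is tested), and every row satisfies
`ratio = 1 + diff_overall/(WISN·N)` exactly. Integer thresholds, not raw
means, enter the projections, matching how planning tables are used.

## Agreement statistics

- **Spearman correlations** between state-level WISN ratios: pairwise for
  centre types with two cadres, partial for more. Partial correlations are
  computed on mid-ranks via OLS residualisation against the rank-transformed
  controls, which agrees with the inverse-rank-correlation-matrix
  formulation to 1e-10 (both are implemented; the agreement is a standing
  cross-check). Listwise deletion handles missing states. p values use the
  t approximation with `n − 2 − #controls` degrees of freedom.
- **Lin's CCC**: `R_C = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with population
  (1/n) moments per Lin's original estimator (a sample-moment option is
  exposed for sensitivity); bias-correction factor `C_b = R_C / r`. The CI
  is a Fisher-type z interval with Lin's (1989) asymptotic variance — the
  CI method is an assumption, as agreement tables in the field rarely state
  one. `R_C < 0.90` is flagged as poor agreement.
- Significance threshold 0.05 without multiplicity correction, matching
  common practice in workforce studies; with 28 CHC pairs this inflates the
  family-wise error rate — a documented limitation.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, not any
particular survey instrument:

- **Panel geometry** (defaults): 5 states × 8 years (2007–2014) × 8
  centre-cadre combinations (PHC nurses/doctors; CHC nurses, GDMOs,
  physicians, surgeons, OBGYNs, paediatricians), 6 facilities per state and
  centre type, with cells missing completely at random at rate 0.5 —
  yielding the unbalanced ~100–200 observations per combo that facility
  surveys produce. Real missingness is unlikely to be MCAR; this is the
  simplest structure with no stated alternative.
- **Service volumes**: negative binomial (Poisson at overdispersion 0,
  default variance inflation 0.1) with mean = base volume × state effect
  (0.8–1.2, mean 1) × year trend (default flat) × a lognormal per-facility
  size multiplier (sd 0.2, mean 1, shared across the facility's years — the
  within-facility correlation the GEE clusters on). Volumes are independent
  across services given these effects; no joint structure is asserted.
- **Combo profiles by inversion**: given a target per-centre requirement
  `w` (defaults 14.9/1.8 PHC nurses/doctors, 45.1/3.3 CHC nurses/GDMOs,
  1.6/1.3/1.1/1.3 CHC physicians/surgeons/OBGYNs/paediatricians — tens of
  nurses, a few doctors per centre), base volumes are solved so the
  analytic WISN of the mean facility equals `w` exactly. This makes
  end-to-end parameter recovery a meaningful test: thresholds recovered
  from 100-facility-year no-effect panels equal `w` after rounding in
  ≥ 90% of seeds (measured at 100% over 50 seeds for w ∈ {2, 4, 15, 45}).
- **Degenerate cases** by rate: 5% of facilities run under 24 h/week
  (exercising the partial-workweek exclusion) and 5% of records lack
  additional activities (exercising the nurse-IAF exclusion).
- **State staffing table**: ~30 states with 80–2000 PHCs and 15–400 CHCs;
  `S = round(w × sanction_bias × N)` with default bias 0.6 (systematic
  under-sanctioning), `P = round(fill × S)` with default fill 0.85 jittered
  by a shared lognormal per-state level (sd 0.3) plus per-cadre noise
  (sd 0.15), clipped so `P ≤ S`. The shared state level is what produces
  positive cross-cadre workload-pressure correlations.

What passing tests on this generator do **not** show: robustness to
informative missingness, to cross-service volume correlation, to
reporting/measurement error in activity times, or to heterogeneity in
leave policies — none of which the generator models.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at 3–6
facilities per state (≈900 activity records, ≈110 retained observations
per combo) and the recovery experiment at 100 facility-years × 50 seeds ×
4 targets; these sizes put every Monte-Carlo check well inside its
sampling-error tolerance while completing in about a minute. Seeds are
threaded from a single run seed through `numpy.random.SeedSequence`; all
stages are deterministic given config + seed (byte-identical outputs,
tested). Ties in QIC selection break toward the first structure in
(independence, exchangeable, ar1) order. Division-guard errors (zero
variance, all-leave policies, shares summing to ≥ 1, singular control
matrices) raise immediately with the offending field or service named.
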