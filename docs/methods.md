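# Methods

## Estimation procedure

The pipeline estimates, for every health-commissioning area, the annual
number of hospital-presenting self-harm episodes and their general-
hospital cost, from (i) an episode-level register covering the catchment
of three sentinel hospital centres and (ii) national geography tables
(population pyramids by single year of age and gender, Market Forces
Factor price indices, age-standardised suicide rates, rural population
fractions).

**Incidence.** The presentation rate per person-year is the episode count
divided by the catchment population, per (age, gender) cell; events are
episodes, not persons, so a person presenting twice contributes two
events. Ages above `age_cap` (default 90) are pooled into one open band
because single-year cells empty out at the oldest ages. Each area's
expected presentations are rate × population per cell, kept fractional
end-to-end (rounding only at report formatting, since downstream cost
multiplication needs unrounded values). Populated area cells with no
sentinel rate — possible only through an age-cap mismatch — get rate 0
and a logged flag rather than a borrowed neighbour rate: conservative and
transparent. National *patient* counts are episodes scaled by the
sentinel patients-to-episodes ratio per gender; this is a declared
approximation, as patient-level rates are not estimated.

**Costing.** Two centres supply per-episode finance-department costs; one
does not. One centre's recorded costs exclude the psychosocial
assessment, so £392 (patients younger than 18) or £228 (adults) is added
to each *assessed* episode there before modelling; the inclusion flag is
flipped afterwards, making the operation idempotent. The imputation is
applied per assessed episode (a per-patient reading is conceivable but
less natural for episode costs). A Gamma GLM with log link is then fitted
to the cost-observed episodes on gender, age (continuous per-year; a
10-year-band switch exists in the configuration), assessment, admission
and method contrasts against self-poisoning (the modal class). Standard
errors are one-way cluster-robust over patients. Fitting and the sandwich
covariance are delegated to statsmodels (`GLM` with `cov_type="cluster"`);
an independent score-equation check (Σ xᵢ(yᵢ−μᵢ)/μᵢ ≈ 0 at β̂) guards the
fit in the test suite. Episodes with non-positive recorded cost (possible
in finance exports) are excluded from fitting with a logged count — the
Gamma support is positive and a two-part model is out of scope — but
still receive predicted costs for aggregation.

Predictions for the cost-missing centre are exp(x·β̂) × mff_target /
mff_fit, where mff_fit is the episode-weighted mean price index of the
fitting centres. This convention makes a flat price index an exact no-op
and leaves observed costs untouched (only predictions are rescaled).

Mean cost per (age, gender) cell is the arithmetic mean over all episodes
carrying a cost — observed for the cost-observed centres, predicted for
the cost-missing one (a configuration switch prices every centre from the
model instead). Cells with fewer than `cost_cell_min_n` (default 5)
episodes take their enclosing 10-year band mean; an empty band falls back
to the gender-wide mean. Both fallbacks set a `pooled_flag`.

**Aggregation and uncertainty.** Area totals are Σ cells of expected
presentations × mean cost. Uncertainty from the cost-model transfer is
propagated by drawing β\* from N(β̂, V̂) per iteration (default 10,000),
recomputing predicted costs, the pooled mean-cost table and all totals,
and taking percentile intervals (2.5th/97.5th at the default 95% level).
Percentile rather than normal-theory intervals: they are the standard
Monte-Carlo reading and assumption-light. Only coefficient uncertainty
varies across draws — incidence and directly observed costs are held
fixed, matching the estimation design where the drawn quantity is the
regression coefficient vector. Since pooling-group memberships do not
depend on the drawn costs, each iteration reduces to one matrix-vector
product (exp(X_pred β\*) summed into groups), which is how 10,000
iterations stay near-instant. A non-PSD covariance (possible from
numerical asymmetry) is projected to the nearest PSD matrix with a
warning. If V̂ = 0 every draw coincides and the interval collapses to the
point estimate, which the tests assert.

**Sensitivity analyses.** Two univariate recalibrations of incidence,
each applied alone: (i) suicide-rate — factor(area, gender) =
area ASR ÷ mean ASR of the three sentinel centre areas; (ii) rurality —
factor = 1 − rural_fraction × reduction (0.31 male / 0.26 female), a
linear interpolation between the urban endpoint (1.0) and the fully-rural
endpoint; a binary mode (full reduction iff rural_fraction > 0.5) is
available behind a configuration switch, since a rural/urban
classification could be read either way. Suicide factors apply uniformly
across ages within gender. Adjusted runs reuse the same Monte-Carlo
machinery, so adjusted totals also carry intervals. Cost totals inherit
the adjustment linearly (factor × presentations × mean cost, exact).

**Reporting.** The 2017-price figure multiplies the national total by the
Hospital & Community Health Services index (1.04062). Presentations- and
patients-per-suicide ratios divide national totals by registered suicide
deaths per stratum, reported to the nearest integer with the unrounded
value retained.

## Synthetic-data generator

The generator emulates the confidential sentinel register plus the
geography inputs, with full closed-form ground truth.

*Episodes.* Three centres with contrasting case-mix: assessment
probabilities 0.73 / 0.58 / 0.50 and admission probabilities 0.78 / 0.55 /
0.37 across centres A–C, self-poisoning shares 0.66 / 0.76 / 0.63, female
shares 0.56–0.60. Ages are drawn from band mixtures (modal male band
40–49 at 30%, modal female band 19–29 at 28%), uniform over integer years
within band. Each episode beyond a stratum's first is a repeat with
probability `repeat_prob` (default 0.12) and is attached to a uniformly
chosen existing patient of the same centre and gender; a patient keeps
one age, so repeat episodes carry consistent demographics. Costs are
Gamma with shape 2 and mean exp(x·β)·mff·exp(b), where b is a log-normal
patient intercept (sd 0.25, the simplest positive-cost clustering
mechanism) and β defaults to intercept 6.109, male 0.10, age 0.008/yr,
assessed 0.35, admitted 0.90, injury −0.15, both +0.20 — giving a mean
episode cost around £1,600 with strong admission and assessment
gradients. The faithful preset totals 12,000 episodes over a two-million-
person catchment (≈ 6 presentations per 1,000 per year concentrated in
ages 10–84); the tiny preset scales to 800 episodes for smoke tests.

For the centre whose recorded costs exclude assessment, the generator
draws the partial cost from a Gamma with mean exp(x·β) − c, so the
post-imputation cost (partial + c) has exactly the model mean. The
post-imputation distribution is a shifted Gamma rather than a Gamma; the
quasi-likelihood estimator is consistent and the sandwich covariance
valid under mean-correctness, which is what the recovery and coverage
tests rely on. With `patient_effect_sd = 0` the mean model holds exactly
and every coefficient is identified.

*Geography.* Twelve commissioning areas (six in the tiny preset) with
England-like pyramids tilted young/old per area, total populations
150k–500k, price indices 0.95–1.12, suicide rates around 15 (male) and
4.5 (female) per 100,000 with ±30% area variation, rural fractions 0–0.8.
The three centre areas are mostly urban and a designated catchment area
is their exact population sum. A `price_variation` switch sets every MFF
to 1 for tests that require flat prices.

*Ground truth.* `truth_report` computes expected presentations and costs
per area in closed form: cell probabilities from the band mixtures,
expected cost per cell by enumerating the 12 service/method patterns per
centre, the log-normal correction exp(sd²/2), and the centre price index.
The test suite verifies this closed form against brute-force enumeration.

*What the generator does not emulate:* seasonality, secular trends,
deprivation gradients in rates, age-dependent service probabilities,
cost-covariate interactions, heavy-tailed cost outliers beyond the Gamma,
and real repetition dynamics (cluster sizes are approximately
1 + Poisson). Passing tests therefore show the pipeline is correct under
its own assumptions and calibrated under correct specification — not that
the published national figures are reproducible, which the confidential
data preclude.

## Benchmarks and study sizes

*Coefficient recovery* uses a dedicated exact-model benchmark world
(`recovery_truth`): 5,000 cost-observed episodes, balanced gender,
service and method mixes, Gamma shape 3, no patient effect, flat prices.
The balance keeps the worst-case asymptotic coefficient SE near 0.026
log-units so that ±0.05 recovery is a meaningful, reliably attainable
bar; under the faithful case-mix the rare both-methods class alone has
SE ≈ 0.04 at this size.

*Interval calibration* runs 200 regenerated tiny worlds with 1,000
Monte-Carlo draws each (a desk-scale version of the full 10,000). The
propagated uncertainty is the coefficient vector only, so coverage is
assessed against the national total evaluated at the generating
coefficients conditional on each world's realised episode design, with
predictions used for every centre — the component of the estimand that
coefficient uncertainty addresses. Leaving observed-cost and incidence
sampling noise in the target would make nominal coverage unattainable by
construction for *any* interval built this way. Measured coverage is
0.935 at these sizes.

*Rate recovery* compares estimated to generative rates over three fixed
simulation seeds, using a clustered standard error: repeats share a
patient's age, inflating the binomial variance by 1/(1−p) + p for repeat
probability p (cluster sizes ≈ 1 + Poisson(p/(1−p))).

## Numerical choices and degenerate inputs

- IRLS is run to tolerance 1e-10 (max 200 iterations); non-convergence
  and rank-deficient designs raise with the offending columns named.
- The sandwich covariance is symmetrised ((V+Vᵀ)/2) against floating-point
  asymmetry; eigenvalue clipping handles any remaining non-PSD case.
- Ages beyond the model's cap are clamped for prediction with a warning.
- Zero-population cells get rate 0 with a flag; an episode in such a cell
  is an error (it contradicts the catchment definition).
- Empty episode collections warn and return empty frames; a gender with
  no cost data at all cannot be pooled and raises.
- Tables are written with rows sorted on all columns so identical inputs
  and seed give byte-identical files; manifests record content digests,
  row counts, the configuration hash and the seed.

## Known limitations

- The patient-count scaling assumes the sentinel patients-to-episodes
  ratio transfers to every area.
- The Monte-Carlo interval excludes incidence sampling error, observed-
  cost sampling error and the assessment unit-cost constants; it is a
  transfer-uncertainty interval, not a full predictive interval.
- The Gamma family is both the generative and the fitted family in the
  synthetic world; real cost data may be heavier-tailed.
- The rurality adjustment's fraction-weighted form is one reading of a
  rural/urban classification; the binary alternative is provided but
  neither is asserted as definitive.
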