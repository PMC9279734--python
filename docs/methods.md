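# Methods

## The problem

Papillary thyroid microcarcinoma (PTMC, papillary thyroid cancer ≤ 1 cm)
frequently harbours lymph-node micrometastases in the central neck
compartment, yet is managed as "low-risk" disease, increasingly with
active surveillance instead of surgery. When a central lymph-node
dissection examines only a few nodes, a pathologically node-negative
report can be a false negative: metastatic nodes were present but none of
them happened to be sampled. This package quantifies that *occult nodal
disease* risk as a function of the number of nodes examined (the LN
yield), derives how many nodes must be examined for the report to be
trusted, corrects the observed prevalence of nodal disease for the missed
cases, and then asks — on a registry-style survival cohort — whether an
inadequate yield (hence occult disease left in the body) actually costs
overall survival.

## The beta-binomial occult-disease model

For a truly node-positive patient, each examined node is positive with a
patient-specific probability `p`, assumed common to all of that patient's
nodes and drawn across patients from a Beta(α, β) law. Given `p`, the
count of positive nodes among `m` examined is Binomial(m, p); marginally
it is beta-binomial. The chance that a truly positive patient shows *no*
positive node in `m` examined is

    P0(m) = B(α, β + m) / B(α, β) = Π_{k=0}^{m-1} (β + k) / (α + β + k),

so `1 − P0(m)` is the detection probability. For an *observed*
node-negative patient, the probability of harbouring occult disease is the
Bayes posterior

    q(m) = π · P0(m) / (π · P0(m) + 1 − π),

where π is the true prevalence of nodal disease. `q(0) = π` exactly (no
information), `q` is strictly decreasing in `m`, and the *minimum adequate
yield* is the smallest `m` with `q(m)` at or below a stated risk threshold
(default 10%). At the package's reference parameters α = 2.50, β = 6.21,
π = 0.389 the sequence `q(1..7)` is 31.2%, 25.2%, 20.5%, 16.9%, 14.0%,
11.8%, 10.0% and the minimum adequate yield is 7 nodes.

Note that `1 − P0(m)` (the detection probability, exposed as
`detection_prob`) is *not* the occult-disease probability: at m = 1 it
gives 28.7%, while the posterior form gives the 31.2% that heads the
sequence above. Both quantities are available; `occult_probability`
implements the posterior form because that is the quantity an observed
node-negative patient cares about.

### Fitting

(α, β) are estimated by maximum likelihood from node-positive patients
with at least two nodes examined. Two likelihoods are implemented:

* **untruncated** (default in the CLI, mirroring the source lineage of the
  method): the plain beta-binomial likelihood on the node-positive subset;
* **zero-truncated** (`truncated=True`): each term divided by
  `1 − P0(m_i)`, conditioning on the patient having been detected at all.

The truncated likelihood is the generative-consistent one: on synthetic
cohorts drawn from the model it recovers (α, β) with < 2% relative error
at n = 200,000, whereas the untruncated fit on the same
condition-on-detection substrate is biased upward (roughly α ≈ 5.4,
β ≈ 10.6 at the reference world). Observed-negative patients cannot enter
either fit — a Beta(2.5, 6.2) law has zero mass at p = 0 and cannot
describe the ~60–70% of patients who are truly node-negative; prevalence
enters separately through the false-negative correction.

The optimiser runs BFGS on (log α, log β) from (0, 0) with the analytic
gradient (digamma differences), gradient tolerance 1e−8, and a 1e6 cap on
either parameter to detect the degenerate point-mass limit (all observed
positivity fractions equal), which is reported as an explicit failure.
All Beta-function ratios are computed as log-gamma differences; Beta
functions are never evaluated directly.

### False-negative correction and corrected prevalence

In the stratum of patients with yield `m`, the detected positives `#TP_m`
undercount the truly positive by the miss odds, so
`#FN_m = #TP_m · P0(m) / (1 − P0(m))` and

    corrected prevalence = Σ_m (#TP_m + #FN_m) / N,

with N the fixed total patient count (capped at 1 with a warning if the
FN estimates overflow). On model-consistent cohorts of 100,000 the
correction recovers the generative prevalence within ±0.01 while the
observed node-positive fraction sits several points lower.

### Uncertainty and fit diagnostics

Confidence intervals are percentile bootstrap: patients resampled with
replacement at the original cohort size, the statistic (including the
refitted α, β) recomputed per replicate, and the 2.5/97.5 percentiles
taken over 2,000 replicates by default. Replicates whose refit fails are
dropped and counted; more than 10% failures aborts. Goodness of fit is a
Pearson chi-square on observed-vs-expected counts of positive nodes within
each yield stratum, cells pooled left-to-right until the expected count
reaches 5 (a trailing remainder folds into the previous cell), with
degrees of freedom #cells − 1 − 2 fitted shapes.

## The survival verification pipeline

Eligibility filtering applies, in order: papillary ICD-O-3 histology
(8050/3, 8260/3, 8340/3, 8341/3, 8342/3, 8343/3), tumour ≤ 10 mm, M0, no
prior malignancy, exclusion of lateral-compartment nodal stage N1b (those
dissections are clinically indicated, not prophylactic), and at least one
node examined — with a per-rule exclusion tally for audit.

Observed node-negative patients are split at a seven-node cutoff into
adequate (≥ 7) and inadequate (1–6) groups; overall survival is compared
by Kaplan–Meier with the two-group log-rank test, overall and in the
≥ 55-year subgroup (boundary inclusive), with 5-/10-year rates read off
the curve at 60/120 months by right-continuous step evaluation (flagged
unavailable beyond the longest follow-up).

The multivariable check is a Cox proportional-hazards model (Efron tie
handling, via lifelines) in which the examined-node count enters through a
restricted cubic spline in Harrell's parameterisation — linear tails
outside the boundary knots, nonlinear columns normalised by
(t_k − t_1)² — with the knot count chosen by refitting the full model at
3, 4 and 5 knots placed at the fixed percentile tables (10/50/90,
5/35/65/95, 5/27.5/50/72.5/95) and minimising AIC = −2·logPL + 2·#params,
ties to fewer knots. Adjustment covariates: sex, age, race,
extrathyroidal extension, multifocality, surgery extent, radioiodine, and
positive-node count; age and positive-node count are specified as 3-knot
splines. The "overall association" of the examined-node count with
survival is a joint Wald chi-square on its spline coefficient block
(df = number of spline columns); a likelihood-ratio variant was considered
and not needed. The hazard-ratio curve exponentiates the spline contrast
against a reference value (the first knot by default, so HR = 1 there
exactly) with delta-method pointwise bands.

Complete cases only: rows missing any model field are dropped and counted.
When a spline covariate has too few distinct values for its percentile
knots to be distinct — in practice the positive-node count, which is 0 for
most registry patients — the covariate falls back to entering linearly,
with a warning. Knot placement requires at least as many distinct values
as knots; numpy's percentile interpolation would otherwise manufacture
formally distinct knots on two-valued data.

## The synthetic world

No patient-level data behind this class of analysis are publicly
deposited (single-centre pathology databases and registry extracts), so
both cohorts are simulated with the structure the analysis assumes.

**Nodal cohort defaults** state the reference world: n = 5,399 patients,
true prevalence 0.389, Beta(2.50, 6.21) positivity, and yields
`1 + NegBinom(r = 1.6, μ = 7.25)` — tuned once so the yield quartiles are
exactly 4/7/11, the median-7 (IQR 4–11) profile of a thorough
central-compartment dissection series. A uniform yield option exists for
clean oracle tests, and an empirical-table option for arbitrary laws. The
simulated true status travels in a hidden `_true_positive` column that
model-facing readers drop.

**Survival cohort defaults**: n = 15,340; exponential event times with
baseline hazard 2.5e−4/month (5-year survival ≈ 98.5%, the survival regime
of low-risk PTMC; a Weibull shape is exposed for non-constant hazards);
proportional-hazards covariate effects supplied as a map from named
covariates to log-hazard ratios (age per decade centred at 50, male sex,
extrathyroidal extension, …); administrative censoring uniform on
[0, 132] months emulating staggered accrual under a fixed database cutoff
(median follow-up ≈ 65 months, IQR ≈ 33–99), plus optional random
exponential censoring; covariate mixes (80% female, mostly-white race mix,
60% total thyroidectomy, 45% radioiodine, 4% extrathyroidal extension, 30%
multifocality) chosen once as registry-plausible for this disease. An
`inject_ineligible_fraction` flag plants N1b / M1 / oversized-tumour /
prior-malignancy records to exercise the filter's audit tally.

What a green test does *not* establish: the generator draws covariates
independently (no age–sex–stage correlation), uses exponential baseline
hazards, ignores competing risks and recurrence, and draws survival
independent of the nodal submodel unless an effect is configured — so the
survival stage is validated on closed-form and null-calibration
properties, not on reproducing any registry's published survival figures,
which require the registry itself.

## Numerical and design choices

* Beta ratios via log-gamma; P0(0) short-circuited to exactly 1 so the
  occult probability at m = 0 is the prior exactly.
* Percentile (not BCa) bootstrap; patient-level (not node-level)
  resampling; seeds recorded in every output.
* Risk profiles default to m_max = 30, the validated yield range.
* The occult-probability prevalence defaults to the cohort's corrected
  prevalence (a single pass — the FN correction does not depend on π, so
  no iteration is needed).
* The CLI derives per-stage substreams from the global seed via
  SeedSequence with a CRC32 stage tag, so stages re-run independently and
  reproducibly.
* Goodness-of-fit cells always use the zero-truncated pmf when the
  substrate conditions on detection (x ≥ 1), whichever likelihood was
  maximised: the test must compare the data against the law the data were
  observed under.

## Known limitations

* The equal-probability-per-node assumption is biologically coarse; the
  model has no node-location structure by design.
* The untruncated fit is retained for method fidelity but is not
  generative-consistent; users who want parameter recovery should pass
  `truncated=True`.
* The Wald block test relies on large-sample normality; at very low event
  counts the likelihood-ratio flag is the safer variant.
* Lateral-compartment (N1b) disease, recurrence outcomes and
  cause-specific survival are out of scope.
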