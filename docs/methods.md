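# Methods

## The model and its assumptions

The outcome is the monthly opioid-related death rate y_t = 100000·d_t/p_t
for a Census Region (optionally a region × gender stratum). Deaths d_t are
counts of certificates whose underlying cause lies in the drug-poisoning
ICD-10 ranges X40–44, X60–64, X85 or Y10–14 and that carry at least one
contributing cause among T40.0–T40.4 or T40.6; a certificate with several
qualifying T codes counts once. The rate is modelled by ordinary least
squares on a segmented (piecewise-linear) design: a global intercept and
monthly slope plus, for each timeline event, an indicator column (level
shift) where the event has an immediate effect and a months-elapsed column
(slope change) where it has a sustained effect. Months are indexed from
January 1999 = 1, and P_t(E) = max(0, t − (index(E) − 1)) so the elapsed
time is 1 in the event month itself. The PHE and CHW events enter with
sustained terms only — they fall late in their calendar months, so a level
shift within the same month is not identifiable at monthly granularity.

OLS inference assumes linearity within segments, independent observations,
and normal homoskedastic errors. Monthly rate data violate the last two
mildly: count noise gives variance proportional to the rate, and adjacent
months are weakly dependent. The default standard errors are classical,
matching standard linear-model output; `fit_ols(..., robust=True)` switches
to HC3 heteroskedasticity-robust errors, which our simulations show are
needed for per-coefficient interval calibration under Poisson count noise
(see "Calibration" below). No autocorrelation correction is applied.

The no-pandemic counterfactual zeroes the COVID indicator, COVID elapsed
and CHW elapsed columns of the design before prediction (the projection
guard rejects any design whose pandemic columns are not exactly zero).
Excess rate, excess deaths and cumulative excess follow by subtraction,
population scaling (s_t = r_t·p_t/100000) and a running sum from month 255
(March 2020). All excess quantities are kept real-valued internally and
rounded only for reporting, avoiding accumulation bias in c_t.

## Population handling

Annual population estimates are anchored at July 1 and interpolated
linearly in elapsed calendar days to the month-end dates carrying the death
counts (a July-to-July span is 365 or 366 days as the calendar dictates).
Dates before the first anchor backfill its value; dates after the last
anchor carry it forward. A month-uniform interpolation mode
(`method="month"`) exists for sensitivity checks; day-based interpolation
is the default because it is the natural semantics of time interpolation on
a datetime index.

## Bootstrap

Confidence intervals for cumulative excess deaths use a Poisson parametric
bootstrap, run separately per region: resample d*_t ~ Poisson(d_t) at every
timepoint (pre-pandemic months included), recompute rates with the fixed
interpolated populations, refit the ITS model, re-project the
counterfactual from the resampled fit, and accumulate excess deaths. The
2.5 and 97.5 empirical percentiles of the B replicate trajectories give the
95% band per month; national bands sum the replicate trajectories across
regions replicate-by-replicate before taking quantiles, preserving the
independence of regional streams. The national point estimate is the sum
of regional point estimates.

Because the design matrix is fixed across replicates, the refit is
implemented as one precomputed pseudoinverse applied to the matrix of all
replicate responses. This is algebraically identical to per-replicate OLS
(verified against the statsmodels path to machine precision in the tests)
and makes B = 1000 essentially free. B defaults to 1000; quantiles default
to the linear-interpolation estimator, configurable (e.g. `inverted_cdf`)
since no single empirical-quantile definition is canonical. Seeds are
mandatory everywhere; the pipeline derives independent per-region
substreams from the run seed via `numpy.random.SeedSequence.spawn`.

The gender-stratified variant resamples counts at the gender-stratum
level, fits the fully interacted model to the stacked strata, and sums the
per-gender excess deaths within each month before cumulating.

## Synthetic data generator

The generator inverts the analysis model: per-stratum coefficient vectors
define expected rates μ_t through the same design construction the fit
uses, expected counts are μ_t·p_t/100000, and observed counts are Poisson
draws with that mean (options: exact noise-free counts, or Gaussian rate
noise with configurable sd and AR(1) coefficient to probe the independence
assumption). Configurations implying μ_t < 0 anywhere in the requested
range are rejected with the offending month named.

The default scenario uses the five-event timeline above with regional
coefficient vectors of realistic magnitude — intercepts 0.11–0.30 deaths
per 100,000, fentanyl-era slope changes around +0.01 per month, immediate
pandemic level shifts 0.31–0.54 — and per-gender scaling (Female 0.6×,
Male 1.4×) reflecting the persistent male excess in opioid mortality.
July-1 population anchors are region-scale (28–57 million per gender
stratum) with ~0.8%/yr linear growth. These values are the package's fixed
study conditions, not tuning knobs.

Record-level certificates are expanded from the counts with a draw mix
over qualifying underlying causes and narcotic T codes; contaminant records
(wrong underlying cause, or no qualifying T code) are added at a requested
fraction f of all records — their number is the deterministic
round(total·f/(1−f)), with only placement and codes randomised — and are
flagged so filter tests can verify exact recovery. WONDER-dialect fixture
files render counts below the suppression threshold as the literal
"Suppressed" token and end with a "---"-prefixed Notes block, matching the
parser surface of real exports. The fixture writer partitions rows into a
final/provisional pair at a split month; real extracts overlap in time, but
the merge rule (final authoritative up to the cutoff) makes the partition
equivalent for testing.

What the generator does not emulate: geographic or demographic
microstructure below region × gender, reporting delays beyond the
final/provisional split, seasonality, and the curvilinear within-segment
patterns visible in some regions' real data. Passing parameter-recovery
tests therefore demonstrates correctness of the estimator under the model's
own assumptions, not robustness to real-data misspecification.

## Calibration and numerical choices

- Parameter recovery: over 500 Poisson-count replicates at population 10⁷
  per stratum, mean coefficient estimates match the truth within
  Monte-Carlo error (OLS is unbiased under mean-correct noise).
- Interval calibration: classical homoskedastic 95% CIs are exact under
  Gaussian noise (tested) but miscalibrated per coefficient under Poisson
  noise, whose variance tracks μ_t (measured coverage 0.77–1.00 across
  coefficients: over-coverage where the rate is low, under-coverage in the
  high-rate pandemic segment). HC3 robust intervals restore nominal
  per-coefficient coverage; HC1 still under-covers slightly in the short
  high-leverage post-intervention segments, which is why HC3 is the robust
  default.
- Bootstrap calibration: the 95% interval for final-month cumulative excess
  covers an injected pandemic effect at the nominal rate (binomial
  tolerance) over 200 independent datasets at B = 200, and a null-effect
  scenario yields intervals straddling zero.
- Degenerate inputs fail loudly: rank-deficient designs name a collinear
  column, suppressed cells poison gender aggregation unless explicitly
  zero-filled, counterfactual designs with live pandemic columns are
  rejected, and merges that would duplicate a stratum-month raise.
- Problem sizes in the test suite and acceptance script (500 fit
  replicates; 200 outer datasets × B = 200; B = 500–1000 for demo runs)
  keep every run to seconds thanks to the vectorised refit while leaving
  Monte-Carlo tolerances comfortably resolvable.

## Known limitations

Timeline dates are fixed a priori (no changepoint estimation); inference
ignores residual autocorrelation; the excess-rate band treats the observed
rate as fixed and shifts the counterfactual prediction interval; attribution
percentages depend on externally published all-cause and non-COVID excess
death totals taken as inputs. Real CDC WONDER extracts must be obtained
interactively; the package reads them but ships none.
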