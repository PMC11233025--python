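# opioid-its

Interrupted time series (ITS) analysis of monthly opioid-related death
rates in the United States, with counterfactual estimation of the excess
opioid deaths associated with the COVID-19 pandemic.

The package is aimed at epidemiologists and biostatisticians studying the
opioid epidemic with CDC WONDER Multiple Cause of Death (MCOD) exports. It
covers the full workflow: parsing WONDER-dialect extracts and merging final
with provisional data, ICD-10 filtering of opioid-related deaths,
population interpolation and rate conversion, segmented regression around a
configurable intervention timeline, no-pandemic counterfactual projection,
excess-death accounting, and Poisson parametric bootstrap confidence
intervals. A synthetic-data generator with known truth makes every stage
testable without access to CDC WONDER.

## Model

Monthly opioid-related death rates per Census Region (y_t, deaths per
100,000, with y_t = 100000·d_t/p_t from counts d_t and interpolated July-1
population anchors p_t) follow a multi-intervention segmented regression:

```
y_t = β0 + β1·t + β2·I_t(Heroin)   + β3·P_t(Heroin)
            + β4·I_t(Fentanyl)     + β5·P_t(Fentanyl)
            + β6·P_t(PHE)
            + β7·I_t(COVID)        + β8·P_t(COVID)
            + β9·P_t(CHW)          + ε_t
```

where t counts months since January 1999 (= month 1), I_t(E) = 1{t ≥
index(E)} is the indicator of event E and P_t(E) = max(0, t − (index(E) −
1)) the months elapsed since it. Immediate effects (β2, β4, β7) are level
shifts; sustained effects (β3, β5, β6, β8, β9) are slope changes. The five
default events are the heroin wave (Jan 2010, month 133), the fentanyl wave
(Jan 2013, month 169), the opioid public-health-emergency declaration (Oct
2017, month 226), the COVID-19 national emergency (Mar 2020, month 255) and
the CDC community-health-worker funding announcement (Mar 2021, month 267).
A fully interacted variant stratifies every term by gender (Female
baseline, Male deviations).

The no-pandemic counterfactual ỹ_t zeroes the COVID and CHW terms. Excess
rate r_t = y_t − ỹ_t converts to excess deaths s_t = r_t·p_t/100000 and
cumulative excess c_t = Σ_{i≥255} s_i. Confidence intervals come from a
parametric bootstrap that resamples d*_t ~ Poisson(d_t) at every month,
refits, re-projects, and takes empirical 2.5/97.5 quantiles of c*_t;
regional replicate trajectories are summed replicate-by-replicate for the
national interval.

## Worked example

```python
from opioid_its import pipeline

sim = pipeline.simulate_stage("scratch/demo_sim", seed=42)   # synthetic WONDER inputs
cfg = pipeline.RunConfig(
    final_counts=sim["final"], provisional_counts=sim["provisional"],
    population=sim["population"], out_dir="scratch/demo_run",
    seed=7, bootstrap_B=1000, make_figures=False)
results = pipeline.run_pipeline(cfg)

south = results["fits"]["South"]
print("South immediate COVID effect:",
      round(south.params["Indicator_COVID"], 3),
      "p =", f"{south.pvalues['Indicator_COVID']:.2e}")
ci = results["national"].ci().iloc[-1]
print("national cumulative excess (Mar 2020 - Oct 2022):",
      f"{ci['point']:,.0f}  (95% bsCI {ci['lower']:,.0f}-{ci['upper']:,.0f})")
```

prints

```
South immediate COVID effect: 0.508 p = 5.34e-93
national cumulative excess (Mar 2020 - Oct 2022): 70,467  (95% bsCI 67,835-72,973)
```

The simulated truth injects an immediate pandemic level shift of ~0.52
deaths per 100,000 in the South (0.5231 at the gender-aggregated scale),
recovered here as 0.508; the national cumulative excess implied by the
generator's coefficients is ≈68,200 deaths, inside the bootstrap interval.
The same analysis runs on real CDC WONDER final/provisional extracts and an
annual population CSV by pointing `RunConfig` at those files.

A CLI mirrors the stages: `opioid-its simulate | ingest | fit |
counterfactual | bootstrap | report | run-all` (see `opioid-its --help`).

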