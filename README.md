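# deplife

**Deprivation-specific life tables from survey-weighted mortality microdata.**

Area-level deprivation indices (such as the European Deprivation Index,
scored per small census geography) make it possible to measure the social
gradient in all-cause mortality even where death records carry no
individual socioeconomic information. `deplife` implements the full
estimation chain for building period life tables stratified by national
deprivation quintile from census-linked longitudinal microdata:

1. **Quintile construction** — areas are ranked by deprivation score and cut
   at population-weighted breakpoints so each quintile holds ≈20% of the
   national population.
2. **Cohort preparation** — each person's most recent census form within a
   rolling window supplies their area; survey-weighted deaths *d_x* and
   exposures *e_x* are pooled over follow-up years by single year of age
   (18–100), sex and quintile.
3. **P-spline smoothing** — deaths are modelled as
   *d_x ~ Poisson(e_x μ_x)* with log *μ_x = B(x)a*, a cubic B-spline basis
   (21 equally spaced segments) and a second-order difference penalty
   *λ‖D₂a‖²* on the coefficients; *λ* minimises
   BIC = deviance + log(n)·ED, with ED the trace of the hat matrix.
4. **Calibration** — a scalar per-sex coefficient (nationally expected over
   sample-observed deaths) shifts the smoothed rates to a national
   reference table.
5. **Life tables** — quotients *q_x = 1 − exp(−m_x)* (open terminal age with
   *e_ω = 1/m_ω*) give the classical *l_x, d_x, L_x, T_x, e_x* columns and
   life-expectancy gaps between quintiles.
6. **Inequality metrics** — age-specific mortality rate ratios
   MRR(x) = exp{B(x)(a_q − a_ref)} versus the least-deprived quintile, with
   delta-method 95% CIs from the two independent penalized-information
   covariances.

Because the real census-linked samples behind such studies are
confidential, the package ships a first-class synthetic cohort generator
(Gompertz–Makeham hazards per sex, proportional quintile effects, rolling
census forms, mean-1 survey weights) with exact ground-truth accessors, so
every stage is testable against known truth.

## Worked example

```python
import deplife as dl

cfg = dl.SimulationConfig(n_individuals=100_000, seed=1)
areas = dl.simulate_areas(500, seed=2)
records = dl.attach_quintiles(dl.simulate_microdata(cfg, areas),
                              dl.assign_quintiles(areas))
counts = dl.aggregate_counts(records)

basis = dl.build_basis()
fit = dl.select_lambda(dl.counts_slice(counts, "male", 5), basis)
print(fit.lam, fit.effective_dimension)
```

prints `5623.41 3.08`: BIC chose a heavy penalty, judging the most deprived
males' log-rate nearly linear in age (effective dimension ≈ 3 of 24
coefficients) — the Gompertz pattern the cohort was generated from. The
smoothed rates rise from 0.00049/year at age 18 to 0.309/year at age 88,
and the fitted deaths sum exactly to the observed 2504.96 (the penalized
score equations conserve the death count). Continuing,

```python
result = dl.run_pipeline(dl.PipelineConfig(simulation=cfg))
print(result.le_gaps.query("sex == 'male' and quintile == 5"))
```

reports a life-expectancy gap between the extreme quintiles of 7.75 years
at age 30 and 5.45 years at age 60 for males — the simulated HR-2 gradient
compressed with age, the same qualitative shape seen in real
deprivation-specific tables. `examples/` contains five short scripts, one
per capability (simulation, smoothing, life tables, MRR curves, full
pipeline), each printing and explaining its output.

A thin CLI mirrors the stages for shell use:

```bash
deplife simulate --out-dir data --seed 1
deplife aggregate --microdata data/microdata.csv --areas data/areas.csv --out counts.csv
deplife fit --counts counts.csv --sex male --quintile 5 --out rates.csv
deplife lifetable --rates rates.csv --out lt.csv
deplife run --config config.yaml --out-dir results
```

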