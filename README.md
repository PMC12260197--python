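# extrapsim

A simulation framework for asking a question that matters in health
technology assessment: **when a trial is small or immature, how badly do the
two standard survival-extrapolation decision models get lifetime survival
wrong?**

Oncology cost-effectiveness models must extrapolate progression-free (PF)
and overall survival (OS) far beyond trial follow-up. Two model structures
dominate practice:

* **Partitioned survival models (PSM)** fit independent parametric curves to
  PFS and OS and read state occupancy directly off them
  (PF = S_PFS(t), PD = S_OS(t) − S_PFS(t), corrected so PFS ≤ OS);
* **Multistate models (MSM)** fit cause-specific transition hazards
  (PF→PD, PF→death, PD→death) under semi-Markov clocks and estimate sojourn
  times by first-event-wins discrete event simulation.

Either can incorporate general-population mortality (GPM) through an
*internal additive hazards* (relative survival) likelihood, where the total
death hazard is h(t) = h\*(t) + λ(t): a fixed background mortality law
h\*(t) from a life table plus a parametric excess hazard λ(t) fitted to the
data, so S(t) = S\*(t)·R(t).

`extrapsim` implements the whole experiment end to end:

1. **Data generation** — complete event histories for 50,000-individual
   populations under four scenario parameterisations (constant, increasing,
   decreasing Weibull progression/excess-death hazards), with uniform
   staggered enrollment over 1.5 y, baseline ages ~ Normal(60, 6) and
   background mortality from a Kannisto–Makeham law fitted to a (shipped,
   synthetic) historical life table.
2. **Trial sampling** — 1,000 replications of 1,050 subjects split into
   cohorts of n ∈ {30, 60, 90, 120, 250, 500}, each administratively
   censored at the calendar time when 30%…100% of subjects have had a PFS
   event (the event-count data cutoffs trials actually use).
3. **Estimation** — maximum-likelihood fits of six parametric families
   (exponential, Weibull, log-normal, log-logistic, generalized gamma,
   Gompertz), naively or as excess hazards against a Gompertz analysis-side
   law from age 60; lowest-AICc selection; multivariate-normal parameter
   draws for 1,000-iteration probabilistic analysis.
4. **Decision models** — four estimators per dataset: naive PSM, PSM with
   GPM, MSM with GPM (5-transition matrix, with a documented 4-transition
   fallback), and a partly naive MSM.
5. **Evaluation** — restricted-mean estimands from the complete population
   (Kaplan–Meier area up to the 1%-survival horizon) and per-grouping MAPE,
   MAE, bias, CI coverage and failure proportions, plus summary figures.

## Worked example

```python
import extrapsim as ex
from extrapsim.study import analyze_dataset

# a complete scenario-1 population and its true estimands
law = ex.fixture_law("generation")
pop = ex.simulate_population(ex.make_scenario(1), law, n=50_000, seed=1)
truth = ex.compute_estimands(pop)
print(f"truth: PF={truth.pf:.2f}  PD={truth.pd:.2f}  OS={truth.os:.2f}  "
      f"horizon={truth.horizon:.0f}")

# one simulated trial: n=120, censored when 50% have had a PFS event
design = ex.StudyDesign(nsim=1, nobs=(120,), pe=(0.5,), seed=7)
cohort = ex.draw_replication(pop, design, 0)[0]
dataset = ex.censor_at_event_fraction(cohort, 0.5)

for e in analyze_dataset(dataset, ("psm_naive", "psm_gpm", "msm_gpm"),
                         ex.fixture_law("analysis"), truth.horizon,
                         n_psa=200, n_des=2000, seed=42):
    print(f"{e.method:10s} OS={e.os:.2f}y "
          f"(95% CI {e.ci['OS'][0]:.2f}-{e.ci['OS'][1]:.2f})")
```

prints

```
truth: PF=1.93  PD=4.33  OS=6.27  horizon=22
psm_naive  OS=4.72y (95% CI 2.44-7.97)
psm_gpm    OS=4.68y (95% CI 2.05-7.90)
msm_gpm    OS=5.56y (95% CI 3.22-8.59)
```

With only half the PFS events observed (1.9 years of follow-up), every
model underestimates the 6.27 true mean life-years; the multistate model
comes closest here, which is the pattern the full simulation quantifies
systematically.

Full or scaled-down studies run from the command line:

```bash
extrapsim run-study --scenario 1 --nsim 5 --nobs 30,120 --pe 0.3,1.0 \
    --n-psa 50 --n-des 1000 --seed 1 --out results/smoke
extrapsim make-figures --performance results/smoke/performance_1.csv --out results/smoke
```

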