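# longlme

Frequentist and Bayesian linear mixed-effects modelling of longitudinal
biomarker trajectories, with sequential data-removal simulations that map
how much data a longitudinal group comparison can lose before it breaks.

## The problem

Longitudinal neuroimaging studies — the motivating case is hippocampal
volume (HV) measured over ~2 years in five clinical groups spanning the
Alzheimer's continuum (stable and converting healthy controls, stable and
converting MCI, AD) — are analysed with linear mixed-effects (LME) models:

    y_ij = x_ij'β + b0_i + b1_i·t_ij + ε_ij,   (b0,b1) ~ N(0, G),  ε ~ N(0, σ²)

where the fixed effects include time, clinical group, group×time
(the atrophy-rate differences of interest), baseline age, sex, APOE-ε4
carrier status and its interaction with time, and intracranial volume.
Two questions dominate study design: *how many subjects* are needed to
keep a group contrast significant, and *how much missingness* the model
tolerates.  The frequentist fit (REML, Wald F-tests with Satterthwaite
degrees of freedom) fails outright once a dataset has fewer observations
than random-effect coefficients (n_obs ≤ 2N for a random-intercept-and-
slope model); the Bayesian fit (Gibbs sampling, credible-interval
inference) remains estimable there.  `longlme` implements both engines on
one model definition, plus the random-removal machinery that degrades a
cohort subject-by-subject or visit-by-visit until significance or
estimability is lost, harvesting the "borderline significant" datasets
where the two frameworks can be compared head to head.

It ships a synthetic-cohort generator whose defaults emulate a balanced
four-visit, 670-subject ADNI-like study (group-specific atrophy rates
of 0/−0.03/−0.02/−0.08/−0.11 sd/year relative to stable controls), so the
entire pipeline is testable without access-controlled data.

## Worked example

```python
from longlme import FrequentistLME, BayesianLME, GenerativeConfig, generate_cohort
from longlme.flme_inference import battery_frame

cohort = generate_cohort(GenerativeConfig(), seed=1)   # 670 subjects, 2680 visits
freq = FrequentistLME().fit(cohort)
print(f"cMCI x time: {freq.result_.coef('group[cMCI]:time'):+.3f} "
      f"(SE {freq.result_.se('group[cMCI]:time'):.3f}), AIC {freq.aic_:.1f}")
print(battery_frame(freq.contrast_battery())[["contrast", "F", "p_bonferroni"]].head(3))

bayes = BayesianLME(n_chains=4, n_iter=2000, n_warmup=1000, random_state=1).fit(cohort)
lo, med, hi = bayes.cri_["group[cMCI]:time"]
print(f"cMCI x time 95% CrI: [{lo:+.3f}, {hi:+.3f}], median {med:+.3f}")
```

Output:

```
cMCI x time: -0.065 (SE 0.012), AIC 988.5
       contrast          F  p_bonferroni
0  sMCI_vs_cMCI  10.168179  1.046203e-02
1    all_groups  12.297431  8.291173e-09
2    AD_vs_cMCI   5.780735  1.153568e-01
cMCI x time 95% CrI: [-0.091, -0.039], median -0.065
```

The converting-MCI group loses an extra 0.065 sd of hippocampal volume
per year relative to stable controls (generating value −0.08); the
frequentist F-tests and the Bayesian credible interval agree that the
cMCI and omnibus contrasts are significant while AD-vs-cMCI is not, and
the posterior median reproduces the REML estimate under weak priors.

The removal simulations run from the same objects:

```python
from longlme import run_many
summary, borderline = run_many("min_n", cohort, "all_groups",
                               n_iterations=50, base_seed=1)
print(summary.final_n_mean, summary.final_n_sd)   # minimum N, mean ± sd
```

A CLI mirrors the library (`longlme simulate | fit | bfit | test |
simulate-removal | eval-borderline | run`); `longlme run --config cfg.yaml
--out results/` executes the whole chain and writes a seed manifest that
makes the run byte-reproducible.

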