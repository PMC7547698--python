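# mifmodel

Computational modelling of effort-based motivated performance in a
monetary incentive force (MIF) task — for researchers in motivation,
neuroeconomics and behavioural modelling who want a tested, fully
reproducible implementation of the utility / effort-cost / stamina
model, its fitting machinery, and the cohort-level analyses built
around it.

## The model

In the MIF task a participant squeezes a hand grip to 50% of their
maximal voluntary contraction to win a trial-specific reward
x ∈ {0.2, 0.5, 1} CHF, over 80 trials in 2 blocks × 2 sessions × 20
trials with a rest break between blocks. Trial success is modelled per
subject with five parameters:

    u(x)       = x^α − τ                    subjective utility
    τ          = b + 2(1 − E)               effort cost
    P(success) = 1 / (1 + e^{−uβ})          performance function

with session energies E = (1, ε_spr, ε_end, ε_spr·ε_end): utility
curvature α, effort-cost baseline b, inverse temperature β, sprint
stamina ε_spr (fatigue within a block) and endurance stamina ε_end
(recovery over the break). The 12 success rates over 3 incentives × 4
sessions are the performance measures (PMs); parameters are estimated
per subject by minimising

    χ² = Σᵢ (PMᵢ^obs − PMᵢ^mod)² / σᵢ²,  df = 12 − 5 = 7,

with a seeded stochastic search (broad sampling + covariance-adaptive
refinement + deterministic polish). The package also provides: a
single-stamina reduced model (ε_end = ε_spr²) and fixed-parameter
variants with paired-t model comparison; a parameter-recovery
experiment; a synthetic cohort generator (27 subjects, 15 isolation /
12 competition, metabolite panel with Gln/Glu couplings, effort
perception, trial data); and the statistical battery (correlation
screen, normality-gated group tests, rank regression, interaction
ANOVA, PM PCA).

## Worked example

Fit one subject whose 12 PMs are exact model predictions:

```python
import numpy as np
from mifmodel import (ModelParameters, predict_performance, cohort_variances,
                      stochastic_search, SearchConfig, chi2_critical,
                      generate_cohort, CohortConfig)

subject = ModelParameters(alpha=0.5, beta=16.1, b=0.36,
                          eps_spr=0.9, eps_end=0.95)
pm = predict_performance(subject)
print(np.round(pm.values, 3))

cohort = generate_cohort(CohortConfig(seed=0))          # for PM variances
sigma2 = cohort_variances([p.pms for p in cohort])
fit = stochastic_search(pm, sigma2, SearchConfig(seed=3))
print(f"chi2 = {fit.chi2:.2e} (df {fit.df}, p_fit {fit.p_fit:.2f}; "
      f"critical value {chi2_critical(7, 0.05):.2f})")
print("recovered:", {k: round(getattr(fit.params, k), 3)
                     for k in ("alpha", "beta", "b", "eps_spr", "eps_end")})
```

prints

```
[[0.803 0.14  0.449 0.037]
 [0.996 0.914 0.982 0.715]
 [1.    0.999 1.    0.996]]
chi2 = 6.28e-24 (df 7, p_fit 1.00; critical value 14.07)
recovered: {'alpha': 0.5, 'beta': 16.1, 'b': 0.36, 'eps_spr': 0.9, 'eps_end': 0.95}
```

The PM grid (rows: incentives 0.2/0.5/1 CHF; columns: sessions 1–4)
shows the model's signature structure — success rises with incentive
and falls with fatigue, recovering partially after the between-block
break (column 3). The search drives the weighted residual χ²
essentially to zero, far below the df-7 critical value 14.07, and
returns the generating parameters exactly.

The full pipeline (cohort simulation → fitting → model comparison →
recovery → statistics) runs from the command line:

```bash
mifmodel run-all --outdir out --seed 1
```

writing `participants.csv`, `trials.csv`, `pms.csv`, `fits.csv`,
`comparison.csv`, `recovery.csv`, `stats.csv`, `pca.csv` plus the
echoed configuration; identical seed and configuration reproduce every
file byte-for-byte. See `docs/methods.md` for the model assumptions,
search design, generator couplings and known limitations.

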