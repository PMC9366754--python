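# elkrsf

Resource selection of elk on landscapes of forage quality and
two-predator risk — and whether individual risk-avoidance costs body
fat or pregnancy.

Elk summering among mountain lions (ambush hunters) and wolves
(coursers) face a classic trade-off: the best forage may be the
riskiest place to eat.  This package implements, as a tested pipeline,
the analysis needed to measure that trade-off from GPS telemetry and
ask whether it has demographic consequences:

1. **Home ranges** — 99% fixed-kernel isopleths from one location per
   animal per day (Gaussian kernel, reference bandwidth).
2. **Used–available designs** — second order (500 points per individual
   range vs 1000 in the population range) and third order (summer
   foraging fixes vs 10 available points each within the range), with
   available points weighted 1000.
3. **Hierarchical Bayesian RSF** — the exponential-form model
   `w(x) = exp(g0_i + gDE_i DE + gML_i ML + gWF_i WF + gDExML_i DE·ML +
   gDExWF_i DE·WF)` with per-individual random intercepts and slopes
   centred on population coefficients (`gcov_i ~ Normal(bcov,
   sigma_cov)`, `sigma_cov ~ Uniform(0, 2)`, `bcov ~ Normal(0, 2)`),
   estimated by a marginal-Laplace fitter with Laplace, ensemble-MCMC
   and fast MAP modes.
4. **Validation** — fivefold by-individual cross-validation with
   percentile-binned habitat ranks and a Spearman test.
5. **Trade-off metric** — per individual, the difference in relative
   use of high-quality forage (95th DE percentile) between high (95th)
   and low (5th percentile) predator risk; negative = risk-averse.
6. **Nonconsumptive-effect models** — Bayesian regressions of % body
   fat (Gaussian) and pregnancy (logistic) on the trade-off, lactation
   and their interaction.
7. **Synthetic data** — landscapes with calibrated predator–forage
   correlations (lion–DE R² = 0.35, wolf–DE 0.15), heterogeneous
   individuals, schedule-realistic telemetry and demography, so every
   stage is verifiable without field data.

Intended users: movement ecologists and quantitative wildlife biologists
who want a transparent, scriptable alternative to stitching this
workflow together by hand.

## Worked example

```python
import numpy as np
from elkrsf import (RSFModelSpec, fit_hierarchical_rsf)
from elkrsf.synthetic import simulate_used_available

# a used–available table drawn from the model itself:
# 40 elk, 300 used fixes each, 10:1 availability, truth
# bDE=0.2, bML=-0.1, bWF=0.3, bDExML=-0.1, sigma=0.15
table, gamma = simulate_used_available(n_individuals=40, n_used=300, seed=3)
post = fit_hierarchical_rsf(table, RSFModelSpec(), method="laplace",
                            draws=200, seed=3)
print(post.summary().round(3))
```

prints (seed 3):

```
                 mean   lo90   hi90   rhat      ess
beta_intercept -0.150 -3.141  2.835  1.007  235.773
beta_de         0.193  0.151  0.234  1.010  186.217
beta_ml        -0.091 -0.134 -0.048  1.021  200.706
beta_wf         0.292  0.250  0.335  1.004  283.633
beta_de:ml     -0.070 -0.110 -0.030  1.002  184.976
beta_de:wf     -0.026 -0.062  0.009  1.008  177.091
sigma_de        0.165  0.131  0.200  0.997  184.619
sigma_ml        0.155  0.127  0.190  1.004  183.908
sigma_wf        0.147  0.119  0.179  1.005  170.104
sigma_de:ml     0.153  0.124  0.181  0.989  190.939
sigma_de:wf     0.141  0.113  0.174  1.013  151.347
```

Every population coefficient's 90% credible interval covers its
generating value; the negative `beta_de:ml` is the forage-by-lion
trade-off (selection for digestible energy weakens under lion risk);
the `sigma_*` rows recover the simulated among-individual heterogeneity
(truth 0.15).  The wide intercept is expected: under the 1000-weighted
design it is dominated by its deliberately vague Normal(b0, 100)
random-intercept structure and carries no selection information.

## The analysis, step by step

Numbered drivers under `analysis/` run the whole study on synthetic
data and write tables under `results/`:

```bash
python analysis/01_simulate.py        # landscapes + telemetry + truth
python analysis/02_home_ranges.py     # 99% kernel isopleths
python analysis/03_design_tables.py   # second-/third-order tables
python analysis/04_fit_rsf.py         # hierarchical RSFs, both orders
python analysis/05_validate.py        # fivefold Boyce-style CV
python analysis/06_tradeoff_nce.py    # trade-offs + body fat/pregnancy
```

The same stages are available as a CLI (`elkrsf run --seed 1 --outdir
runs/demo`, with `simulate | homerange | design | fit | validate |
tradeoff | nce` subcommands, `--fast` for MAP mode, and `--set
key=value` config overrides) or programmatically via
`elkrsf.run_pipeline`.

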