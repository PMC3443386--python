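# jointlsm — joint modelling of longitudinal and time-to-event data

`jointlsm` implements shared random effects joint models for a continuous
longitudinal marker and a (right-censored) failure time, together with the
two quick approximations practitioners often reach for first — a naive
proportional-hazards model with the observed marker as a time-dependent
covariate, and a two-stage model that plugs mixed-model fitted values into
a survival fit.  It is built around the setting that motivates such
models in screening programmes: abdominal aortic aneurysm (AAA) diameters
measured at surveillance visits, with the hazard of rupture driven by the
current underlying (measurement-error-free) diameter.

The package is for biostatisticians who want to (a) fit the joint model by
classical maximum likelihood or Bayesian MCMC, (b) predict an individual's
future marker values and conditional event risk from their measurement
history, and (c) quantify, by replicated simulation, how badly the
approximate methods understate the marker-hazard association (regression
dilution) and misstate the baseline hazard.

## The model

For subject *i* with measurements *y<sub>ij</sub>* at times
*t<sub>ij</sub>*:

```
y_ij  = m_i(t_ij) + e_ij,          e_ij ~ N(0, sigma^2)
m_i(t) = beta11 + beta12 t + U_1i + U_2i t,   (U_1i, U_2i) ~ N_2(0, Sigma)
h_i(t) = lambda * exp( alpha1 U_1i + alpha2 U_2i + alpha3 (m_i(t) - c) )
```

The same random intercept and slope drive both the growth trajectory and,
through the association parameters `alpha1/alpha2/alpha3`, the hazard.
`c` is a fixed centering constant (47.15 mm by default, the population
mean over a 10-year follow-up) so that `lambda` is the hazard for a
subject whose underlying value equals `c`.  Because the log-hazard is
linear in *t* given the random effects, the integrated hazard has the
closed form `H(t) = lambda e^a (e^{bt} - 1)/b` used by every fitter and
by the posterior-predictive machinery.

Fitters:

* `JointModel(...).fit()` — maximum likelihood with mode-centered,
  curvature-scaled (adaptive) Gauss–Hermite quadrature over the random
  effects; Wald SEs from the finite-difference Hessian.
* `BayesianJointModel(...).run()` — Metropolis-within-Gibbs with
  Normal(0, 10^4) priors on fixed effects, Uniform(0, 100) on sigma and a
  scaled inverse-Wishart prior on Sigma; posterior prediction of future
  measurements and conditional survival for a new subject.
* `ExponentialTDModel` on `episodes_locf(...)` — the naive
  time-dependent covariate model (last observation carried forward).
* `LinearGrowthModel(...).fit()` + `episodes_fitted(...)` — the
  two-stage plug-in model on a 2-year, 6-month or monthly grid.
* `run_study(...)` — replicated simulation studies of bias and coverage.

## Worked example

Simulate one dataset from the main study scenario (1000-subject scale
reduced to 300 here) and fit the joint model:

```python
from jointlsm import make_scenario, simulate, JointModel

ds = simulate(make_scenario("table1", n_subjects=300, seed=7))
print(ds.data.n_events, round(ds.data.person_years))   # 19 1513
res = JointModel(ds.data, association=("current",), center=47.15).fit()
print(res.summary())
```

```
Shared random effects joint model (MLE, adaptive Gauss-Hermite)
  subjects: 300   events: 19   loglik: -2889.6650   converged: True
  association: current
  parameter       estimate          SE                    95% CI
  beta11           38.1894      0.3659        (37.4723, 38.9065)
  beta12            1.5342      0.1041          (1.3301, 1.7382)
  sigma             2.7815      0.0994          (2.5866, 2.9763)
  Sigma11          34.1256      3.3094        (27.6393, 40.6119)
  Sigma12           2.9364      0.6764          (1.6108, 4.2620)
  Sigma22           1.7862      0.2454          (1.3053, 2.2672)
  log_lambda       -4.8886      0.3881        (-5.6492, -4.1279)
  alpha1            0.0000     (fixed)
  alpha2            0.0000     (fixed)
  alpha3            0.2155      0.0329          (0.1511, 0.2799)
```

The truth behind this simulation is `beta11 = 38.5`, `beta12 = 1.73`,
`sigma = 2.8`, `log lambda = log(0.008) = -4.83` and `alpha3 = 0.2`: with
only 19 events the association and baseline hazard are recovered within
one standard error, and `exp(alpha3) ≈ 1.24` reads as a 24% higher
rupture hazard per mm of underlying diameter.  The same model fits from
the command line (`jointlsm simulate`, `jointlsm fit --method joint-mle`,
`jointlsm study`, `jointlsm predict`); Bayesian prediction of a new
subject's growth curve and conditional rupture risk works on the output
of `jointlsm fit --method joint-bayes`.

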