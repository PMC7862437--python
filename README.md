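# ddmexplore

Drift-diffusion modelling of explore–exploit choices and response times in
horizon-style two-armed bandit tasks.

## The problem

In horizon-style bandit games, people see four instructed plays of two slot
machines (setting up unequal \[1 3\] or equal \[2 2\] information) and then
make 1 or 6 free choices. On the first free choice, longer horizons make
people both more information-seeking (**directed exploration**) and more
variable (**random exploration**). Choice data alone cannot say *how* the
brain raises its behavioral variability: a shallower choice curve is equally
consistent with a weaker reward signal relative to neural noise, or with a
lower evidence threshold. Response times break the tie.

`ddmexplore` is for computational cognitive scientists who want that
analysis as a reusable, tested pipeline: a generative model of the task, a
condition-dependent drift-diffusion model (DDM) with exact first-passage
likelihoods, the logistic-choice and RT-regression reference models, the
exclusion rules, horizon contrasts, a parameter-recovery harness, and the
sensitivity analysis that attributes random exploration to signal-to-noise
versus threshold changes.

## The model

The decision variable follows dX = μ dt + dW between boundaries ±β,
starting at αβ, plus a non-decision time T₀ (diffusion scale fixed, c = 1).
Per trial, drift, threshold and bias are functions of the observed reward
difference ΔR and information difference ΔI:

    μ = c₀^μ + c_R^μ·ΔR + c_I^μ·ΔI
    β = c₀^β + c_R^β·ΔR + c_I^β·ΔI
    α = 2·L(c₀^α + c_R^α·ΔR + c_I^α·ΔI) − 1

Ten parameters per subject per horizon, fit by maximum likelihood on
(choice, RT) pairs via Wiener first-passage densities. When bias and
threshold slopes vanish, the DDM choice curve is exactly the logistic
choice model with decision noise σ = 1/(2√2·|c_R^μ|·c₀^β) — so the horizon
ratios of c_R^μ (the signal-to-noise ratio, SNR) and c₀^β (baseline
threshold) decompose the change in random exploration:

    σ(h1)/σ(h6) = [c_R^μ(h6)/c_R^μ(h1)] · [c₀^β(h6)/c₀^β(h1)]

See `docs/methods.md` for conventions, priors, numerics and limitations.

## Worked example

```python
import numpy as np
from ddmexplore import analysis, ddm_fitting, horizon_task

# simulate one synthetic subject: 40 games per horizon x condition cell
coeffs = horizon_task.default_coefficients()
trials = horizon_task.simulate_dataset(coeffs, n_games_per_cell=40, rng_seed=42)

# fit the 10-parameter DDM per horizon and run the sensitivity analysis
fits = ddm_fitting.fit_cohort(trials)
report = analysis.sensitivity_ratios(fits)
for k in ("median_ratio_cR_mu", "median_ratio_c0_beta",
          "median_predicted_sigma_ratio_h1_h6", "dominant_contributor"):
    print(k, report.summary[k])
```

prints

```
median_ratio_cR_mu 0.603976329337047
median_ratio_c0_beta 0.9646047710165816
median_predicted_sigma_ratio_h1_h6 0.5825984488595978
dominant_contributor cR_mu
```

Reading: this subject's fitted reward-on-drift coefficient shrinks to ~0.60
of its horizon-1 value in horizon 6 while the baseline threshold barely
moves (~0.96), so the predicted decision noise roughly doubles
(σ(h1)/σ(h6) ≈ 0.58) and the increase in random exploration is attributed
chiefly to the signal-to-noise change — the generating coefficients used
ratios 0.645 and 0.933.

The same analysis is scriptable from the shell:

```bash
ddmexplore simulate --seed 0 --out trials.csv
ddmexplore fit --in trials.csv --model ddm --out ddm_params.csv
ddmexplore analyze --params ddm_params.csv --out report/
ddmexplore run --seed 0 --out full_run/     # end-to-end pipeline
```

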