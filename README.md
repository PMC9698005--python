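# mingled

Systems analysis of phenotype heterogeneity in diet-challenged mice: a
whole-body glucose/lipid kinetic model (MINGLeD) estimated with time-varying
parameters (ADAPT), plus the downstream responder/non-responder phenotype
analyses.

## The problem

Inbred APOE*3-Leiden.CETP mice fed a high-fat high-cholesterol diet (60% of
energy from fat, 0.25 w% cholesterol) split into two phenotypes despite
identical genetics and housing: *responders* (baseline chow plasma
triglyceride ≥ 1.0 mM) develop hypertriglyceridemia and obesity, while
*non-responders* (baseline TG < 1.0 mM) stay lean with flat TG. This package
implements the computational machinery to ask *which metabolic processes must
differ* between the groups, for modellers and metabolic physiologists working
with longitudinal cohort data.

## The model and the estimator

**MINGLeD** (Model INtegrating GLucose and Lipid Dynamics) is a
four-compartment ODE model — liver, plasma, periphery, intestinal lumen —
with 18 metabolite pools x, 41 fluxes j and 39 kinetic parameters θ:

    dx/dt = S · j(x, θ),      j_i = k_i · x_substrate(i)

All reactions are irreversible and first order; dietary inflows (glucose j1,
TG j11, cholesterol j24) are zeroth-order forcings; the CETP exchange flux
(j34) is driven by the plasma TG pool and trans-intestinal cholesterol
excretion (TICE, j35) by the VLDL-C pool.

**ADAPT** (Analysis of Dynamic Adaptations in Parameter Trajectories) fits
slowly drifting parameters to longitudinal data. Per Monte-Carlo iteration it
samples a data realization from Normal(mean, SD) at each measurement time,
interpolates with splines, initializes (θ, x) at a steady state fitted to
t = 0, then marches over an N-step grid minimizing

    Σ_k ((ŷ_k(t_n; θ) − s_k(t_n)) / σ_k(t_n))²
      + λ Σ_i ((θ_i − θ_i,n−1) / (θ_i,ref · Δt))²

with λ = 0.01 and N = 200 as the published settings. The ensemble over
realizations is summarized by the pointwise median and the 35th–65th
percentile band ("30% of solutions around the median").

Downstream analyses: baseline-TG stratification, fecal bile-acid
hydrophobicity index (molar-fraction-weighted Heuman coefficients),
correlation tables, group comparison of flux trajectories via band overlap,
and the energy-imbalance arithmetic linking fat-mass differences to daily
energy expenditure.

## Worked example

```python
import numpy as np
from mingled import (Model, AdaptConfig, GroundTruthSpec,
                     generate_ground_truth, run, energy_imbalance,
                     imbalance_fraction)
from mingled.network import PARAMETER_INDEX

model = Model()

# simulate the model with a known 30% linear fall in VLDL-TG production,
# then ask ADAPT to recover it from the noisy longitudinal dataset
spec = GroundTruthSpec(drift={"k_vldl_tg_production": ((0.0, 1.0), (196.0, 0.7))})
dataset, truth = generate_ground_truth(spec, model, np.random.default_rng(42))
result = run(dataset, model, AdaptConfig(n_steps=50, n_iterations=10, seed=1))

est = np.median(result.quantity("k_vldl_tg_production"), axis=0)
true = truth.param_array(result.grid)[PARAMETER_INDEX["k_vldl_tg_production"]]
print(f"mean relative error: {np.mean(np.abs(est - true) / true):.1%}")
# mean relative error: 2.9%

# the energy-imbalance worked example: 5 g of fat over 12 weeks
imb = energy_imbalance(5.0, 84.0, 9.4)
print(f"{imb:.2f} kcal/day = {imbalance_fraction(imb, 12.0):.1f}% of a 12 kcal/day EE")
# 0.56 kcal/day = 4.7% of a 12 kcal/day EE
```

The first number says the estimated parameter trajectory tracks the true
30% decline to within a few percent on average; the second reproduces the
0.6 kcal/day (≈5% of energy expenditure) figure at one-decimal rounding.

A command-line pipeline wraps the same machinery:

```sh
mingled simulate --seed 0 --out out            # synthetic 36+11-mouse cohort
mingled fit out/dataset.csv --profile ci --seed 0 --out out/fit
mingled analyze --per-mouse out/per_mouse.csv --fit out/fit --out out/analysis
mingled report --out out/analysis
```

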