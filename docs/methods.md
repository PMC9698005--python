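# Methods

## The kinetic model

The model partitions whole-body glucose and lipid metabolism over four
compartments (liver, plasma, periphery, intestinal lumen) with 18 pools,
41 fluxes and 39 parameters. Pools are in µmol per mouse; carbohydrate pools
in µmol glucose equivalents and acetyl-CoA pools in µmol acetyl units. Fixed
stoichiometric yields link the units: 2 acetyl per glucose (glycolysis +
pyruvate dehydrogenase), 24 acetyl per triglyceride (three ~C16 fatty
acids), 18 acetyl per cholesterol, 3 fatty acids per TG. Fluxes are in
substrate-pool units per day.

Every reaction is irreversible first order in a single pool, a deliberately
coarse choice: the estimator compensates for kinetic simplicity by letting
rate coefficients drift under data constraints, so rate laws encode
connectivity and stoichiometry, not enzyme mechanism. Three exceptions:

* dietary inflows (glucose j1, TG j11, cholesterol j24) are zeroth-order
  forcings set by food intake and diet composition (defaults: 3500, 960 and
  16 µmol/day, a ~2.5 g/day high-fat high-cholesterol diet);
* amino-acid routing from dietary protein (j6–j9) is zeroth order with four
  partition parameters (gluconeogenic/ketogenic × liver/periphery);
* the CETP flux (j34, HDL-C → VLDL-C) is proportional to the plasma (VLDL)
  TG pool, the physiological driver of CETP exchange, not to its substrate.

Trans-intestinal cholesterol excretion (TICE, j35) is first order in the
VLDL-C pool and routes plasma cholesterol directly to the lumen. Bile acids
cycle enterohepatically (synthesis j30, biliary secretion j36, reabsorption
j38, fecal loss j39). The 39th parameter is the fraction of unabsorbed
fecal fat recovered as free fatty acids (default 0.17), used only in the
fecal-FFA observable mapping.

Because every flux is linear in the state at fixed parameters, the system
is dx/dt = A(θ)x + b(θ). Steady states are solved linearly (with bounded
root-finding and long-horizon relaxation as fallbacks), and the estimation
loop propagates states exactly with a matrix exponential, which is what
makes step-wise re-estimation of all 39 parameters affordable.

### Reference parameterization

Defaults are built from a design table of target pools and mass-balanced
steady-state fluxes (k = j*/x*), describing an obese mouse on the high-fat
diet: plasma TG 1.5 mM, TC 3 mM, glucose 8 mM, ~8.9 g peripheral fat
(body weight ≈ 34 g with a 25 g lean mass), fecal outputs of 31 µmol/day
neutral sterols, 25 µmol/day bile acids and ~31 µmol/day FFA, VLDL-TG
production 250 µmol/day, hepatic de novo lipogenesis 20 µmol TG/day. The
implied energy turnover (~3 kcal/day from glucose oxidation, ~8 kcal/day
from fat oxidation) is consistent with the 12 kcal/day daily energy
expenditure used in the energy-imbalance example. The design point is an
exact steady state by construction and the Jacobian there is stable.

### Observables

Plasma concentrations divide pools by a configurable plasma volume (default
1.0 mL); body weight is a constant lean mass plus peripheral TG mass
(885.4 g/mol); fecal and flux observables map directly to fluxes. Total
cholesterol is VLDL-C + HDL-C, so TC ≥ HDL-C holds structurally.

## The estimation procedure

Each Monte-Carlo iteration: (1) sample every observable at every measurement
time from Normal(mean, SD), truncated at zero, and interpolate (natural
cubic spline by default; monotone PCHIP and low-order polynomial variants
available); (2) fit a steady-state initial condition to the realization at
t = 0 by bounded least squares; (3) march over a uniform grid (0–196 days),
at each step re-estimating all parameters by minimizing weighted data misfit
at the step's endpoint plus the change penalty
λ·Σ((θᵢ−θᵢ,prev)/(θᵢ,ref·Δt))². Published settings: 200 steps, λ = 0.01.

Numerical conventions, all configurable:

* data SDs interpolate linearly in time and are floored at 5% of |mean| so
  zero-variance points cannot dominate the objective;
* θ_ref is the initialization value floored at machine epsilon; bounds keep
  θ ≥ 0 (trust-region reflective least squares, x_scale = θ_ref,
  ftol = xtol = 1e-6, at most 40 objective evaluations per step — tightening
  these changes trajectories by ≲1e-3 relative);
* initialization adds a weak ridge toward the reference parameterization
  (weight 0.01 on relative deviation): 39 parameters against ~14 observables
  are otherwise under-determined, and the ridge selects the solution nearest
  the nominal physiology; up to 10 restarts from log-normally perturbed
  starts guard against stalls;
* cross-sectional group-average constraints (VLDL-TG production, hepatic de
  novo lipogenesis, biliary secretion, liver lipids) enter the objective
  only between their measurement weeks (4–28) and are re-sampled per
  iteration like every other observable;
* failed iterations are excluded; a run errors out if more than 10% fail.

The ensemble is summarized by the pointwise median and the 35th–65th
percentile band — the reading of "30% of solutions around the median"
adopted here; a median ± 30% convention is available via configuration.

### Regularization behavior

Aggregate damping is monotone: summed reference-normalized total variation
of the parameter trajectories does not increase, and total misfit does not
decrease, across λ = 0.01 → 1 → 100 (asserted in the test suite). Two
caveats, verified empirically at several grids and tolerances: individual
parameters whose trajectories are insensitive to λ show noise-level total
variation differences of either sign, and the unregularized λ = 0 limit can
destabilize — greedy per-step fitting drives states to extremes and the
total misfit can *exceed* that at λ = 0.01. Per-trajectory, per-parameter
monotonicity is therefore not guaranteed by the procedure; only the per-step
damping at fixed previous state is. This is the reason the method is used
with λ > 0 in the first place.

## Synthetic data

Two generators, both first-class and deterministic given a seed:

**Template cohort** (default 36 responders, 11 non-responders, sampled at
weeks 0/4/9/13/20/24/28, mirroring the 4–6-week design). Group templates
are piecewise-cubic control-point curves: responder plasma TG rises from
week 4 (baseline 1.5 mM), peaks at 4.0 mM at week 20 and settles at 2.5 mM
by week 24; non-responder TG is flat at 0.7 mM. A per-mouse log-normal
latent "bile-acid availability" factor couples fecal bile-acid output (and
its deoxycholate share) positively and fecal FFA output negatively, acting
only after diet start; this reproduces the study's cross-mouse correlation
pattern (fecal FFA vs fecal bile acids ρ ≈ −0.97 in the default cohort) and
keeps baseline TG uncoupled so threshold stratification recovers the labels.
Measurement CVs are observable-specific (4–15%; body weight lowest as a
scale reading). Cross-sectional constraints are emitted once as whole-cohort
averages, identical for both groups, at the reference model's steady-state
values. The generator emulates group structure, noise and correlations —
not within-mouse autocorrelation, attrition (supported via configuration
but defaulting to full follow-up), or any mechanism; passing tests on it
shows the pipeline's statistical machinery works, not that the biology of
real cohorts is captured.

**Model-consistent ground truth**: simulates the kinetic model itself from
steady state with piecewise-linear parameter drift, samples observables at
the study weeks, and reports group means with SD/√n sampling error and SD
columns equal to the per-mouse CV × value (n = 12 by default, CV 5%; body
weight 2% where per-observable CVs are given). The true parameter
trajectory is returned for recovery scoring.

## Downstream analyses

* **Stratification**: non-responder iff baseline (week 0, chow) plasma TG is
  strictly below 1.0 mM; mice lacking a baseline are excluded with a
  warning.
* **Hydrophobicity index**: HFI = Σ fraction_s · c_s over molar fractions,
  with unconjugated Heuman-scale coefficients shipped as editable external
  literature constants (LCA 1.00, DCA 0.72, CDCA 0.59, CA 0.13, UDCA −0.31,
  muricholates −0.78 to −0.90). The generator emits deconjugated fecal
  species, matching gas-chromatographic fecal bile-salt analysis.
* **Correlations**: Spearman by default (fecal measures are skewed),
  Pearson available; pairwise-complete deletion; constant series are an
  error, not a zero.
* **Trajectory comparison**: per grid point, median difference and band
  overlap between two groups' ensembles; a quantity is flagged "separated"
  when the 30% bands are disjoint over ≥50% of the horizon. Descriptive by
  design — no hypothesis tests are attached to estimated trajectories.
* **Energy imbalance**: Δfat·density/period with a 9.4 kcal/g body-fat
  energy density default; 5 g over 84 days gives 0.56 ≈ 0.6 kcal/day, 5% of
  a 12 kcal/day expenditure.

## Problem sizes and defaults

The command-line `ci` profile and the test suite run 50-step grids with
1–10 Monte-Carlo iterations; the `paper` profile selects the published
200-step, 100-iteration, λ = 0.01 configuration. The acceptance script uses
50 steps × 10 iterations for recovery, 50 steps × 1 iteration per λ for the
regularization sweep, and 40 steps × 4 iterations per group for the
end-to-end contrast.

## Known limitations

* Rate laws are first order by design; saturation, allostery, insulin
  action and erythrocyte cholesterol are out of scope.
* The parameter inventory beyond the named fluxes follows this package's
  canonical completion of the network; alternative index conventions for
  TICE vs biliary cholesterol secretion are handled by binding semantics to
  flux names.
* Identifiability is partial (39 parameters, ~14 observables): the
  initialization ridge and the change penalty select solutions near the
  reference physiology; parameters far from any observable are reported
  essentially as their prior trajectory.
* The ensemble band reflects measurement-noise propagation, not structural
  model uncertainty.
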