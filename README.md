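# fpmat — in vivo fluorescent-protein maturation kinetics in budding yeast

Fluorescent proteins only become visible after their chromophore matures,
and in fast-dividing yeast the maturation half-time of many popular FPs is
comparable to the cell cycle itself. `fpmat` implements a model-based
pipeline for estimating in vivo maturation rates from time-lapse
fluorescence of optogenetically induced FP expression: a delay-differential
gene-expression cascade simulated over stochastically growing-and-dividing
mother cells, fitted to population-averaged fluorescence by grid-based
maximum likelihood, with profile-likelihood confidence intervals and AIC
selection between one- and two-step maturation mechanisms. It is aimed at
quantitative cell biologists and modellers who need maturation-corrected
reporter kinetics or want to run the estimation on their own tracking data.

## The model

After a step induction at t = 0, abundances in a mother cell follow

    dm/dt  = k_r s(t − τ₁) − k_dr m
    dPd/dt = k_p m(t − τ₂) − k_m Pd          (two-step: Pd1 → Pd2 → Pm)
    dPm/dt = k_m Pd

with delays τ₁ = 2 min (light → active promoter) and τ₂ = 4 min
(mRNA → immature protein). The cell's volume V(t) grows linearly within
each cycle and loses the bud at cytokinesis; cycle parameters (T, μ, V_d)
are drawn from a multivariate log-normal fitted to tracked cells, and at
each division every species is multiplied by the retained fraction
f_c = (V₁ − V_d)/V₁, so the measured concentration P_m/V is continuous.
The observable is the 500-cell average of P_m/V with Gaussian noise
σ = 0.02·max y, giving the least-squares likelihood

    χ²(θ) = Σₙ (y(tₙ) − ŷ(tₙ, θ))² / σ²,   θ = [k_dr, k_p, k_m],  k_r = k_p.

χ² is evaluated on a dense log-spaced grid; profile likelihoods
χ²_PL(θᵢ) = min over the other parameters reuse the same grid, and the 95%
CI is the sub-level set at χ²(θ*) + 3.841. Maturation half-times are
t₅₀ = ln 2 / k_m (one-step) or, for two-step FPs, the time for half of a
pure dark pool to mature (root-finding; the sum of step half-times is a
lower bound). See `docs/methods.md` for the full account.

## Worked example

Generate a ground-truthed synthetic experiment (50 tracked mother cells,
sfGFP-like one-step truth with a 6.9-min half-time), then fit it:

```python
from fpmat import FitConfig, MaturationModel, generate_dataset, preset_params

ds = generate_dataset(preset_params("sfgfp"), n_cells=50, seed=300, dt=0.2)
model = MaturationModel(ds, kind="one_step",
                        config=FitConfig.reduced(seed=777),
                        name="sfGFP-like")
res = model.fit()
print(res.summary())
```

```
Maturation model fit
======================================================
model kind:       one-step
observations:     41
sigma (2% rule):  0.6998
chi2 at optimum:  24.90
AIC:              30.90
------------------------------------------------------
parameter estimates (1/min):
  k_dr   0.08588
  k_p    1.131
  k_m    0.06922
------------------------------------------------------
FP          t50 (min)   95% C.I.
sfGFP-like  10.0        [5.0, 15.2]
```

The recovered half-time (10.0 min) sits inside the 95% profile-likelihood
CI, which also contains the generating truth of 6.9 min. The CI is wide on
purpose: for fast FPs the maturation rate and the mRNA degradation rate
shape the rise curve interchangeably (the model is symmetric under swapping
k_dr and k_m), so the data constrain the pair, not the point — the profile
reports exactly that. `res.compare(...)` fits the other maturation kind and
selects by AIC; `res.plot_fit()` / `res.plot_profile()` draw diagnostics.

The same pipeline runs from the shell on tab-separated tracking tables:

```sh
fpmat synth --preset sfgfp --n-cells 50 --seed 300 --out demo
fpmat fit --tracks demo/tracks.tsv --cycles demo/cycles.tsv \
          --kind one_step --reduced --out demo_fit
```

Derived predictors are one call away: `simulate_chx_shutoff` (fluorescence
rise after a translation-shutoff chase, plateau 1 + λ/k_m),
`simple_concentration_model` (fast deterministic dilution approximation),
`histone_pulse_model` and `align_cell_cycle_traces` (cell-cycle-resolved
reporter profiles on the standard 70-point normalised grid), and
`maturation_half_time` / `two_step_lower_bound` for half-time conversions.

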