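# Methods

`fpmat` estimates in vivo maturation kinetics of fluorescent proteins (FPs)
in budding yeast from population-averaged, time-lapse fluorescence after
step induction of FP expression. This note documents the models, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Abundance model

After induction at t = 0, species abundances in a single mother cell follow
a linear delay-differential cascade:

    dm/dt    = k_r s(t - tau1) - k_dr m          (mRNA)
    dPd/dt   = k_p m(t - tau2) - k_m Pd          (dark precursor)
    dPm/dt   = k_m Pd                            (mature FP)

with a Heaviside input `s` (the light-responsive promoter is treated as
switched permanently on: the activator's dark reversion is slow compared
with the pulse spacing used experimentally). The two-step variant splits
maturation into `Pd1 -> Pd2 -> Pm` with rates `k_m1`, `k_m2`. All states are
zero before `tau1`. There is no FP degradation term: loss is entirely by
division (full model) or by a linear dilution term (simplified model).

Parameters (per minute unless noted):

| parameter | meaning | default / bounds |
|---|---|---|
| `k_r` | transcription rate, promoter on | tied to `k_p` during inference |
| `k_dr` | mRNA degradation rate | bounds [0.0462, 0.1386] (5–15 min mRNA half-life) |
| `k_p` | translation rate per mRNA | free amplitude, bounds [1e-3, 10] |
| `k_m`, `k_m1`, `k_m2` | maturation rates | upper bound 0.1386 (5-min half-time); grid lower edge ln2/300 |
| `tau1` | light-to-promoter delay | 2 min |
| `tau2` | mRNA-to-immature-protein delay | 4 min |

The total delay `tau1 + tau2 = 6 min` is treated as a known constant. Its
mis-specification matters more for fast-maturing FPs: a ±2-min error shifts
the fitted half-time of a ~7-min FP relatively more than that of a ~50-min
FP (asserted as a test invariant).

## Volume model

A mother cell grows linearly within each cycle, `V(t) = V0_c + mu_c t`,
and at cytokinesis loses the bud volume `Vd_c`; the retained fraction is
`f_c = (V1_c - Vd_c)/V1_c`. Cycle parameters `(T, mu, Vd)` are drawn per
cycle from a multivariate log-normal fitted to tracked-cell records
(empirical mean and (n-1)-covariance of the logs); draws are rejected until
`mu*T > Vd`, so every simulated mother gains net volume per cycle (aging).
Initial volumes are normal; each cell starts a uniform random phase `tau`
into its first cycle with volume `V0 + mu*tau`, and its first division
occurs at `T - tau` (the phase consumes part of the first cycle — the
alternative reading, a full first cycle of length `T`, would make phase and
volume inconsistent).

At division, all species abundances are multiplied by `f_c`. Because the
volume drops by the same factor, the measured concentration `Pm/V` is
continuous across divisions (asserted to 1e-9 on every simulated
trajectory). The delayed translation term reads the *stored* mRNA history:
for arguments before a division it sees pre-reset values, since ribosome
loading at time t reflects the mRNA present at `t - tau2`.

## Numerical integration

The cascade is integrated by the method of steps: fixed-step RK4 on a mesh
containing every discontinuity point (`tau1`, `tau1+tau2`, division times
and their `tau2`-shifted images, and all output times), with cubic-Hermite
interpolation of the stored mRNA history (values and analytic slopes) for
the delayed argument. The step is capped at `2/(k_max + dilution)` for
explicit stability and at `tau2` so the delayed argument always lies in
recorded history. Defaults: `dt = 0.05 min` for single-cell simulation
(matches the exact matrix-exponential solution of the division-free cascade
to better than 1e-6 relative and passes a step-halving check at 1e-4),
`dt = 0.5 min` inside the fitting forward model (integration error far
below the 2% observation noise). The integrator is vectorised across
parameter values sharing a cell's division events, which is what makes the
dense likelihood grids affordable.

Division resets are linear, so the whole forward model is exactly linear in
the product `k_r * k_p`; all population means are therefore simulated once
at unit amplitude and rescaled. This identity (not an approximation) also
lets the amplitude parameter be minimised in closed form at every grid
node, `a* = <y,u>/<u,u>` clamped to bounds, avoiding amplitude-quantisation
artefacts in the profiles. The `k_p` grid is kept for profiling `k_p`
itself.

## Estimation

Observed data are the population-mean concentration `y(t_n)` on a 5-min
grid to 200 min, modelled as the 500-cell (configurable) forward average
plus i.i.d. Gaussian noise with `sigma = 0.02 * max y` — sigma is set by
rule, not estimated. Maximum likelihood is the chi-square minimiser

    chi2(theta) = sum_n (y(t_n) - yhat(t_n, theta))^2 / sigma^2

evaluated on a dense log-spaced grid over `(k_dr, k_m)` (default 60 points
per dimension) with the amplitude concentrated out; no local optimiser is
needed for three parameters, and the same grid evaluations provide all
profile likelihoods. A single fixed seed drives the forward volume
trajectories for every theta (common random numbers), making the objective
deterministic and smooth. Optional refinement iteratively zooms a small
log-spaced grid (default 7 points/dimension, 2 iterations) around the best
node — grid-based and derivative-free, and it vectorises, which is why it
is used instead of a simplex; it is off by default.

`k_r = k_p` is enforced because fluorescence units are arbitrary: only the
product is identifiable. For two-step models `k_m2 = k_m1`: with both rates
free the likelihood has a flat valley along pairs `(k_m1, k_m2)` sharing
the same equivalent half-time (shown directly in a test: chi2 varies by
<1% of the across-valley variation), so the individual rates are
practically unidentifiable unless they differ by an order of magnitude —
in which case the slow step dominates and a one-step model suffices anyway.

A further structural feature worth knowing: the one-step cascade is
symmetric under exchanging `k_dr` and `k_m` (the transfer-function poles
swap; the amplitude change is absorbed by `k_p`). Within the allowed boxes
this makes the likelihood ridge genuinely flat for fast FPs whose `k_m`
overlaps the `k_dr` band, and ML half-time estimates scatter accordingly —
the profile CIs are wide in exactly this direction and remain valid.

Profile likelihood: `chi2_PL(theta_i) = min over others`, read off the
dense grid; the 95% CI is the sub-level set at `chi2* + 3.841`
(chi-square(1) quantile), with threshold crossings log-interpolated between
grid nodes. A profile still below threshold at the lower grid edge is
reported one-sided ("no lower bound" on the rate, infinite upper half-time).
Half-time CIs map rate CIs monotonically: `ln2/k` (one-step) or the
simulated equivalent half-time (two-step).

Model selection uses `AIC = chi2 + 2k` (Gaussian constants cancel at fixed
sigma); tied two-step and one-step models both have k = 3 free parameters,
so the comparison reduces to chi2. On synthetic data the discrimination
power is limited by the 2% noise rule: noise-free replicates select the
generating kind 100% of the time with mean Delta-AIC ≈ 4.5–8, but the
noise-induced spread of Delta-AIC (sd ≈ 4.5) brings expected accuracy to
~86–92% per arm at the study's scale; the 90% selection test documents this
honestly (see "Study sizes" below).

Equivalent two-step half-time: the time at which the mature fraction of a
closed `Pd1 -> Pd2 -> Pm` system starting from pure `Pd1` reaches 1/2,
found by Brent root-finding (1e-6 min tolerance) on the sequential-kinetics
solution (confluent branch at equal rates). The sum of step half-times
`ln2/k_m1 + ln2/k_m2` is a lower bound (property-tested). For step
half-times of 17 and 30 min the equivalent half-time is 56 min.

## Derived predictors

**Translation shutoff (CHX).** From balanced growth at rate `lambda`
(production balancing dilution), stopping translation and dilution lets the
dark pool mature: relative fluorescence rises monotonically from 1 to
`1 + lambda/k_m` (one-step) or `1 + Pd1/Pm + Pd2/Pm` (two-step, closed
forms). Slower maturers rise more — the panel ordering across
sfGFP-, mVenus-, mCherry- and mKate2-like parameters reproduces the
half-time ordering. Computed in closed form, no integration.

**Simplified concentration model.** The same cascade written directly in
concentrations, with `-lambda x` on every species replacing division
events. The default `lambda` is the mother-lineage dilution rate
`ln(1 + mu*T/V0)/T` (log-normal means): tracked mothers do not double in
volume per cycle — they grow from `V0` to `V0 + mu*T` and shed the bud —
so the population doubling rate `ln2/T` (available as `mode="doubling"`)
overstates their dilution by ~60% and biases half-time estimates
accordingly. With the mother-lineage rate, simple-model fits reproduce the
individual-based estimates exactly on noise-free mVenus-like and two-step
fixtures; for the fastest FPs the `k_dr`/`k_m` ridge lets the two
estimators wander apart (~35% on a noise-free sfGFP-like fixture), so
cross-model agreement should only be expected for FPs whose maturation is
slower than mRNA turnover.

**Histone-pulse reporter.** Histone synthesis is a rectangular pulse over
the normalised cycle (default: budding at 0.375 — the 30:50 segment split —
to 0.75; height 1 au/min; mother retains 0.7 of the tagged pool at
division); maturation acts on the pulse through the one- or two-step
cascade with no mRNA stage or delays. Cycles are propagated by exact matrix
exponentials segment by segment until the boundary state is periodic
(relative tolerance 1e-6). The profile is reported on the standard 70-point
grid: 30 points karyokinesis-to-budding, 50 budding-to-karyokinesis, last
10 dropped (the window therefore ends at 0.875 of the cycle — the pulse
must end before that for the pre-anaphase plateau to be visible, which is
why the default `pulse_end` is 0.75). A fast reporter (7-min half-time)
shows plateau–rise–plateau; a slow two-step reporter (22-min steps) rises
even through G1, because precursor made in the previous cycle is still
maturing — the "paradoxical" G1 increase.

**Trace alignment** interpolates each annotated cycle linearly onto the
same 30+50 grid, drops the last 10 points, and averages across cycles.

## Synthetic data

The generator emulates the study design: 50 tracked mother cells (each with
its own stochastic volume trajectory), concentrations sampled every 5 min
to 200 min, Gaussian noise `sigma = 0.02 * max` added to the population
mean (per-cell noise available), and the t = 0 sample pinned to zero to
emulate autofluorescence subtraction. Fixture cell-cycle law: log-normal
with means (80 min, 0.2 fL/min, 12 fL), log-scale SDs (0.2, 0.2, 0.3),
uncorrelated; initial volumes N(30, 5²) fL. ~24% of raw draws violate
`mu*T > Vd` and are rejected. Kinetic presets tie `k_r = k_p = 1`, mRNA
half-life 10 min, and ground-truth half-times of 6.9 min (sfGFP-like),
20.8 min (mVenus-like) and 22-min steps (mRFP1/mCherry-like two-step).

What passing tests show: the estimation machinery recovers generating
parameters within the quoted uncertainty when the model is correctly
specified and the noise follows the declared rule. What they do not show:
robustness to segmentation errors, bleaching, autofluorescence dynamics,
within-cycle growth-rate fluctuation, or mother/bud concentration
gradients — none of which the generator emulates.

## Study sizes and runtimes

Chosen as desk-scale defaults: recovery runs fit 50-cell datasets with 100
forward cells, 20 grid points per dimension and refinement (seconds per
fit); the coverage and AIC studies use 50 replicates per arm at lighter
fidelity (25 forward cells, 12 grid points, dt = 1 min), where fitting
fidelity was verified not to limit selection accuracy. Synthetic data for
tests are generated at `dt = 0.2 min`. Full-fidelity settings (500 forward
cells, 60-point grids) remain the library defaults.

## Known limitations

- The delays are constants, not estimated; the light input is a step.
- Two-step rates are reported as a single tied value; individual step rates
  are not recoverable from this experimental design.
- For FPs with `k_m` inside the `k_dr` box, the `k_dr`/`k_m` exchange
  symmetry widens half-time CIs and makes the ML point sensitive to noise;
  interpret the CI, not the point estimate.
- The simplified concentration model treats dilution as a constant rate,
  ignoring mother-cell aging (dilution actually slows as mothers enlarge).
- The histone model's pulse shape and retention are stylised defaults, not
  measured quantities.
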