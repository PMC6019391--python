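# Methods

## The model

`satrace` implements a rectified two-accumulator race model of two-choice
perceptual decisions.  Evidence for the correct and the incorrect response
accumulates independently in discrete time; per step of length `dt` each
accumulator gains

    dx = v * dt + sigma * sqrt(dt) * N(0, 1),      x <- max(x + dx, 0)

(an Euler–Maruyama discretization of a drift–diffusion increment, rectified
at zero so accumulated evidence is never negative).  Starting points are
drawn per trial and per accumulator from `Uniform(0, S_z)`.  The first
accumulator to reach the boundary `A` determines the choice; the reaction
time adds a non-decision time drawn from a uniform of mean `T_er` and width
`S_Ter`.  The 2 (speed/accuracy instruction) x 2 (easy/hard difficulty)
design gives drift rates per difficulty (shared across instructions) and,
depending on the model variant, a boundary and possibly a start-point range
or non-decision mean per instruction.  The accuracy boundary is pinned to 1
for identifiability (the scaling property: multiplying `A`, `S_z`, both
drifts and `sigma` of a cell by any `c > 0` leaves behavior unchanged).

The noise step uses `sigma * sqrt(dt)`: this is the only discretization
under which the forced-excursion column of the reference parameter table
(every speed-condition value divided by the speed boundary, `0.499 / 0.893 =
0.559`) is consistent with the scaling property, so the tabled noise
parameter is stored as a standard deviation even though the table labels the
row as a variance.

### Forced-excursion re-expression

`to_forced_excursion` divides every evidence-unit parameter of the speed
cells (`A`, `S_z`, `v_correct`, `v_incorrect`, `sigma`) by the fitted speed
boundary, leaving `T_er`/`S_Ter` untouched.  The result is mathematically
equivalent trial-for-trial — the package checks this *exactly*: each
simulated trial owns a private seed and consumes random draws in a fixed
order (start correct, start incorrect, non-decision, two normals per step),
so free and forced parameter sets reproduce each other's choices and RTs to
the float, and hence identical QMPE objectives.  Boundary crossing is
detected with a relative tolerance (`x >= A * (1 - 1e-9)`) so that exact
zero-noise ramps cross at the closed-form step despite float summation.

Ties (both accumulators first crossing on the same step) resolve to the
accumulator farther above the boundary; exact ties flip a coin from the
trial's stream.  Both events have probability ~0 under noise.

## QMPE fitting

Behavioral fitting uses quantile maximum probability estimation: the
0.1/0.3/0.5/0.7/0.9 RT quantiles (type-7 linear interpolation) of correct
and error responses per condition define six bins per response type; the
objective is the multinomial kernel `sum N_i ln max(p_i, 1e-10)` with
proportions `p_i` estimated from seeded simulation (trials that never cross
within the 5x-median-RT horizon are excluded from both data and predicted
proportions).  Cells with fewer than 10 errors collapse to a median split;
cells with none keep a single error-mass bin so the error rate still
constrains the fit.

Three variants are compared (K = free parameters): model 1 frees only the
speed boundary across instructions (K=9); model 2 additionally frees the
start-point range (K=10); model 3 instead frees the non-decision mean
(K=10).  Ranking uses `AIC = -2LL + 2K`, `BIC = -2LL + K ln n` and Akaike
weights `exp(-delta_i/2) / sum_j exp(-delta_j/2)`.

### Optimization

The objective is deterministic given the fit seed, and because every
simulated trial has its own seed stream it varies *smoothly* with the
parameters (common random numbers); this matters more than raw speed for
the global search.  Fitting runs differential evolution (Sobol
initialization, population 6 per dimension, 42 generations, no early
stopping — the relative `tol` of the library implementation is meaningless
against an objective of magnitude ~1e5) on a 1,200-trial-per-condition
objective (censored at 60% of the full horizon — implausible candidates
would otherwise burn the whole horizon on every trial), then a bounded Powell refinement on a 5,000-trial objective, and
reports likelihood/AIC/BIC from the full 10,000-trial objective (the
simulation size the original design prescribes).  The search phase runs on
a scale-aware sub-box of the bounds covering empirically sensible values
(drifts up to 4 per median RT, noise up to 1.6 per root median RT, and so
on); the Powell refinement runs on the full bounds, so estimates can leave
the box.  Ten dimensions of weakly identified surface are simply too much
for an affordable evolution over the full box volume, and restricting only
the *search* phase preserves the bounds' role as hard constraints.  Inside
bootstrap loops a Nelder–Mead refinement from the original estimates
(`refit_simplex`) replaces the global search.

Bounds: `A_speed in (0.2, 2]`, start-point range expressed as a fraction
(< 0.95) of the cell's boundary, drifts in [0, 10], `sigma in (0.01, 5]`,
`S_Ter <= 2 T_er`.  The non-decision mean is capped at 0.8x the *median* RT
rather than any function of the minimum RT: with start points up to `S_z`
an accumulator can begin arbitrarily close to the boundary, so the fastest
RTs genuinely undercut `T_er` and a minimum-RT cap would exclude the true
value (verified on synthetic data, where such a cap pinned `T_er` at the
bound and biased every other parameter).

### What recovery can and cannot do

At 10,000 trials per condition the maximum of the QMPE objective lies at
the generating parameters (a simplex started from the truth does not move),
and affordable optimization recovers the speed boundary to a few percent
and the correct-response drifts to well within 15%.  The *incorrect*
drifts, however, are very weakly identified at realistic values (0.098 and
0.004 in median-RT units): error RTs are driven almost entirely by noise
and start-point variability, so a wide valley in (`v_incorrect`, `S_z`,
`S_Ter`, `T_er`) changes the objective by only tens of nats.  Recovering
them to ±15% relative error would require essentially exact convergence of
a 10-dimensional global search (hours of CPU), which the package does not
attempt; the acceptance suite documents this as an expected shortfall of
the incorrect-drift recovery, not of the estimator.

## Neural-signal machinery

### MEP-difference signal

MEP amplitudes are z-scored within muscle x participant x session and the
responding-minus-nonresponding difference per trial is smoothed on a fixed
grid by a Gaussian-kernel weighted mean with FWHM = 5% of median RT
(`sigma_k = FWHM / (2 sqrt(2 ln 2))`).  Default grids: stimulus-locked
0–150% of median RT, response-locked −100–0%, in 1% steps (the original
design states the step and FWHM; the spans are package choices).  Grid
points with summed kernel weight below 1.0 are masked — a weighted mean
supported by less than one trial's worth of weight is dominated by a single
far-away point.

Confidence bands are per-grid-point BCa bootstrap intervals over trials
(bias correction from the fraction of bootstrap signals below the observed
one; acceleration from the jackknife skewness, which for a weighted mean
has a closed leave-one-out form).  The bias-corrected-only variant (no
acceleration) is used where many intervals are needed cheaply.

Two permutation tests compare conditions, both permuting trial labels and
re-smoothing per permutation: a build-up-slope test (OLS slope of the
stimulus-locked signal between 50% and 100% of median RT) and a
cluster-amplitude test whose candidate clusters are maximal grid runs where
the two groups' 90% BCa bands do not overlap, scored by the sum of
point-wise differences against the permutation distribution of the largest
absolute cluster sum.  P-values use the exact-test convention
`(1 + #{null >= obs}) / (1 + n_perm)`, two-sided by doubling the smaller
tail and capping at 1.  With duplicated groups the observed difference is
exactly zero and the p-value sits at the top of its range (not exactly 1 —
the null distribution is continuous around the observed value).

### Model-predicted MEP signals

For each condition, simulated trials are probed at TMS latencies resampled
from the observed schedule.  The whole of `T_er` is treated as
pre-accumulation delay (the signal is recorded at the motor end of the
pipeline, and RTs are EMG-onset-like), jittered per trial by `S_Ter`;
pulses before accumulation onset read zero from both accumulators, and
pulses after the simulated response are discarded, mirroring the empirical
censoring.  The correct-minus-incorrect readout is smoothed on the data
grids; a single fitted amplitude scale per model (closed form
`sum(p*o)/sum(p*p)`) maps model units to z-units.

### CPP-style predictions

The centroparietal ERP is modelled as the *sum* of the two rectified
accumulators: flat until a sensory delay `T_e`, accumulating until the
boundary, then continuing for a motor duration `T_r = T_er - T_e` (stimulus
still on until the overt response); each trial is baseline-corrected by its
first sample and removed from averages once it has responded, exactly as
the empirical epochs are treated.  The `S_Ter` spread jitters `T_e`
(mirroring the MEP-side convention).  Behavior is untouched by the split:
predicted RT distributions equal the behavioral simulator's exactly under
shared seeds.  The `(scale, T_e)` pair minimizing the summed MSE over both
alignments and all conditions is found by a deterministic grid over
`T_e in [0, T_er]` (21 points) with the closed-form scale at each, plus a
bounded scalar refinement around the best grid point — with scale profiled
out the problem is one-dimensional, so a stochastic multi-start search
would add cost without benefit.

### Model comparison

Predictions are scored against observed signals by MSE over all unmasked,
pairwise-overlapping grid points of all conditions and alignments, after
each model's single amplitude scale is fitted.  For MEP-style data,
`AIC = n ln(MSE) + 2K` with K=1 (only the amplitude was free) feeds Akaike
weights; no AIC is computed for epoch-style data, whose autocorrelation
invalidates the independence assumption.  The free-vs-forced contrast is
additionally bootstrapped: each replicate resamples RT trials within
condition, refits locally from the original estimates, rebuilds the forced
twin, resamples the neural data within condition, refits scales, and
records `MSE(free) - MSE(forced)` (positive favors the forced variant);
the 95% interval is bias-corrected (no acceleration) and the p-value is the
smallest alpha at which the BC interval excludes zero.

## Synthetic studies

The generator emulates the study structure: 18 participants x 324 trials
per condition cell (TMS-style preset, time normalized to median RT) or 23 x
200 (EEG-style preset, milliseconds); TMS pulses planned on 66% of trials
in four equal-width equiprobable bins of a 5–500 ms (speed) / 5–600 ms
(accuracy) window, cancelled when the response precedes the pulse; MEP
amplitudes are `baseline + gain * accumulator(t_pulse) + N(0, sd)` per
muscle role; epochs are `gain * summed trace + AR(1) noise` censored at the
response, with a pure-noise pre-stimulus baseline.  Observation-model
defaults are stand-ins chosen for realism, not estimates: MEP noise SD 1.0
on the z-scale (trial-level MEP variability is at least as large as the
decision-related modulation), epoch gain 25 µV per evidence unit with noise
SD 10 µV and AR(1) 0.9 (EEG epochs are strongly autocorrelated), a 5%
uniform participant jitter on `T_er` only (the study pooled trials), and a
0.3565 dropout rate for MEP attrition matching the study's reported loss.
Because every trial stores its seed, the generators re-derive exact
accumulator states for any subset of trials, so noiseless configurations
reproduce model predictions to the float — useful for end-to-end identity
tests, but note what passing them does not show: synthetic MEPs/epochs are
linear, Gaussian/AR(1) readouts of the true decision variable, with none of
the nonstationarity, artifacts or electrode/muscle confounds of real data.

## Problem sizes and determinism

Default sizes follow the original design where stated (10,000 simulated
trials for fitting objectives, 20,000 for MEP prediction, 1999 bootstrap/
permutation iterations); validation suites run reduced sizes chosen once
for desk-scale runtimes (e.g. 200-repetition type-I simulations at 99
permutations, 199 bootstraps) — calibration conclusions are unchanged by
these sizes, only their Monte-Carlo resolution.  Every stochastic stage
takes an explicit seed; per-trial seed streams make common-random-number
comparisons exact, and all seeds derived internally stay below 2^31.

## Known limitations

* Urgency-gated and leaky-integration variants are out of scope; the
  forced-excursion re-expression is a time-invariant gain change, related
  to but distinct from urgency.
* No within- or across-trial drift variability.
* The incorrect-response drifts are weakly identified at realistic values
  (see recovery above).
* Post-response accumulator behavior is undefined; all averages censor at
  the response.
* Group-level (pooled) fitting is the default, as in the original design;
  per-participant fitting works but has no hierarchical shrinkage.
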