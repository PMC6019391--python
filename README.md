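# satrace

Race-model analysis of the speed–accuracy tradeoff (SAT): a rectified
two-accumulator race model of two-choice perceptual decisions, quantile
maximum probability (QMPE) fitting of its speed/accuracy variants, the
forced-excursion re-parameterization, and simulation-based prediction of two
neurodynamic signals — a smoothed motor-evoked-potential (MEP) difference
signal indexing corticospinal excitability, and a centroparietal-positivity
(CPP) style ERP — together with the permutation and bootstrap statistics
needed to compare model variants against such signals.

**Who it is for.** Researchers in decision neuroscience who want to test
*how* the brain implements speed/accuracy instructions: as a change in the
baseline-to-boundary excursion (the classic account), or as a mathematically
equivalent global gain change spread across drift, noise and start-point
parameters (the forced-excursion account), which makes different predictions
for neural accumulation profiles even though the behavioral fits are
identical.

## The model

Evidence for the correct and incorrect response accumulates independently:

    dx = v dt + sigma sqrt(dt) N(0,1),   x <- max(x + dx, 0)

with start points `Uniform(0, S_z)`, absorbing boundary `A` (accuracy
boundary pinned to 1), and uniform non-decision time `T_er ± S_Ter/2`.
Difficulty moves the drift rates `v_correct`, `v_incorrect`; instruction
moves the boundary (and, in the best-supported variant, the start-point
range).  Because race models are invariant to a common scaling of the
evidence-unit parameters, a fitted model can be re-expressed with *equal*
boundaries by dividing every speed-condition evidence parameter by the
fitted speed boundary — same behavior, trial for trial, but very different
implied neural activity.  `satrace` verifies that equivalence exactly
(common random numbers, identical choices and RTs) rather than
approximately.

## Worked example

Re-express the published TMS-experiment estimates under the forced-excursion
constraint, and check the two variants are behaviorally identical:

```python
>>> import satrace
>>> forced = satrace.to_forced_excursion(satrace.TMS_STUDY_PARAMS, "speed")
>>> round(forced.cell("speed", "easy").start_range, 3)
0.586
>>> round(forced.cell("speed", "easy").drift_correct, 3)
1.433
>>> design = [("speed", "easy", 1000)]
>>> sim = satrace.SimConfig(dt=0.01, max_time=5.0, n_trials=1000, seed=1)
>>> a = satrace.simulate_dataset(satrace.TMS_STUDY_PARAMS, design, sim)
>>> b = satrace.simulate_dataset(forced, design, sim)
>>> (a["choice"] == b["choice"]).all(), float((a["rt"] - b["rt"]).abs().max())
(True, 0.0)
```

The start-point range 0.523 divided by the speed boundary 0.893 gives 0.586;
drifts rescale the same way (1.280 → 1.433); and under shared seeds the
free and forced parameter sets produce the same choice and the same RT on
every one of the 1000 trials — the equivalence is exact, not statistical.

From the shell, the same pipeline runs as:

```bash
satrace simulate --params tms --n-trials 2000 --seed 7 --out trials.csv
satrace fit --data trials.csv --model model2 --seed 7 --out fit.json
satrace rescale --fit fit.json --out forced.json
satrace synth --preset tms --seed 7 --out study/   # full synthetic study
```

## Layout

| module | contents |
| --- | --- |
| `satrace.params` | parameter containers, validation, forced-excursion re-expression, published estimates |
| `satrace.simulate` | trial-level simulation kernels (per-trial seed streams) |
| `satrace.fitting` | quantile bins, QMPE objective, differential-evolution fit, AIC/BIC/weights |
| `satrace.mep` | z-scoring, Gaussian-kernel signal, BCa bands, slope/cluster permutation tests, MEP predictions |
| `satrace.cpp` | summed-accumulator (CPP-style) predictions, censored averaging, scale/T_e optimization |
| `satrace.compare` | signal MSE, amplitude scaling, MSE-based AIC, bootstrap of the MSE difference |
| `satrace.pipelines` | end-to-end free-vs-forced MEP comparison used by the bootstrap |
| `satrace.synth` | synthetic studies with ground-truth manifests |
| `satrace.io`, `satrace.cli` | CSV/JSON/YAML schemas and the `satrace` command |

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
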