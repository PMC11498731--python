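# tigermove

Behavioural segmentation and habitat-selection analysis of hourly GPS
telemetry from dispersing large carnivores, built around two models that
movement ecologists routinely combine:

1. **A 2-state hidden Markov movement model (HMM).** Each hourly step is
   summarized by its length `s_t` (m) and turning angle `θ_t` (rad).
   Step lengths follow a zero-inflated gamma distribution per state
   (point mass `π0_k` at exactly 0, gamma with mean `μ_k` and sd `σ_k`
   otherwise); turning angles follow a wrapped Cauchy with mean `ϑ_k`
   and concentration `ρ_k`. The two states capture *encamping* (short,
   undirected steps) and *travelling* (long, directed steps). The
   state-switching probabilities are logistic in standardized
   environmental covariates at the step's end point,

       γ_kj(z) = logistic(β0_kj + β_kj · z),

   with distance-to-village, distance-to-water and NDVI as covariates.
   Fitting maximizes the forward log-likelihood; behaviour is decoded
   with the Viterbi algorithm, and long-run behaviour along a covariate
   gradient is summarized by the stationary probabilities
   `δ_enc(z) = γ_21/(γ_12 + γ_21)` with delta-method CIs.

2. **An integrated step-selection function (iSSF).** Every used step is
   matched with 15 random steps drawn from a tentative movement kernel
   (gamma lengths × von Mises turns around the previous bearing), and
   habitat preference is estimated by conditional logistic regression

       L(β) = Π_i exp(β·x_used,i) / Σ_j exp(β·x_ij),

   with movement-adjustment terms (step, log step, cos turn, optionally
   × day/night). Effect sizes are reported as relative selection
   strength, `RSS(x1, x2) = exp(β·(x1 − x2))`, with Wald intervals.

Supporting stages: hourly-lattice regularization, missing-fix imputation
with a continuous-time correlated random walk (integrated
Ornstein–Uhlenbeck velocity, Kalman-filter ML + RTS smoothing), raster
covariate preparation (built-up→village thresholding, Euclidean distance
transforms, 6→3 forest-class merging, 100 m resampling), displacement
summaries with Mann–Whitney day/night comparisons, and a synthetic-data
generator that produces landscapes and trajectories with exactly the
statistical structure the analysis assumes — so the whole chain is
testable without any field data.

## Worked example

Generate a synthetic scenario (raster stack, two switching-walk tracks
with 10% missing fixes, run config) and run the full pipeline:

```bash
tigermove simulate --seed 7 --outdir scenario --n-steps 800 --n-animals 2
tigermove run-all --config scenario/run.yaml
```

`scenario/out/` then holds the analysis tables. On this seed,
`hmm_emissions.csv` reads

```
state,mean_step_m,mean_step_lo,mean_step_hi,sd_step_m,...,angle_mean,angle_concentration
encamping,94.65086348,90.26851657,99.24596412,47.24417112,...,2.948454897,0.2552255126
travelling,678.8518302,623.1300874,739.556341,901.6090796,...,0.02085883789,0.7236582722
```

i.e. the fitted encamping state takes ~95 m steps (95% CI 90–99) with
turn-back angles (mean ≈ π, concentration 0.26) and the travelling state
~679 m steps (CI 623–740) with directed angles (mean ≈ 0, concentration
0.72), recovering the generator's 100 m / 700 m truth from imputed,
noisy tracks. `state_budget.csv` reports the Viterbi activity budget
(here 35% encamping / 65% travelling),
`stationary_*.csv` the stationary state probabilities along
each covariate with pointwise CIs, `issf_models.csv` the AIC ranking of
the three candidate selection models, `issf_coefficients.csv` the
conditional-logistic coefficient table (Factor, Coefficient, SE,
P value), and `rss.csv` relative selection strengths for configured
contrasts (e.g. habitat 5 km vs 500 m from a village). `manifest.json`
records config, seeds and input checksums; re-running a config
reproduces every table byte for byte.

The same machinery is available as a library:

```python
from tigermove import simulate, hmm, trajectory as tj

cfg = simulate.SimConfig(seed=7)
stack = simulate.make_landscape(cfg)
track, states = simulate.simulate_hmm_track(cfg, stack)
steps = tj.assign_diel(tj.compute_steps(track))
for c in cfg.covariates:
    steps[c] = track.attrs["step_covariates"][c].to_numpy()
fit = hmm.fit_hmm(steps, covariates=cfg.covariates)
print(fit.emission_table())
```

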