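# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Track preparation

Fixes are snapped to an hourly lattice anchored at the first fix
(nearest slot, tolerance ±5 min; off-lattice fixes are dropped with a
warning, duplicate slots keep the earliest). Gaps longer than `max_gap`
(default 24 h) split a track into independent *bursts*: imputing a full
day of carnivore movement would dominate the step statistics with model
output, so long gaps are never bridged. Shorter gaps become explicit
missing slots.

Missing slots are predicted with a continuous-time correlated random
walk: per coordinate, velocity is an Ornstein–Uhlenbeck process with
autocorrelation rate `beta` (1/h) and noise scale `sigma` (m·h^-1.5),
position is its integral, and fixes are observed with isotropic Gaussian
error `obs_sd` (m). The state-space model is discretized *exactly* over
each inter-fix interval (no Euler error), the likelihood is evaluated by
the Kalman filter, and `(beta, sigma[, obs_sd])` are estimated by
Nelder–Mead on log scales. Imputed positions are Rauch–Tung–Striebel
smoother means. The prior at each burst start is N(first observed
position, 10^6 m²) for position and the stationary N(0, sigma²/(2·beta))
for velocity; the first observation still contributes to the
likelihood. This prior is part of the model definition and the tests'
joint-Gaussian oracle uses the same one.

Steps are Euclidean displacements between consecutive fixes of a burst;
on the hourly lattice a step in metres is also a speed in m/h. Turning
angles are signed (counter-clockwise positive), wrapped to (−π, π], and
*missing* — not zero — at burst starts and next to zero-length steps.
Day/night uses fixed local clock bounds (06:00–18:00 by default); a
sunrise/sunset mode is deliberately out of scope. The Mann–Whitney U
comparison uses midranks, a tie-corrected normal Z with continuity
correction, and an exact enumeration p-value when min(n) ≤ 8 and the
pooled sample is tie-free.

## Hidden Markov movement model

Emissions per state k: step lengths are zero-inflated gamma — point mass
`pi0_k` at exactly 0 (a fix pair must coincide to the millimetre; no
jitter threshold is applied by default) plus
`(1 − pi0_k)·Gamma(shape = mu_k²/sigma_k², rate = mu_k/sigma_k²)` — and
turning angles are wrapped Cauchy`(vartheta_k, rho_k)`. Missing angles
contribute only the step-length term. When the data contain no exact
zeros the zero-mass is reported as 0 rather than as an arbitrary
boundary estimate.

Transitions: the 2×2 matrix at step t has off-diagonals
`logistic(b0 + b·z_t)` where `z_t` are standardized covariates at the
step's end point (one-lag convention; the synthetic generator uses the
matching convention — the state for the next step is drawn from Γ
evaluated at the current location). Each burst is initialized at the
stationary distribution of Γ at its first step. Bursts and animals
contribute additively to one pooled likelihood; per-animal fits are a
matter of subsetting the step table.

Fitting: L-BFGS-B on working parameters (log mu, log sigma, logit pi0,
unconstrained angle mean, logit rho, raw transition coefficients) with
the forward recursion compiled by numba. Default initial emission
values are the conventional encamping/travelling starting points for
hourly large-carnivore telemetry — means 100/700 m, sds 50/1000 m,
zero-masses 0.01/0.05, concentrations 0.3/0.7 — with angle means
*estimated*, initialized at 0. The multi-start schedule is: (1) the
initial values; (2) the same values with the encamping angle mean at π
("turn-back" encamping); (3+) seed-controlled jitter, with angle means
redrawn uniformly on the circle. Start (2) exists because the
(vartheta, rho) surface has a saddle at rho = 0: from vartheta = 0, an
optimizer facing turn-back data collapses rho to 0 (where vartheta
becomes unidentifiable) instead of rotating the mean, and — because the
angle term couples to the state assignment — this also inflates the
travelling step mean by about 2%, enough to break confidence-interval
calibration. After the best start, L-BFGS-B is re-run from its own
optimum up to three times (restarting resets the curvature memory and
tightens convergence on weakly identified directions). States are
relabelled so state 0 has the smaller fitted step mean; Viterbi ties
break toward the lower state index.

Uncertainty: the working-scale covariance is the inverse of a
central-difference Hessian; natural-scale CIs transform the working
interval (e.g. `exp(log mu ± 1.96·se)`). Stationary-curve CIs use the
delta method on `logit(delta_enc)` over the transition-coefficient
covariance block.

## Integrated step-selection function

The tentative kernel is a gamma ML fit to positive used step lengths and
a von Mises ML fit to defined turning angles. Each usable step (one with
a defined previous bearing) becomes a stratum: the used step plus
`n_random = 15` candidates drawn from the kernel around the previous
bearing, with per-stratum RNG substreams keyed by (seed, step index) so
stratum sets are reproducible regardless of processing order. Candidates
leaving the landscape are dropped (counted); a stratum survives with ≥ 2
rows and the used row is never dropped.

The estimator maximizes the stratum-conditional log-likelihood by
Newton–Raphson with step-halving (vectorized over strata via segmented
reductions); SEs come from the observed information and p-values are
two-sided Wald. Divergence guards (|β| > 50 or near-perfect per-stratum
prediction) convert complete separation into an explicit error. The
statsmodels conditional-logit implementation serves as an independent
cross-check in the test suite, never as the estimator.

Model terms are named strings; `col:day` / `col:night` multiply a column
by the diel indicator. The three default candidate models are (1)
habitat only, (2) habitat + movement adjustments (step, log step, cos
turn), (3) habitat × diel + movement × diel; "turning angle" enters as
cos(θ), the standard kernel-correction transform. The forest one-hot
reference category is non-forest; water cells in the 6-class product map
to non-forest in the 3-class scheme (neither merge rule claims them).
Continuous habitat covariates are standardized across all rows of the
strata table (used + available) and the constants are stored with the
fit so RSS contrasts can be specified in natural units.

## Landscape

All layers share one planar grid in projected metres; cell (i, j) is
centred at `(x0 + (j+0.5)·cell, y0 + (i+0.5)·cell)`. Continuous layers
are sampled bilinearly, categorical layers nearest-neighbour, so cell
centres are exact for every layer and categorical sampling can never
invent categories. Distance layers are cell-centre to cell-centre
(edge geometry below the 100 m resolution is unrecoverable anyway) and
are exactly 0 on source cells. Rasters are written as TIFF with the grid
(origin, cell size, shape) stored as JSON in the image-description tag;
layer roles are declared in a YAML file, and any grid mismatch between
layers is a hard error naming both grids.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not tiger biology: NDVI is a smoothed Gaussian random field rescaled to
[−0.1, 0.6]; villages are dilated random cells (built-up fraction 0.9 on
patches over low background noise, so the 0.75 threshold recovers them
exactly); water is a rasterized random polyline; the 6 forest classes
are NDVI thresholds plus the water class. The default landscape is
400×400 cells at 100 m (a 40 km box, 25 villages) — dispersal-scale
walkers with 700 m mean, 1000 m sd steps cross a 15 km box in ~20 steps,
so a small domain turns boundary handling into the dominant signal.

The switching walk draws the next state from Γ(z) at the walker's
current location, then the step and turn from the state's distributions.
Boundary handling is specular reflection by default (position and
heading folded back; affected step indices are logged, because a
reflected step's realized displacement is shorter than its drawn
length). For parameter-recovery experiments the generator offers a
periodic mode — an unbounded walk reading covariates from the landscape
tiled periodically — under which realized steps follow the emission
model exactly; with reflection even on a 40 km box the travelling-mean
truncation (~2%, comparable to the ML standard error at 10⁴ steps) would
degrade nominal CI coverage for reasons that have nothing to do with the
estimator. Recovery runs standardize covariates with the *landscape*
constants used during generation (passed explicitly); the pipeline
default — standardizing within the dataset — is an affine
reparametrization that leaves the likelihood invariant but changes the
slope scale, so recovery comparisons must share constants.

The selection walk scores candidate steps by `exp(β·x)` and picks one by
softmax. The number of generative candidates is C = 400: the finite-C
softmax approximates the continuous selection density with O(1/C)
coefficient attenuation, and at C = 50 the measured NDVI attenuation
(−0.05, ~0.7 standard errors at 2000 strata) was large enough to pull
nominal-95% interval coverage to ~88%; at C = 400 the residual error is
well below a quarter standard error. Recovery experiments draw their
random steps from the *generating* kernel and fit the habitat-only
model, which is then correctly specified; the pipeline default (kernel
refit from used steps + movement-adjustment terms) is the practical
configuration for real data.

Everything is deterministic under the master seed (numpy PCG64 via
SeedSequence spawn keys, one named stream per purpose).

## What the tests show — and what they do not

Exact checks (forward recursion vs enumeration over all 2^T sequences,
Viterbi vs exhaustive argmax, Kalman likelihood vs the joint Gaussian
density, stationary distribution vs the eigen-solution, conditional
logit vs dense grid search, Mann–Whitney vs full enumeration) validate
the algorithms. Simulation studies — 50 replicates of 5 tracks × 2000
steps for the HMM, 50 replicates of 2000 strata for the iSSF — validate
estimator calibration *under the generating model*: correct emission
families, Markov switching, softmax selection, no GPS error in the
switching walk, habitat layers without temporal change. Real telemetry
violates several of these (fix-success bias, temporally varying NDVI,
behaviour beyond two states), so passing tests demonstrate that the
implementation is faithful, not that the model is true of any animal.

Problem sizes in tests and the acceptance script (tracks of 10⁴ steps
per replicate, 12–50 replicates) are chosen so recovery standard errors
sit well inside the tolerances being asserted.

## Known limitations

- The CTCRW is fitted per animal on observed fixes and assumes a single
  (beta, sigma) regime; behaviourally heterogeneous gaps inherit one
  smoothing scale.
- Reflection at the landscape edge shortens realized displacements of
  boundary-hitting steps; interior covariate exposure is essentially
  unbiased, but edge-adjacent analyses should use a larger domain.
- The K-state machinery is written generically but only K = 2 is
  exercised and supported; model selection over K is out of scope.
- Stationary-curve CIs are pointwise delta-method intervals, not
  simultaneous bands.
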