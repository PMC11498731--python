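"""Synthetic landscapes and trajectories for end-to-end testing.

The generator mirrors the statistical structure the analysis assumes —
not tiger biology.  A landscape is a smoothed Gaussian random field
(NDVI), dilated random village patches (built-up fraction), a rasterized
random polyline (water) and NDVI-thresholded forest classes, on a 100 m
planar grid.  Trajectories come in two flavours:

* :func:`simulate_hmm_track` — a 2-state switching walk: the state
  evolves by the covariate-dependent transition matrix evaluated at the
  current location; given the state, the step is zero-inflated gamma and
  the turn wrapped Cauchy.  True states are returned for recovery tests.
* :func:`simulate_ssf_track` — habitat-biased step selection: at each
  step ``n_candidates`` proposals are drawn from the true movement
  kernel and one is selected with probability proportional to
  ``exp(beta . x)``; an iSSF fit should recover ``beta``.

Default truth values for the switching walk (step means 100/700 m, sds
50/1000 m, zero-mass 0.01/0.05, turn concentrations 0.3/0.7) are the
conventional encamping/travelling starting values for hourly large-
carnivore telemetry; the encamping turn mean is pi (turn-backs), the
travelling mean 0 (directed).  Transition intercepts put the long-run
budget near 35% encamping / 65% travelling, and by default the distance-
to-village covariate pushes animals toward travelling far from villages.

Everything is deterministic under the master seed (numpy Generator /
PCG64 with named spawn keys).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from tigermove import landscape as ls
from tigermove.hmm import EmissionParams
from tigermove.issf import MovementKernel


@dataclass
class SimConfig:
    seed: int = 0
    nrow: int = 400
    ncol: int = 400
    cell: float = 100.0
    n_villages: int = 25
    # HMM truth
    hmm_emissions: EmissionParams = field(default_factory=lambda: EmissionParams(
        mu=[100.0, 700.0], sigma=[50.0, 1000.0], zeromass=[0.01, 0.05],
        angle_mean=[math.pi, 0.0], rho=[0.3, 0.7]))
    #: rows: 0->1 and 1->0; columns: intercept, then `covariates`
    trans_beta: np.ndarray = field(default_factory=lambda: np.array(
        [[-1.7346, 0.5, 0.0, 0.0],   # encamp->travel rises with dist_village
         [-2.4423, 0.0, 0.0, 0.0]]))
    covariates: tuple[str, ...] = ("dist_village", "dist_water", "ndvi")
    # iSSF truth
    ssf_beta: dict[str, float] = field(default_factory=lambda: {
        "ndvi": 1.0, "dist_village": 0.5, "forest": 0.8, "open_forest": 0.4})
    ssf_kernel: MovementKernel = field(default_factory=lambda: MovementKernel(
        shape=2.0, rate=0.005, vm_mean=0.0, kappa=1.0))
    n_candidates: int = 400
    # track shape
    n_steps: int = 2000
    n_animals: int = 5
    missing_rate: float = 0.1

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=tuple(key)))


def make_landscape(cfg: SimConfig) -> ls.LandscapeStack:
    """Deterministic synthetic covariate stack (see module docstring)."""
    if cfg.nrow < 50 or cfg.ncol < 50:
        raise ValueError("landscape must be at least 50x50 cells")
    grid = ls.Grid(0.0, 0.0, cfg.cell, cfg.nrow, cfg.ncol)
    stack = ls.LandscapeStack(grid)

    # NDVI: smoothed white noise rescaled to [-0.1, 0.6]
    rng = cfg.rng(0)
    field_ = ndimage.gaussian_filter(rng.standard_normal((cfg.nrow, cfg.ncol)), sigma=6.0)
    lo, hi = field_.min(), field_.max()
    ndvi = -0.1 + (field_ - lo) / (hi - lo) * 0.7
    stack.add("ndvi", ndvi)

    # villages: random cells dilated to patches -> built-up fraction
    rng = cfg.rng(1)
    mask = np.zeros((cfg.nrow, cfg.ncol), dtype=bool)
    ii = rng.integers(5, cfg.nrow - 5, size=cfg.n_villages)
    jj = rng.integers(5, cfg.ncol - 5, size=cfg.n_villages)
    mask[ii, jj] = True
    mask = ndimage.binary_dilation(mask, iterations=2)
    builtup = np.where(mask, 0.9, 0.0) + rng.uniform(0.0, 0.3, size=mask.shape) * ~mask
    stack.add("builtup_fraction", np.clip(builtup, 0.0, 1.0))

    # water: random polyline crossing the grid, rasterized on cells
    rng = cfg.rng(2)
    water = np.zeros((cfg.nrow, cfg.ncol), dtype=np.uint8)
    j = int(rng.integers(cfg.ncol // 4, 3 * cfg.ncol // 4))
    i = 0
    while i < cfg.nrow:
        i2 = min(cfg.nrow - 1, i + int(rng.integers(5, 15)))
        j2 = int(np.clip(j + int(rng.integers(-8, 9)), 1, cfg.ncol - 2))
        n = max(abs(i2 - i), abs(j2 - j)) + 1
        ri = np.round(np.linspace(i, i2, n)).astype(int)
        rj = np.round(np.linspace(j, j2, n)).astype(int)
        water[ri, rj] = 1
        if i2 == cfg.nrow - 1:
            break
        i, j = i2, j2
    stack.add("water_mask", water)

    # forest cover: NDVI-thresholded 6-class product, water class on the river
    f6 = np.full((cfg.nrow, cfg.ncol), ls.FOREST6_NONFOREST, dtype=np.uint8)
    f6[ndvi > 0.15] = ls.FOREST6_SHRUB
    f6[ndvi > 0.25] = ls.FOREST6_OPEN
    f6[ndvi > 0.35] = ls.FOREST6_MOD_DENSE
    f6[ndvi > 0.45] = ls.FOREST6_DENSE
    f6[water.astype(bool)] = ls.FOREST6_WATER
    stack.add("forest6", f6)

    stack.derive()
    return stack


def landscape_standardizer(stack: ls.LandscapeStack,
                           roles: tuple[str, ...] = ("dist_village", "dist_water",
                                                     "ndvi")) -> ls.Standardizer:
    """Whole-landscape standardization constants (the generative truth scale)."""
    tab = {r: stack[r].ravel() for r in roles}
    return ls.Standardizer.fit(tab, roles)


class _FastSampler:
    """Vectorized layer sampling on precomputed arrays (no DataFrame overhead).

    Bilinear for continuous layers, nearest for categorical; points are
    clamped to the grid (matching ``mode='nearest'`` edge handling of the
    landscape module's sampler at interior-adjacent points).
    """

    def __init__(self, stack: ls.LandscapeStack, continuous: tuple[str, ...],
                 categorical: tuple[str, ...] = ()):
        self.grid = stack.grid
        self.cont = np.stack([np.asarray(stack[r], dtype=float) for r in continuous]) \
            if continuous else None
        self.cat = np.stack([np.asarray(stack[r], dtype=float) for r in categorical]) \
            if categorical else None
        self.cont_names = continuous
        self.cat_names = categorical

    def sample(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Returns (continuous (nc, n), categorical (nk, n)) layer values."""
        g = self.grid
        fi = np.clip(np.atleast_1d(np.asarray(y, dtype=float) - g.y0) / g.cell - 0.5,
                     0, g.nrow - 1)
        fj = np.clip(np.atleast_1d(np.asarray(x, dtype=float) - g.x0) / g.cell - 0.5,
                     0, g.ncol - 1)
        cont = cat = None
        if self.cont is not None:
            i0 = np.minimum(fi.astype(int), g.nrow - 2)
            j0 = np.minimum(fj.astype(int), g.ncol - 2)
            di, dj = fi - i0, fj - j0
            c = self.cont
            cont = (c[:, i0, j0] * (1 - di) * (1 - dj) + c[:, i0, j0 + 1] * (1 - di) * dj
                    + c[:, i0 + 1, j0] * di * (1 - dj) + c[:, i0 + 1, j0 + 1] * di * dj)
        if self.cat is not None:
            cat = self.cat[:, np.round(fi).astype(int), np.round(fj).astype(int)]
        return cont, cat


def _sample_wrapped_cauchy(rng, mean: float, rho: float, size=None):
    u = rng.uniform(0.0, 1.0, size=size)
    if rho == 0:
        return mean + 2.0 * np.pi * (u - 0.5)
    return mean + 2.0 * np.arctan((1.0 - rho) / (1.0 + rho)
                                  * np.tan(np.pi * (u - 0.5)))


def _reflect(v: float, lo: float, hi: float) -> tuple[float, bool]:
    reflected = False
    while v < lo or v > hi:
        reflected = True
        if v < lo:
            v = 2 * lo - v
        else:
            v = 2 * hi - v
    return v, reflected


def _times(n: int, start: str = "2016-01-01T00:00:00+05:30") -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n, freq="h")


def simulate_hmm_track(cfg: SimConfig, stack: ls.LandscapeStack,
                       animal: str = "t1", stream: int = 10,
                       std: ls.Standardizer | None = None,
                       boundary: str = "reflect",
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """One 2-state switching track of ``cfg.n_steps`` hourly steps.

    Returns (track DataFrame, true state per step).  The track has
    ``n_steps + 1`` fixes; true state k of step t generated the move from
    fix t to fix t+1.

    ``boundary`` — ``"reflect"``: specular reflection at the landscape
    edge (track stays on the landscape; the reflected steps' realized
    displacements are shortened, and their indices are logged in
    ``track.attrs["reflected_steps"]``); ``"periodic"``: the walk is
    unbounded and covariates are read from the landscape tiled
    periodically, so realized steps follow the emission model exactly
    (used by parameter-recovery checks).  The raw covariate values used
    at each step's end point are stored in
    ``track.attrs["step_covariates"]``.
    """
    if boundary not in ("reflect", "periodic"):
        raise ValueError("boundary must be 'reflect' or 'periodic'")
    rng = cfg.rng(stream)
    em = cfg.hmm_emissions
    std = std or landscape_standardizer(stack, cfg.covariates)
    xmin, ymin, xmax, ymax = stack.grid.extent
    x = 0.5 * (xmin + xmax)
    y = 0.5 * (ymin + ymax)

    sampler = _FastSampler(stack, cfg.covariates)
    mu_z = np.array([std.means[c] for c in cfg.covariates])
    sd_z = np.array([std.sds[c] for c in cfg.covariates])

    def raw_at(px, py):
        if boundary == "periodic":
            px = xmin + (px - xmin) % (xmax - xmin)
            py = ymin + (py - ymin) % (ymax - ymin)
        raw, _ = sampler.sample(px, py)
        return raw[:, 0]

    # initial state from the stationary law at the start point
    from scipy.special import expit
    z = (raw_at(x, y) - mu_z) / sd_z
    xv = np.concatenate([[1.0], z])
    g01 = expit(cfg.trans_beta[0] @ xv)
    g10 = expit(cfg.trans_beta[1] @ xv)
    state = int(rng.uniform() < g01 / (g01 + g10))

    xs, ys = [x], [y]
    states = np.zeros(cfg.n_steps, dtype=int)
    raws = np.zeros((cfg.n_steps, len(cfg.covariates)))
    heading = rng.uniform(-np.pi, np.pi)
    reflected = []
    for t in range(cfg.n_steps):
        states[t] = state
        if rng.uniform() < em.zeromass[state]:
            step = 0.0
        else:
            shape = em.mu[state] ** 2 / em.sigma[state] ** 2
            step = rng.gamma(shape, em.sigma[state] ** 2 / em.mu[state])
        turn = float(_sample_wrapped_cauchy(rng, em.angle_mean[state], em.rho[state]))
        if step > 0:
            heading = math.atan2(math.sin(heading + turn), math.cos(heading + turn))
        x2 = x + step * math.cos(heading)
        y2 = y + step * math.sin(heading)
        if boundary == "reflect":
            # specular reflection: fold position and heading back into the box
            x2, rx = _reflect(x2, xmin + 1.0, xmax - 1.0)
            y2, ry = _reflect(y2, ymin + 1.0, ymax - 1.0)
            if rx:
                heading = math.atan2(math.sin(heading), -math.cos(heading))
            if ry:
                heading = math.atan2(-math.sin(heading), math.cos(heading))
            if rx or ry:
                reflected.append(t)
        x, y = x2, y2
        xs.append(x)
        ys.append(y)
        # next state from Gamma(z) at the new location
        raw = raw_at(x, y)
        raws[t] = raw
        z = (raw - mu_z) / sd_z
        xv = np.concatenate([[1.0], z])
        p_switch = expit(cfg.trans_beta[state] @ xv)
        if rng.uniform() < p_switch:
            state = 1 - state
    track = pd.DataFrame({"animal": animal, "time": _times(len(xs)),
                          "x": xs, "y": ys, "source": "observed", "burst": 0})
    track.attrs["reflected_steps"] = reflected
    track.attrs["step_covariates"] = pd.DataFrame(raws, columns=list(cfg.covariates))
    return track, states


def simulate_ssf_track(cfg: SimConfig, stack: ls.LandscapeStack,
                       animal: str = "t1", stream: int = 20,
                       std: ls.Standardizer | None = None) -> pd.DataFrame:
    """Habitat-biased track: candidates from the true kernel, softmax selection."""
    rng = cfg.rng(stream)
    k = cfg.ssf_kernel
    std = std or landscape_standardizer(stack, ("ndvi", "dist_village", "dist_water"))
    beta_terms = sorted(cfg.ssf_beta)
    cont_terms = tuple(t for t in beta_terms if t in std.means)
    forest_terms = tuple(t for t in beta_terms if t in ("forest", "open_forest"))
    sampler = _FastSampler(stack, cont_terms,
                           ("forest3",) if forest_terms else ())
    b_cont = np.array([cfg.ssf_beta[t] for t in cont_terms])
    mu_c = np.array([std.means[t] for t in cont_terms])
    sd_c = np.array([std.sds[t] for t in cont_terms])
    xmin, ymin, xmax, ymax = stack.grid.extent
    x = 0.5 * (xmin + xmax)
    y = 0.5 * (ymin + ymax)
    heading = rng.uniform(-np.pi, np.pi)
    xs, ys = [x], [y]
    n_resample = 0
    for _ in range(cfg.n_steps):
        while True:
            lens = rng.gamma(k.shape, 1.0 / k.rate, size=cfg.n_candidates)
            turns = rng.vonmises(k.vm_mean, k.kappa, size=cfg.n_candidates)
            heads = heading + turns
            cx = x + lens * np.cos(heads)
            cy = y + lens * np.sin(heads)
            ok = stack.grid.contains(cx, cy)
            if ok.any():
                break
            n_resample += 1
        cx, cy, lens, heads = cx[ok], cy[ok], lens[ok], heads[ok]
        cont, cat = sampler.sample(cx, cy)
        w = np.zeros(cx.size)
        if cont_terms:
            w += b_cont @ ((cont - mu_c[:, None]) / sd_c[:, None])
        if forest_terms:
            f3 = cat[0]
            if "forest" in cfg.ssf_beta:
                w += cfg.ssf_beta["forest"] * (f3 == ls.FOREST3_FOREST)
            if "open_forest" in cfg.ssf_beta:
                w += cfg.ssf_beta["open_forest"] * (f3 == ls.FOREST3_OPENFOREST)
        w = np.exp(w - w.max())
        w /= w.sum()
        pick = rng.choice(w.size, p=w)
        x, y, heading = float(cx[pick]), float(cy[pick]), float(heads[pick])
        xs.append(x)
        ys.append(y)
    track = pd.DataFrame({"animal": animal, "time": _times(len(xs)),
                          "x": xs, "y": ys, "source": "observed", "burst": 0})
    track.attrs["n_resampled"] = n_resample
    return track


def inject_missingness(track: pd.DataFrame, rate: float,
                       rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Drop interior fixes independently with probability ``rate``; endpoints stay."""
    if not 0 <= rate < 0.5:
        raise ValueError("missing rate must lie in [0, 0.5)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(track)
    drop = rng.uniform(size=n) < rate
    drop[0] = drop[-1] = False
    return track[~drop].reset_index(drop=True)


def hmm_recovery_study(seed: int = 0, n_replicates: int = 50, n_animals: int = 5,
                       n_steps: int = 2000,
                       slope_into_travel: float = 0.5) -> "pd.DataFrame":
    """Simulation-recovery study for the 2-state model.

    Each replicate simulates ``n_animals`` tracks of ``n_steps`` hourly
    steps from the default emission truth (step means 100/700 m) with one
    covariate-driven transition (distance-to-village pushes encamping ->
    travelling), pools them, refits the model and records the fitted step
    means with their 95% CIs.  Tracks use the periodic boundary so the
    realized steps follow the emission model exactly.

    Returns one row per replicate with columns ``mu_enc``, ``mu_trav``,
    their CI bounds, coverage flags and the Viterbi decoding accuracy.
    """
    from tigermove import hmm, trajectory as tj

    cfg = SimConfig(seed=seed % (2 ** 31), covariates=("dist_village",),
                    trans_beta=np.array([[-1.7346, slope_into_travel],
                                         [-2.4423, 0.0]]),
                    n_steps=n_steps)
    stack = make_landscape(cfg)
    std = landscape_standardizer(stack, ("dist_village",))
    truth_mu = cfg.hmm_emissions.mu
    rows = []
    for rep in range(n_replicates):
        parts, all_states = [], []
        for a in range(n_animals):
            track, states = simulate_hmm_track(
                cfg, stack, animal=f"t{a + 1}", stream=1000 + rep * n_animals + a,
                std=std, boundary="periodic")
            st = tj.compute_steps(track)
            st["dist_village"] = track.attrs["step_covariates"]["dist_village"].to_numpy()
            parts.append(st)
            all_states.append(states)
        steps = pd.concat(parts, ignore_index=True)
        states = np.concatenate(all_states)
        fit = hmm.fit_hmm(steps, covariates=("dist_village",), standardizer=std,
                          n_starts=2, seed=rep)
        tab = fit.emission_table()
        decoded = hmm.viterbi(steps, fit)
        rows.append({
            "replicate": rep,
            "mu_enc": tab["mean_step_m"][0], "mu_trav": tab["mean_step_m"][1],
            "mu_enc_lo": tab["mean_step_lo"][0], "mu_enc_hi": tab["mean_step_hi"][0],
            "mu_trav_lo": tab["mean_step_lo"][1], "mu_trav_hi": tab["mean_step_hi"][1],
            "enc_covered": bool(tab["mean_step_lo"][0] <= truth_mu[0]
                                <= tab["mean_step_hi"][0]),
            "trav_covered": bool(tab["mean_step_lo"][1] <= truth_mu[1]
                                 <= tab["mean_step_hi"][1]),
            "decode_accuracy": float((decoded == states).mean()),
            "budget_travelling": float((decoded == 1).mean()),
        })
    return pd.DataFrame(rows)


def ssf_recovery_study(seed: int = 0, n_replicates: int = 50,
                       n_strata: int = 2000) -> "pd.DataFrame":
    """Simulation-recovery study for the step-selection estimator.

    Each replicate simulates one habitat-selecting track (true softmax
    selection over 50 kernel candidates), builds strata with 15 random
    steps drawn from the generating kernel and refits the habitat-only
    conditional logit.  Returns one row per replicate x coefficient with
    the estimate, Wald CI and a coverage flag against the generating
    value.
    """
    from tigermove import issf, trajectory as tj

    cfg = SimConfig(seed=seed % (2 ** 31), n_steps=n_strata)
    stack = make_landscape(cfg)
    std = landscape_standardizer(stack)
    terms = tuple(sorted(cfg.ssf_beta))
    rows = []
    for rep in range(n_replicates):
        track = simulate_ssf_track(cfg, stack, stream=3000 + rep, std=std)
        steps = tj.assign_diel(tj.compute_steps(track))
        strata, _ = issf.build_strata(steps, stack, cfg.ssf_kernel,
                                      n_random=15, seed=4000 + rep)
        fit = issf.fit_clogit(strata, terms, standardizer=std)
        for t in terms:
            lo = fit.coef[t] - 1.959963984540054 * fit.se[t]
            hi = fit.coef[t] + 1.959963984540054 * fit.se[t]
            rows.append({"replicate": rep, "term": t, "truth": cfg.ssf_beta[t],
                         "estimate": fit.coef[t], "lo": lo, "hi": hi,
                         "covered": bool(lo <= cfg.ssf_beta[t] <= hi)})
    return pd.DataFrame(rows)


def truth_manifest(cfg: SimConfig) -> dict:
    """Truth values echoed for test harnesses / run manifests (JSON-safe)."""
    em = cfg.hmm_emissions
    return {
        "seed": cfg.seed,
        "generator": "numpy PCG64 via SeedSequence spawn keys",
        "hmm": {"mu": em.mu.tolist(), "sigma": em.sigma.tolist(),
                "zeromass": em.zeromass.tolist(), "angle_mean": em.angle_mean.tolist(),
                "rho": em.rho.tolist(), "trans_beta": np.asarray(cfg.trans_beta).tolist(),
                "covariates": list(cfg.covariates)},
        "ssf": {"beta": dict(cfg.ssf_beta),
                "kernel": {"shape": cfg.ssf_kernel.shape, "rate": cfg.ssf_kernel.rate,
                           "vm_mean": cfg.ssf_kernel.vm_mean,
                           "kappa": cfg.ssf_kernel.kappa},
                "n_candidates": cfg.n_candidates},
        "landscape": {"nrow": cfg.nrow, "ncol": cfg.ncol, "cell": cfg.cell,
                      "n_villages": cfg.n_villages},
        "track": {"n_steps": cfg.n_steps, "n_animals": cfg.n_animals,
                  "missing_rate": cfg.missing_rate},
    }
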