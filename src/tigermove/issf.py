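"""Integrated step-selection function (iSSF).

Each observed ("used") step is matched with ``n_random`` candidate steps
drawn from a tentative movement kernel — gamma step lengths and von
Mises turns applied to the previous step's bearing — forming a stratum.
Habitat covariates are sampled at every candidate end point and the
used-vs-available contrast is estimated by conditional logistic
regression,

    L(beta) = prod_i  exp(beta . x_used_i) / sum_j exp(beta . x_ij),

with movement-adjustment terms (step length, log step length, cos of
the turning angle, optionally interacted with the diel period) that
correct the tentative kernel.  Relative selection strength between two
habitat vectors x1, x2 is exp(beta . (x1 - x2)) with a Wald interval.

Model terms are named strings: a bare column name, or ``col:day`` /
``col:night`` for a diel interaction (the column multiplied by the
period indicator).  The forest one-hot reference category is non-forest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tigermove import landscape as ls

N_RANDOM_DEFAULT = 15

#: the three candidate models, from habitat-only to the full
#: habitat x diel + movement x diel structure
DEFAULT_MODELS: dict[str, tuple[str, ...]] = {
    "M1_habitat": ("ndvi", "dist_village", "forest", "open_forest"),
    "M2_habitat_movement": ("ndvi", "dist_village", "forest", "open_forest",
                            "step", "log_step", "cos_ta"),
    "M3_habitat_diel": ("ndvi", "dist_village",
                        "forest:day", "open_forest:day",
                        "forest:night", "open_forest:night",
                        "cos_ta", "log_step:day", "log_step:night",
                        "step:day", "step:night", "cos_ta:night"),
}


class SsfError(ValueError):
    pass


@dataclass
class MovementKernel:
    """Tentative kernel: gamma(shape, rate) steps, von Mises(mean, kappa) turns."""

    shape: float
    rate: float
    vm_mean: float = 0.0
    kappa: float = 0.0

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0 or self.kappa < 0:
            raise SsfError("invalid kernel parameters")

    @property
    def mean_step(self) -> float:
        return self.shape / self.rate


@dataclass
class SsfFit:
    model: str
    terms: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_strata: int
    standardizer: ls.Standardizer | None = None

    @property
    def aic(self) -> float:
        return 2.0 * len(self.coef) - 2.0 * self.loglik

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"Factor": self.coef.index, "Coefficient": self.coef.values,
                             "SE": self.se.values, "P value": self.pvalues.values})


def fit_kernel(steps_df: pd.DataFrame) -> MovementKernel:
    """ML gamma fit on positive used step lengths, von Mises fit on defined turns."""
    s = steps_df["step"].to_numpy(dtype=float)
    ang = steps_df["angle"].to_numpy(dtype=float)
    ang = ang[np.isfinite(ang)]
    s = s[s > 0]
    if s.size == 0:
        raise SsfError("all step lengths are zero")
    if ang.size < 30:
        raise SsfError("need >= 30 steps with defined turning angles")
    shape, _, scale = stats.gamma.fit(s, floc=0)
    kappa, loc, _ = stats.vonmises.fit(ang, fscale=1)
    return MovementKernel(shape=shape, rate=1.0 / scale, vm_mean=float(loc),
                          kappa=float(kappa))


def generate_random_steps(x0: float, y0: float, bearing: float,
                          kernel: MovementKernel, n: int = N_RANDOM_DEFAULT,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw n candidate steps from (x0, y0) relative to the previous bearing.

    Returns (x, y, lengths, turns).
    """
    if rng is None:
        rng = np.random.default_rng()
    if not np.isfinite(bearing):
        raise SsfError("undefined bearing: previous step required")
    lengths = rng.gamma(kernel.shape, 1.0 / kernel.rate, size=n)
    turns = rng.vonmises(kernel.vm_mean, kernel.kappa, size=n) if kernel.kappa > 0 \
        else rng.uniform(-np.pi, np.pi, size=n)
    head = bearing + turns
    return x0 + lengths * np.cos(head), y0 + lengths * np.sin(head), lengths, turns


def build_strata(steps_df: pd.DataFrame, stack: ls.LandscapeStack,
                 kernel: MovementKernel, n_random: int = N_RANDOM_DEFAULT,
                 seed: int = 0,
                 habitat_roles: tuple[str, ...] = ("ndvi", "dist_village",
                                                   "dist_water", "forest3"),
                 ) -> tuple[pd.DataFrame, dict]:
    """Used + random candidate table, one stratum per usable observed step.

    A step is usable when its own turn (hence the previous bearing) is
    defined.  Candidates falling outside the landscape are dropped; a
    stratum survives if at least 2 rows (the used row always survives).
    Per-stratum RNG substreams make each stratum reproducible
    independently of processing order.  Returns (strata, accounting).
    """
    df = steps_df.reset_index(drop=True)
    ang = df["angle"].to_numpy(dtype=float)
    usable = np.isfinite(ang)
    counts = {"steps": len(df), "strata": 0, "skipped_no_bearing": int((~usable).sum()),
              "candidates_dropped_off_landscape": 0, "strata_dropped": 0}
    ss = np.random.SeedSequence(seed)
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        raise SsfError("no usable strata (no steps with defined bearing)")
    x0 = df["x_start"].to_numpy(dtype=float)[idx]
    y0 = df["y_start"].to_numpy(dtype=float)[idx]
    heading = np.arctan2(df["y"].to_numpy(dtype=float)[idx] - y0,
                         df["x"].to_numpy(dtype=float)[idx] - x0)
    bearing = heading - ang[idx]
    m = idx.size
    # per-stratum substreams: each stratum's candidates depend only on
    # (seed, original step index), not on processing order
    clen = np.empty((m, n_random))
    cturn = np.empty((m, n_random))
    for row, i in enumerate(idx):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=ss.entropy,
                                                           spawn_key=(int(i),)))
        clen[row] = rng.gamma(kernel.shape, 1.0 / kernel.rate, size=n_random)
        cturn[row] = rng.vonmises(kernel.vm_mean, kernel.kappa, size=n_random) \
            if kernel.kappa > 0 else rng.uniform(-np.pi, np.pi, size=n_random)
    heads = bearing[:, None] + cturn
    cx = x0[:, None] + clen * np.cos(heads)
    cy = y0[:, None] + clen * np.sin(heads)
    # interleave the used row first in every stratum
    xs = np.column_stack([df["x"].to_numpy(dtype=float)[idx], cx]).ravel()
    ys = np.column_stack([df["y"].to_numpy(dtype=float)[idx], cy]).ravel()
    lens = np.column_stack([df["step"].to_numpy(dtype=float)[idx], clen]).ravel()
    turns = np.column_stack([ang[idx], cturn]).ravel()
    stratum = np.repeat(idx, n_random + 1)
    used = np.tile(np.r_[1, np.zeros(n_random, dtype=int)], m)
    inside = stack.grid.contains(xs, ys)
    inside[used == 1] = True  # used rows are never dropped
    counts["candidates_dropped_off_landscape"] = int((~inside).sum())
    big_enough = np.add.reduceat(inside, np.arange(0, inside.size, n_random + 1)) >= 2
    survivors = np.repeat(big_enough, n_random + 1)
    counts["strata_dropped"] = int(m) - int(big_enough.sum())
    counts["strata"] = m - counts["strata_dropped"]
    keep = inside & survivors
    out = pd.DataFrame({"stratum": stratum[keep], "used": used[keep],
                        "x": xs[keep], "y": ys[keep], "step": lens[keep],
                        "turn": turns[keep]})
    diel = df["diel"].to_numpy()[idx] if "diel" in df else np.full(m, "day")
    out["diel"] = np.repeat(diel, n_random + 1)[keep]
    if counts["strata"] == 0:
        raise SsfError("no usable strata (all strata dropped)")
    cov = ls.sample_covariates(out["x"].to_numpy(), out["y"].to_numpy(), stack,
                               roles=tuple(r for r in habitat_roles if r in stack))
    for role in cov.columns:
        if role in ("x", "y", "in_extent"):
            continue
        out[role] = cov[role].to_numpy()
    if "forest3" in out:
        oh = ls.forest3_onehot(out["forest3"].to_numpy())
        out["forest"] = oh["forest"].to_numpy()
        out["open_forest"] = oh["open_forest"].to_numpy()
    # movement-adjustment columns; log step guarded against exact zeros
    out["log_step"] = np.log(np.maximum(out["step"].to_numpy(dtype=float), 1e-6))
    out["cos_ta"] = np.cos(out["turn"].to_numpy(dtype=float))
    return out, counts


def build_design(strata: pd.DataFrame, terms: tuple[str, ...],
                 standardizer: ls.Standardizer | None = None,
                 standardize: tuple[str, ...] = ("ndvi", "dist_village", "dist_water"),
                 ) -> tuple[pd.DataFrame, ls.Standardizer | None]:
    """Design matrix for a term list; ``col:day``/``col:night`` are diel interactions.

    Continuous habitat covariates named in ``standardize`` are z-scored
    across all rows (used + available) unless a fitted standardizer is
    supplied; its constants are returned for back-transformation.
    """
    df = strata.copy()
    base_cols = sorted({t.split(":")[0] for t in terms})
    missing = [c for c in base_cols if c not in df.columns]
    if missing:
        raise SsfError(f"terms reference missing columns: {missing}")
    to_std = [c for c in standardize if c in base_cols]
    if to_std:
        if standardizer is None:
            standardizer = ls.Standardizer.fit(df, to_std)
        df[to_std] = standardizer.transform(df[to_std])[to_std]
    X = pd.DataFrame(index=df.index)
    diel = df["diel"].to_numpy() if "diel" in df else np.full(len(df), "day")
    for t in terms:
        if ":" in t:
            col, period = t.split(":")
            X[t] = df[col].to_numpy(dtype=float) * (diel == period)
        else:
            X[t] = df[t].to_numpy(dtype=float)
    return X, standardizer


def _group_bounds(groups: np.ndarray) -> np.ndarray:
    """Start indices of contiguous stratum blocks (input must be block-sorted)."""
    change = np.flatnonzero(np.diff(groups)) + 1
    return np.concatenate([[0], change])


def clogit_loglik(beta, X: np.ndarray, used: np.ndarray, groups: np.ndarray) -> float:
    """Conditional-logistic log-likelihood, evaluated directly.

    ``L(beta) = sum_i [eta_used_i - log sum_j exp(eta_ij)]`` over strata i.
    Rows must be sorted so each stratum is contiguous.
    """
    eta = X @ np.asarray(beta, dtype=float)
    starts = _group_bounds(np.asarray(groups))
    mx = np.maximum.reduceat(eta, starts)
    rep = np.repeat(np.arange(starts.size), np.diff(np.append(starts, eta.size)))
    lse = np.log(np.add.reduceat(np.exp(eta - mx[rep]), starts)) + mx
    return float(eta[used == 1].sum() - lse.sum())


def _clogit_grad_hess(beta, X, used, groups):
    eta = X @ beta
    starts = _group_bounds(groups)
    rep = np.repeat(np.arange(starts.size), np.diff(np.append(starts, eta.size)))
    mx = np.maximum.reduceat(eta, starts)
    e = np.exp(eta - mx[rep])
    denom = np.add.reduceat(e, starts)
    p = e / denom[rep]                       # within-stratum choice probabilities
    M = np.empty((starts.size, X.shape[1]))  # per-stratum E[x]
    for k in range(X.shape[1]):
        M[:, k] = np.add.reduceat(p * X[:, k], starts)
    grad = X[used == 1].sum(axis=0) - M.sum(axis=0)
    H = -((X * p[:, None]).T @ X - M.T @ M)  # -observed information
    return grad, H


def fit_clogit(strata: pd.DataFrame, terms: tuple[str, ...], model: str = "model",
               standardizer: ls.Standardizer | None = None,
               tol: float = 1e-10, maxiter: int = 50) -> SsfFit:
    """Conditional logistic regression of used vs available candidates.

    Maximizes the stratum-conditional log-likelihood by Newton-Raphson
    with step-halving; SEs from the observed information at the optimum,
    two-sided Wald p-values.  Raises on apparent complete separation
    (coefficients diverging).
    """
    X, standardizer = build_design(strata, terms, standardizer)
    order = strata["stratum"].to_numpy().argsort(kind="stable")
    Xm = X.to_numpy(dtype=float)[order]
    y = strata["used"].to_numpy()[order]
    g = strata["stratum"].to_numpy()[order]
    informative = np.repeat(np.bincount(np.unique(g, return_inverse=True)[1]) >= 2,
                            np.bincount(np.unique(g, return_inverse=True)[1]))
    Xm, y, g = Xm[informative], y[informative], g[informative]
    n_strata = np.unique(g).size
    if n_strata < len(terms) + 1:
        raise SsfError(f"too few informative strata ({n_strata}) for {len(terms)} terms")

    beta = np.zeros(len(terms))
    ll = clogit_loglik(beta, Xm, y, g)
    for _ in range(maxiter):
        grad, H = _clogit_grad_hess(beta, Xm, y, g)
        try:
            delta = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            raise SsfError("singular information matrix (collinear design)")
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = clogit_loglik(cand, Xm, y, g)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll_prev, ll = cand, ll, ll_new
        if np.any(np.abs(beta) > 50) or ll > n_strata * math.log(0.999):
            # near-perfect per-stratum prediction: beta is running away
            raise SsfError("conditional logit diverged (possible complete separation)")
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            break
    else:
        raise SsfError("conditional logit did not converge")

    _, H = _clogit_grad_hess(beta, Xm, y, g)
    cov_arr = np.linalg.inv(-H)
    se_arr = np.sqrt(np.diag(cov_arr))
    coef = pd.Series(beta, index=list(terms))
    se = pd.Series(se_arr, index=list(terms))
    cov = pd.DataFrame(cov_arr, index=list(terms), columns=list(terms))
    pv = pd.Series(2.0 * stats.norm.sf(np.abs(coef / se)), index=list(terms))
    return SsfFit(model=model, terms=tuple(terms), coef=coef, se=se, pvalues=pv,
                  cov=cov, loglik=ll, n_strata=n_strata, standardizer=standardizer)


def compare_models(strata: pd.DataFrame,
                   models: dict[str, tuple[str, ...]] | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, SsfFit]]:
    """Fit each candidate model; AIC table sorted best-first."""
    models = models or DEFAULT_MODELS
    fits = {name: fit_clogit(strata, terms, model=name)
            for name, terms in models.items()}
    tab = pd.DataFrame({"model": list(fits), "k": [len(f.coef) for f in fits.values()],
                        "loglik": [f.loglik for f in fits.values()],
                        "AIC": [f.aic for f in fits.values()]})
    tab = tab.sort_values("AIC", kind="stable").reset_index(drop=True)
    tab["dAIC"] = tab["AIC"] - tab["AIC"].iloc[0]
    return tab, fits


def rss(fit: SsfFit, x1: dict[str, float], x2: dict[str, float],
        z_crit: float = 1.959963984540054) -> tuple[float, float, float]:
    """Relative selection strength exp(beta . (x1 - x2)) with 95% Wald CI.

    x1/x2 map habitat term names to values on the model's (standardized)
    scale; terms not mentioned are held equal and cancel.  Movement
    adjustment terms should not appear in the contrast.
    """
    d = pd.Series(0.0, index=fit.coef.index)
    for name in set(x1) | set(x2):
        if name not in fit.coef.index:
            raise SsfError(f"contrast term {name!r} absent from model {fit.model!r}")
        d[name] = float(x1.get(name, 0.0)) - float(x2.get(name, 0.0))
    log_rss = float(fit.coef @ d)
    var = float(d @ fit.cov @ d)
    half = z_crit * math.sqrt(max(var, 0.0))
    return math.exp(log_rss), math.exp(log_rss - half), math.exp(log_rss + half)
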