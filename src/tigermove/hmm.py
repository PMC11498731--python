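"""Two-state hidden Markov movement model with covariate-driven transitions.

Observation model, per hourly step t:

* step length ``s_t`` — zero-inflated gamma: point mass ``pi0_k`` at
  exactly 0 plus ``(1 - pi0_k) * Gamma(shape, rate)`` with
  ``shape = mu_k^2 / sigma_k^2`` and ``rate = mu_k / sigma_k^2`` (so the
  parameters are the state step mean and sd in metres);
* turning angle ``theta_t`` — wrapped Cauchy with mean direction
  ``vartheta_k`` and concentration ``rho_k in [0, 1)``; angles undefined
  at burst starts contribute no angle term.

State process: a 2-state Markov chain whose off-diagonal transition
probabilities are logistic in standardized environmental covariates
evaluated at the step's end point (one-lag convention),

    gamma_kj(z) = logistic(eta_kj),  eta_kj = b0_kj + b_kj . z

Each burst is initialized at the stationary distribution of Gamma(z)
at its first step.  Fitting maximizes the forward log-likelihood over
working-scale parameters (log mu, log sigma, logit pi0, vartheta,
logit rho, transition coefficients) by quasi-Newton with multi-start;
the working-scale covariance comes from the numerically-differentiated
Hessian.  States are relabelled after fitting so state 0 has the
smaller step mean ("encamping"), state 1 the larger ("travelling").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize
from scipy.special import expit, gammaln, logit

from tigermove.landscape import Standardizer

STATE_NAMES = ("encamping", "travelling")

#: default initial emission values: (mu m, sigma m, zero-mass, angle concentration)
#: short/undirected "encamping" vs long/directed "travelling"
DEFAULT_INITIAL_EMISSIONS = ((100.0, 50.0, 0.01, 0.3),
                             (700.0, 1000.0, 0.05, 0.7))


class HmmError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class EmissionParams:
    """Per-state step and turn parameters; arrays of length K (= 2)."""

    mu: np.ndarray        # step mean, m
    sigma: np.ndarray     # step sd, m
    zeromass: np.ndarray  # P(step == 0)
    angle_mean: np.ndarray
    rho: np.ndarray       # wrapped-Cauchy concentration

    def __post_init__(self):
        for name in ("mu", "sigma", "zeromass", "angle_mean", "rho"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.mu <= 0) or np.any(self.sigma <= 0):
            raise HmmError("mu and sigma must be positive")
        if np.any((self.zeromass < 0) | (self.zeromass >= 1)):
            raise HmmError("zeromass must lie in [0, 1)")
        if np.any((self.rho < 0) | (self.rho >= 1)):
            raise HmmError("rho must lie in [0, 1)")

    @property
    def shape(self) -> np.ndarray:
        return self.mu ** 2 / self.sigma ** 2

    @property
    def rate(self) -> np.ndarray:
        return self.mu / self.sigma ** 2


@dataclass
class HmmFit:
    emissions: EmissionParams
    trans_beta: np.ndarray          # (2, 1+p): rows 0->1 and 1->0
    covariates: tuple[str, ...]
    standardizer: Standardizer | None
    loglik: float
    theta: np.ndarray               # working-scale parameter vector
    cov: np.ndarray | None          # working-scale covariance
    n_steps: int
    n_starts: int
    converged: bool

    def emission_table(self, z: float = 1.959963984540054) -> pd.DataFrame:
        """Natural-scale emission estimates with 95% CIs (delta on the working scale)."""
        rows = []
        if self.cov is not None:
            d = np.diag(self.cov)
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        else:
            se = np.full(self.theta.size, np.nan)
        for k, name in enumerate(STATE_NAMES):
            lo_mu, hi_mu = np.exp(np.log(self.emissions.mu[k]) + np.array([-1, 1]) * z * se[k])
            lo_sd, hi_sd = np.exp(np.log(self.emissions.sigma[k]) + np.array([-1, 1]) * z * se[2 + k])
            rows.append({"state": name, "mean_step_m": self.emissions.mu[k],
                         "mean_step_lo": lo_mu, "mean_step_hi": hi_mu,
                         "sd_step_m": self.emissions.sigma[k],
                         "sd_step_lo": lo_sd, "sd_step_hi": hi_sd,
                         "zeromass": self.emissions.zeromass[k],
                         "angle_mean": self.emissions.angle_mean[k],
                         "angle_concentration": self.emissions.rho[k]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# emission densities

def step_logdensity(s, mu: float, sigma: float, zeromass: float = 0.0) -> np.ndarray:
    """Log density of the zero-inflated gamma step-length model.

    Point mass ``zeromass`` at s == 0, ``(1 - zeromass) * Gamma`` for
    s > 0 parameterized by mean ``mu`` and sd ``sigma``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise HmmError("step lengths must be >= 0")
    if mu <= 0 or sigma <= 0 or not 0 <= zeromass < 1:
        raise HmmError("invalid step-density parameters")
    a = mu * mu / (sigma * sigma)
    rate = mu / (sigma * sigma)
    out = np.full(s.shape, -np.inf)
    pos = s > 0
    sp = s[pos]
    out[pos] = (math.log1p(-zeromass) + a * math.log(rate)
                + (a - 1.0) * np.log(sp) - rate * sp - gammaln(a))
    if zeromass > 0:
        out[~pos] = math.log(zeromass)
    return out


def angle_logdensity(theta, mean: float, rho: float) -> np.ndarray:
    """Wrapped-Cauchy log density on (-pi, pi]; rho = 0 is circular uniform."""
    theta = np.asarray(theta, dtype=float)
    if not 0 <= rho < 1:
        raise HmmError("rho must lie in [0, 1)")
    return np.log((1.0 - rho * rho)
                  / (2.0 * np.pi * (1.0 + rho * rho - 2.0 * rho * np.cos(theta - mean))))


def transition_matrix(z, trans_beta: np.ndarray) -> np.ndarray:
    """2x2 transition matrix at covariate vector z (standardized, no intercept).

    ``trans_beta`` rows are (intercept, slopes...) for the 0->1 and 1->0
    transitions; diagonals are the complements, so rows sum to 1.
    """
    x = np.concatenate([[1.0], np.atleast_1d(np.asarray(z, dtype=float))])
    g01 = float(expit(trans_beta[0] @ x))
    g10 = float(expit(trans_beta[1] @ x))
    return np.array([[1.0 - g01, g01], [g10, 1.0 - g10]])


def stationary_distribution(g01: float, g10: float) -> np.ndarray:
    """delta of the 2-state chain: delta_0 = g10 / (g01 + g10)."""
    tot = g01 + g10
    if tot <= 0:
        raise HmmError("degenerate chain: gamma_01 + gamma_10 == 0")
    return np.array([g10 / tot, g01 / tot])


# ---------------------------------------------------------------------------
# forward recursion and Viterbi (numba kernels over concatenated bursts)

@njit(cache=False)
def _forward_nb(logb, g01, g10, starts, delta0):
    ll = 0.0
    for bi in range(starts.shape[0] - 1):
        s, e = starts[bi], starts[bi + 1]
        m = max(logb[s, 0], logb[s, 1])
        if not np.isfinite(m):
            return -np.inf
        a0 = delta0[bi, 0] * math.exp(logb[s, 0] - m)
        a1 = delta0[bi, 1] * math.exp(logb[s, 1] - m)
        w = a0 + a1
        if w <= 0.0:
            return -np.inf
        ll += math.log(w) + m
        a0 /= w
        a1 /= w
        for t in range(s + 1, e):
            p0 = a0 * (1.0 - g01[t]) + a1 * g10[t]
            p1 = a0 * g01[t] + a1 * (1.0 - g10[t])
            m = max(logb[t, 0], logb[t, 1])
            if not np.isfinite(m):
                return -np.inf
            a0 = p0 * math.exp(logb[t, 0] - m)
            a1 = p1 * math.exp(logb[t, 1] - m)
            w = a0 + a1
            if w <= 0.0:
                return -np.inf
            ll += math.log(w) + m
            a0 /= w
            a1 /= w
    return ll


@njit(cache=False)
def _viterbi_nb(logb, g01, g10, starts, delta0):
    T = logb.shape[0]
    path = np.zeros(T, dtype=np.int64)
    back = np.zeros((T, 2), dtype=np.int64)
    for bi in range(starts.shape[0] - 1):
        s, e = starts[bi], starts[bi + 1]
        v0 = math.log(delta0[bi, 0]) + logb[s, 0]
        v1 = math.log(delta0[bi, 1]) + logb[s, 1]
        for t in range(s + 1, e):
            # into state 0
            c00 = v0 + math.log(1.0 - g01[t])
            c10 = v1 + math.log(g10[t])
            if c00 >= c10:  # ties toward the lower previous index
                n0, back[t, 0] = c00, 0
            else:
                n0, back[t, 0] = c10, 1
            # into state 1
            c01 = v0 + math.log(g01[t])
            c11 = v1 + math.log(1.0 - g10[t])
            if c01 >= c11:
                n1, back[t, 1] = c01, 0
            else:
                n1, back[t, 1] = c11, 1
            v0 = n0 + logb[t, 0]
            v1 = n1 + logb[t, 1]
        last = 0 if v0 >= v1 else 1
        path[e - 1] = last
        for t in range(e - 1, s, -1):
            path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# working-scale packing and likelihood assembly

def _pack(em: EmissionParams, beta: np.ndarray) -> np.ndarray:
    return np.concatenate([np.log(em.mu), np.log(em.sigma), logit(em.zeromass),
                           em.angle_mean, logit(em.rho), np.asarray(beta).ravel()])


def _unpack(theta: np.ndarray, p: int) -> tuple[EmissionParams, np.ndarray]:
    em = EmissionParams(mu=np.exp(theta[0:2]), sigma=np.exp(theta[2:4]),
                        zeromass=expit(theta[4:6]),
                        angle_mean=np.arctan2(np.sin(theta[6:8]), np.cos(theta[6:8])),
                        rho=expit(theta[8:10]))
    beta = theta[10:].reshape(2, 1 + p)
    return em, beta


def _emission_logb(steps: np.ndarray, angles: np.ndarray, em: EmissionParams) -> np.ndarray:
    T = steps.size
    logb = np.zeros((T, 2))
    has_angle = np.isfinite(angles)
    for k in range(2):
        logb[:, k] = step_logdensity(steps, em.mu[k], em.sigma[k], em.zeromass[k])
        logb[has_angle, k] += angle_logdensity(angles[has_angle],
                                               em.angle_mean[k], em.rho[k])
    return logb


def _design(Z: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(Z.shape[0]), Z])


def _trans_probs(X: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return expit(X @ beta[0]), expit(X @ beta[1])


def _delta0(g01: np.ndarray, g10: np.ndarray, starts: np.ndarray) -> np.ndarray:
    idx = starts[:-1]
    tot = g01[idx] + g10[idx]
    d0 = np.where(tot > 0, g10[idx] / np.where(tot > 0, tot, 1.0), 0.5)
    return np.column_stack([d0, 1.0 - d0])


def _step_arrays(steps_df: pd.DataFrame, covariates: tuple[str, ...],
                 standardizer: Standardizer | None):
    """Extract (s, theta, Z, burst start indices) from a step table.

    ``standardizer=None`` means the covariate columns are used as-is
    (i.e. already on the model scale).
    """
    df = steps_df.reset_index(drop=True)
    if covariates:
        sub = df[list(covariates)]
        if standardizer is not None:
            sub = standardizer.transform(sub)
        Z = sub.to_numpy(dtype=float)
    else:
        Z = np.empty((len(df), 0))
    keys = (df["animal"].astype(str) + "/" + df["burst"].astype(str)
            if "burst" in df else pd.Series("0", index=df.index))
    change = np.flatnonzero(keys.to_numpy() != np.roll(keys.to_numpy(), 1))
    starts = np.concatenate([[0] if change.size == 0 else change, [len(df)]]).astype(np.int64)
    if starts[0] != 0:
        starts = np.concatenate([[0], starts]).astype(np.int64)
    return (df["step"].to_numpy(dtype=float), df["angle"].to_numpy(dtype=float),
            Z, starts, standardizer)


def forward_loglik(steps: np.ndarray, angles: np.ndarray, Z: np.ndarray,
                   starts: np.ndarray, em: EmissionParams, beta: np.ndarray,
                   delta0: np.ndarray | None = None) -> float:
    """Forward log-likelihood over all bursts (additive across bursts).

    ``delta0`` defaults to the stationary distribution of Gamma(z) at
    each burst's first step.
    """
    logb = _emission_logb(steps, angles, em)
    X = _design(Z)
    g01, g10 = _trans_probs(X, beta)
    if delta0 is None:
        delta0 = _delta0(g01, g10, starts)
    ll = _forward_nb(logb, g01, g10, starts.astype(np.int64), delta0)
    if not np.isfinite(ll):
        raise HmmError("non-finite forward likelihood (degenerate parameters)")
    return float(ll)


# ---------------------------------------------------------------------------
# fitting

def fit_hmm(steps_df: pd.DataFrame,
            covariates: tuple[str, ...] = ("dist_village", "dist_water", "ndvi"),
            initial_emissions=DEFAULT_INITIAL_EMISSIONS,
            standardizer: Standardizer | None = None,
            n_starts: int = 5, seed: int = 0,
            compute_cov: bool = True) -> HmmFit:
    """Maximum-likelihood fit of the 2-state model.

    ``steps_df`` needs columns ``step``, ``angle`` (NaN where undefined),
    ``animal``/``burst`` and the covariate columns (natural units;
    standardized internally unless a fitted ``standardizer`` is given).
    Multi-start: the supplied initial values plus ``n_starts - 1``
    seed-jittered variants; the best optimum is kept and states are
    relabelled so state 0 has the smaller step mean.
    """
    if standardizer is None and covariates:
        standardizer = Standardizer.fit(steps_df, covariates)
    s, ang, Z, starts, standardizer = _step_arrays(steps_df, covariates, standardizer)
    p = Z.shape[1]
    X = _design(Z)
    has_angle = np.isfinite(ang)
    any_zero = np.any(s == 0)

    def nll(theta):
        try:
            em, beta = _unpack(theta, p)
        except HmmError:
            return 1e12
        logb = _emission_logb(s, ang, em)
        g01, g10 = _trans_probs(X, beta)
        d0 = _delta0(g01, g10, starts)
        ll = _forward_nb(logb, g01, g10, starts, d0)
        return -ll if np.isfinite(ll) else 1e12

    em0 = EmissionParams(
        mu=[initial_emissions[0][0], initial_emissions[1][0]],
        sigma=[initial_emissions[0][1], initial_emissions[1][1]],
        zeromass=[max(initial_emissions[0][2], 1e-4), max(initial_emissions[1][2], 1e-4)],
        angle_mean=[0.0, 0.0],
        rho=[initial_emissions[0][3], initial_emissions[1][3]])
    beta0 = np.zeros((2, 1 + p))
    beta0[:, 0] = -2.0  # mild state persistence at the start
    theta0 = _pack(em0, beta0)

    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for i in range(max(1, n_starts)):
        if i == 0:
            start = theta0
        elif i == 1:
            # turn-back encamping: the concentrated-at-pi alternative for the
            # slow state's angle mean, which theta = 0 cannot reach once the
            # optimizer has collapsed the concentration to the rho = 0 saddle
            start = theta0.copy()
            start[6] = np.pi
        else:
            start = theta0 + rng.normal(0.0, 0.4, size=theta0.size)
            # circular angle means need wide jitter to escape the rho->0 ridge
            start[6:8] = rng.uniform(-np.pi, np.pi, size=2)
        res = optimize.minimize(nll, start, method="L-BFGS-B",
                                options={"maxiter": 1000, "maxfun": 40000,
                                         "ftol": 1e-10, "gtol": 1e-6})
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None or best.fun >= 1e12:
        raise HmmError("HMM fit failed from every start")

    # restart-polish: re-running L-BFGS resets its curvature memory and
    # reliably tightens convergence on flat (weakly identified) directions
    for _ in range(3):
        res = optimize.minimize(nll, best.x, method="L-BFGS-B",
                                options={"maxiter": 1000, "maxfun": 40000,
                                         "ftol": 1e-12, "gtol": 1e-8})
        if res.fun >= best.fun - 1e-9:
            break
        best = res

    theta = best.x.copy()
    em, beta = _unpack(theta, p)
    if em.mu[0] > em.mu[1]:  # relabel: encamping = smaller step mean
        swap = np.arange(theta.size)
        for block in range(5):  # pairwise emission blocks
            swap[2 * block], swap[2 * block + 1] = 2 * block + 1, 2 * block
        b0 = 10
        swap[b0:b0 + 1 + p], swap[b0 + 1 + p:b0 + 2 * (1 + p)] = \
            np.arange(b0 + 1 + p, b0 + 2 * (1 + p)), np.arange(b0, b0 + 1 + p)
        theta = theta[swap]
        em, beta = _unpack(theta, p)

    # zero-mass is not identifiable without zero steps; report 0 there
    if not any_zero:
        em.zeromass = np.zeros(2)

    cov = None
    if compute_cov:
        from statsmodels.tools.numdiff import approx_hess3

        H = approx_hess3(theta, nll)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)

    return HmmFit(emissions=em, trans_beta=beta, covariates=tuple(covariates),
                  standardizer=standardizer, loglik=-float(best.fun), theta=theta,
                  cov=cov, n_steps=int(s.size), n_starts=n_starts,
                  converged=bool(best.success) and n_ok > 0)


def loglik_at(steps_df: pd.DataFrame, fit_or_theta, covariates=None,
              standardizer=None) -> float:
    """Forward log-likelihood of a step table under a fit (convenience)."""
    if isinstance(fit_or_theta, HmmFit):
        fit = fit_or_theta
        s, ang, Z, starts, _ = _step_arrays(steps_df, fit.covariates, fit.standardizer)
        return forward_loglik(s, ang, Z, starts, fit.emissions, fit.trans_beta)
    raise TypeError("pass an HmmFit")


def viterbi(steps_df: pd.DataFrame, fit: HmmFit) -> np.ndarray:
    """Globally most probable state sequence (0 = encamping, 1 = travelling)."""
    s, ang, Z, starts, _ = _step_arrays(steps_df, fit.covariates, fit.standardizer)
    logb = _emission_logb(s, ang, fit.emissions)
    X = _design(Z)
    g01, g10 = _trans_probs(X, fit.trans_beta)
    d0 = _delta0(g01, g10, starts)
    return _viterbi_nb(logb, g01, g10, starts, d0)


def state_budget(states) -> np.ndarray:
    """Proportion of steps spent in each state; sums to 1."""
    states = np.asarray(states)
    if states.size == 0:
        raise HmmError("empty state sequence")
    return np.array([(states == k).mean() for k in range(2)])


def stationary_curve(fit: HmmFit, covariate: str, grid,
                     z_crit: float = 1.959963984540054) -> pd.DataFrame:
    """Stationary state probabilities along one covariate, others at their mean.

    Returns natural-units grid values with ``p_encamping`` and a
    pointwise delta-method 95% CI (computed on the logit scale from the
    working covariance of the transition coefficients).
    """
    if covariate not in fit.covariates:
        raise HmmError(f"{covariate!r} is not a fitted transition covariate")
    ci = fit.covariates.index(covariate)
    p = len(fit.covariates)
    nb = 2 * (1 + p)
    bvec = fit.trans_beta.ravel()
    cov_b = fit.cov[10:, 10:] if fit.cov is not None else None

    def logit_d0(b, zfocal):
        beta = b.reshape(2, 1 + p)
        x = np.zeros(1 + p)
        x[0] = 1.0
        x[1 + ci] = zfocal
        g01 = expit(beta[0] @ x)
        g10 = expit(beta[1] @ x)
        d = g10 / (g01 + g10)
        d = min(max(d, 1e-12), 1 - 1e-12)
        return math.log(d / (1 - d))

    rows = []
    for val in np.atleast_1d(np.asarray(grid, dtype=float)):
        zf = float(fit.standardizer.transform_value(covariate, val)) \
            if fit.standardizer is not None else float(val)
        l0 = logit_d0(bvec, zf)
        d0 = expit(l0)
        lo = hi = np.nan
        if cov_b is not None:
            g = np.zeros(nb)
            h = 1e-5
            for j in range(nb):
                bp, bm = bvec.copy(), bvec.copy()
                bp[j] += h
                bm[j] -= h
                g[j] = (logit_d0(bp, zf) - logit_d0(bm, zf)) / (2 * h)
            var = float(g @ cov_b @ g)
            if var >= 0:
                half = z_crit * math.sqrt(var)
                lo, hi = expit(l0 - half), expit(l0 + half)
        rows.append({"covariate": covariate, "value": float(val),
                     "p_encamping": d0, "lo": lo, "hi": hi,
                     "p_travelling": 1.0 - d0})
    return pd.DataFrame(rows)
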