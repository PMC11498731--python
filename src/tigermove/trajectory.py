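"""Track regularization, CTCRW gap imputation and displacement statistics.

Tracks are pandas DataFrames with columns ``animal``, ``time``
(timezone-aware or naive local Timestamps on an hourly lattice after
regularization), ``x``, ``y`` (projected metres), ``source``
(``observed`` / ``imputed`` / ``missing``) and ``burst`` (int; gaps
longer than ``max_gap`` split an animal's track into bursts that are
modelled independently).

Missing fixes inside a burst are predicted with a continuous-time
correlated random walk: the animal's velocity is an Ornstein-Uhlenbeck
process (autocorrelation rate ``beta``, 1/h; noise scale ``sigma``,
m/h^1.5) and position its integral, observed with isotropic Gaussian GPS
error ``obs_sd`` (m).  The model is discretized exactly over each
inter-fix interval and fitted by maximum likelihood via the Kalman
filter; missing positions are the Rauch-Tung-Striebel smoother means.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

HOUR = pd.Timedelta(hours=1)


class TrackError(ValueError):
    pass


# ---------------------------------------------------------------------------
# regularization

def regularize(fixes: pd.DataFrame, interval: pd.Timedelta = HOUR,
               max_gap: pd.Timedelta = pd.Timedelta(hours=24),
               tolerance: pd.Timedelta = pd.Timedelta(minutes=5)) -> pd.DataFrame:
    """Snap fixes to the hourly lattice and expose missing slots.

    Fixes are assigned to the nearest lattice slot (anchored at the first
    fix) and kept only if within ``tolerance`` of it; when two fixes land
    on one slot the earliest is kept with a warning.  Runs of missing
    slots no longer than ``max_gap`` become explicit ``missing`` rows;
    longer gaps split the track into separate bursts.
    """
    if len(fixes) < 2:
        raise TrackError("regularize needs at least 2 fixes")
    df = fixes.sort_values("time").reset_index(drop=True)
    t0 = df["time"].iloc[0]
    slot = ((df["time"] - t0) / interval).round().astype(int)
    offset = (df["time"] - (t0 + slot * interval)).abs()
    keep = offset <= tolerance
    if not keep.all():
        warnings.warn(f"dropped {(~keep).sum()} fixes off the lattice by > {tolerance}")
    df, slot = df[keep], slot[keep]
    dup = slot.duplicated()
    if dup.any():
        warnings.warn(f"{dup.sum()} duplicate slots after snapping; keeping earliest")
        df, slot = df[~dup], slot[~dup]
    slot = slot.to_numpy()
    max_gap_slots = int(max_gap / interval)

    animal = df["animal"].iloc[0] if "animal" in df else "animal"
    rows = []
    burst = 0
    for i, (s, row) in enumerate(zip(slot, df.itertuples())):
        if i > 0:
            gap = s - slot[i - 1]
            if gap > max_gap_slots:
                burst += 1
            else:
                for m in range(slot[i - 1] + 1, s):
                    rows.append((animal, t0 + m * interval, np.nan, np.nan,
                                 "missing", burst))
        rows.append((animal, t0 + int(s) * interval, row.x, row.y, "observed", burst))
    return pd.DataFrame(rows, columns=["animal", "time", "x", "y", "source", "burst"])


# ---------------------------------------------------------------------------
# CTCRW (integrated Ornstein-Uhlenbeck velocity) via Kalman filter/smoother

@dataclass
class CtcrwParams:
    beta: float     # velocity autocorrelation rate, 1/h
    sigma: float    # velocity noise scale, m / h^1.5
    obs_sd: float   # GPS error sd, m

    def __post_init__(self):
        if self.beta <= 0 or self.sigma <= 0 or self.obs_sd < 0:
            raise TrackError("CTCRW parameters out of range")


#: prior position variance (m^2) at the first fix of a burst — vague
_P0_POS = 1.0e6


def _discretize(beta: float, sigma: float, dt: float):
    """Exact transition (F) and process covariance (Q) for [pos, vel] over dt hours."""
    phi = math.exp(-beta * dt)
    F = np.array([[1.0, (1.0 - phi) / beta], [0.0, phi]])
    s2 = sigma * sigma
    q_vv = s2 * (1.0 - phi * phi) / (2.0 * beta)
    q_pv = s2 * (1.0 - phi) ** 2 / (2.0 * beta * beta)
    q_pp = s2 / (beta * beta) * (dt - 2.0 * (1.0 - phi) / beta
                                 + (1.0 - phi * phi) / (2.0 * beta))
    Q = np.array([[q_pp, q_pv], [q_pv, q_vv]])
    return F, Q


def _burst_arrays(track: pd.DataFrame):
    """Per burst: hours-from-start, positions (NaN at missing), observed mask."""
    for _, b in track.groupby("burst", sort=True):
        t = (b["time"] - b["time"].iloc[0]) / HOUR
        yield (t.to_numpy(dtype=float), b["x"].to_numpy(dtype=float),
               b["y"].to_numpy(dtype=float),
               (b["source"].to_numpy() == "observed"), b.index.to_numpy())


def _kalman_1d(times, obs, observed, params: CtcrwParams, smooth: bool):
    """Filter (and optionally RTS-smooth) one coordinate of one burst.

    Returns (loglik, smoothed or filtered position means).  The prior at
    the first observed fix is N(first obs, _P0_POS) for position and the
    stationary N(0, sigma^2/(2 beta)) for velocity; the first observation
    itself still enters the likelihood.
    """
    n = len(times)
    first = int(np.argmax(observed))
    m = np.array([obs[first], 0.0])
    P = np.diag([_P0_POS, params.sigma ** 2 / (2.0 * params.beta)])
    H = np.array([1.0, 0.0])
    R = params.obs_sd ** 2
    ll = 0.0
    means = np.zeros((n, 2))
    covs = np.zeros((n, 2, 2))
    preds = np.zeros((n, 2))
    pred_covs = np.zeros((n, 2, 2))
    Fs = np.zeros((n, 2, 2))
    for k in range(n):
        if k > 0:
            F, Q = _discretize(params.beta, params.sigma, times[k] - times[k - 1])
            m = F @ m
            P = F @ P @ F.T + Q
            Fs[k] = F
        preds[k], pred_covs[k] = m, P
        if observed[k]:
            v = obs[k] - H @ m
            S = H @ P @ H + R
            if S <= 0:
                S = 1e-12
            K = (P @ H) / S
            m = m + K * v
            P = P - np.outer(K, P @ H)
            ll += -0.5 * (math.log(2.0 * math.pi * S) + v * v / S)
        means[k], covs[k] = m, P
    if not smooth:
        return ll, means[:, 0]
    sm = means.copy()
    sP = covs.copy()
    for k in range(n - 2, -1, -1):
        Pp = pred_covs[k + 1]
        G = covs[k] @ Fs[k + 1].T @ np.linalg.inv(Pp)
        sm[k] = means[k] + G @ (sm[k + 1] - preds[k + 1])
        sP[k] = covs[k] + G @ (sP[k + 1] - Pp) @ G.T
    return ll, sm[:, 0]


def ctcrw_loglik(track: pd.DataFrame, params: CtcrwParams) -> float:
    """Kalman-filter log-likelihood of the observed fixes, summed over bursts and x/y."""
    ll = 0.0
    for times, x, y, observed, _ in _burst_arrays(track):
        if observed.sum() < 2:
            continue
        ll += _kalman_1d(times, x, observed, params, smooth=False)[0]
        ll += _kalman_1d(times, y, observed, params, smooth=False)[0]
    return ll


def fit_ctcrw(track: pd.DataFrame, estimate_obs_sd: bool = True,
              obs_sd: float = 25.0, x0: tuple[float, float] = (0.5, 300.0),
              ) -> tuple[CtcrwParams, float]:
    """ML fit of (beta, sigma[, obs_sd]) over the observed fixes.

    Defaults start at beta = 0.5/h, sigma = 300 m/h^1.5 and, when the GPS
    error sd is estimated, 25 m — ordinary magnitudes for hourly
    large-mammal telemetry.  Returns (params, log-likelihood).
    """
    nobs = (track["source"] == "observed").groupby(track["burst"]).sum()
    if nobs.max() < 10:
        raise TrackError("fit_ctcrw needs a burst with >= 10 observed fixes")

    def nll(theta):
        b, s = math.exp(theta[0]), math.exp(theta[1])
        o = math.exp(theta[2]) if estimate_obs_sd else obs_sd
        try:
            return -ctcrw_loglik(track, CtcrwParams(b, s, o))
        except (FloatingPointError, OverflowError):
            return 1e12

    t0 = [math.log(x0[0]), math.log(x0[1])] + ([math.log(obs_sd)] if estimate_obs_sd else [])
    res = optimize.minimize(nll, t0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    if not res.success:
        raise TrackError(f"CTCRW fit did not converge: {res.message}")
    b, s = math.exp(res.x[0]), math.exp(res.x[1])
    o = math.exp(res.x[2]) if estimate_obs_sd else obs_sd
    return CtcrwParams(b, s, o), -res.fun


def impute(track: pd.DataFrame, params: CtcrwParams) -> pd.DataFrame:
    """Fill missing slots with Kalman-smoother means; observed fixes untouched."""
    out = track.copy()
    for times, x, y, observed, idx in _burst_arrays(track):
        if (~observed).sum() == 0 or observed.sum() < 2:
            continue
        _, sx = _kalman_1d(times, x, observed, params, smooth=True)
        _, sy = _kalman_1d(times, y, observed, params, smooth=True)
        miss = ~observed
        out.loc[idx[miss], "x"] = sx[miss]
        out.loc[idx[miss], "y"] = sy[miss]
        out.loc[idx[miss], "source"] = "imputed"
    return out


# ---------------------------------------------------------------------------
# steps, turning angles, diel labels

def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    return w


def compute_steps(track: pd.DataFrame) -> pd.DataFrame:
    """Step series: one row per move between consecutive fixes of a burst.

    ``step`` is the Euclidean displacement (m; on the hourly lattice this
    is also m/h), ``angle`` the signed turn (rad, (-pi, pi], CCW
    positive) between successive displacement vectors — undefined (NaN)
    on a burst's first step or next to a zero-length step.  ``x``/``y``
    are the step's endpoint; ``imputed`` flags steps touching an imputed
    fix.
    """
    parts = []
    for (animal, burst), b in track.groupby(["animal", "burst"], sort=True):
        b = b[b["source"] != "missing"]
        if len(b) < 2:
            warnings.warn(f"burst {burst} of {animal}: < 2 fixes, skipped")
            continue
        x, y = b["x"].to_numpy(), b["y"].to_numpy()
        dx, dy = np.diff(x), np.diff(y)
        step = np.hypot(dx, dy)
        heading = np.arctan2(dy, dx)
        angle = np.full(len(step), np.nan)
        ok = (step[1:] > 0) & (step[:-1] > 0)
        angle[1:][ok] = wrap_angle(heading[1:] - heading[:-1])[ok]
        imput = (b["source"].to_numpy() == "imputed")
        parts.append(pd.DataFrame({
            "animal": animal, "burst": burst, "time": b["time"].to_numpy()[1:],
            "x": x[1:], "y": y[1:], "x_start": x[:-1], "y_start": y[:-1],
            "step": step, "angle": angle,
            "imputed": imput[1:] | imput[:-1],
        }))
    if not parts:
        raise TrackError("no burst with >= 2 fixes")
    return pd.concat(parts, ignore_index=True)


def assign_diel(steps: pd.DataFrame, day_start: int = 6, day_end: int = 18) -> pd.DataFrame:
    """Label each step day/night by local clock hour, day = [day_start, day_end)."""
    hours = pd.DatetimeIndex(steps["time"]).hour
    out = steps.copy()
    out["diel"] = np.where((hours >= day_start) & (hours < day_end), "day", "night")
    return out


def displacement_summary(steps: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Mean +/- SE of step length, optionally per group (e.g. diel x forest class).

    SE is sd/sqrt(n); with a single step it is reported missing.  Empty
    groups are simply absent.
    """
    s = steps.dropna(subset=["step"])
    if by:
        g = s.groupby(by, observed=True)["step"]
        out = g.agg(n="count", mean_step="mean", se_step="sem").reset_index()
    else:
        v = s["step"]
        out = pd.DataFrame({"n": [len(v)], "mean_step": [v.mean()],
                            "se_step": [v.sem() if len(v) > 1 else np.nan]})
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass
class MannWhitneyResult:
    U_a: float
    U_b: float
    Z: float
    p: float
    method: str  # "exact" or "asymptotic"


def mann_whitney_u(a, b, exact_max_n: int = 8) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with midranks, tie-corrected normal Z.

    p is exact (full enumeration of rank assignments) when
    min(n_a, n_b) <= ``exact_max_n`` and there are no ties across the
    pooled sample; otherwise the tie-corrected normal approximation with
    continuity correction.  U_a + U_b = n_a * n_b always.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise TrackError("mann_whitney_u: both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    Ua = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    Ub = na * nb - Ua

    # tie-corrected normal approximation with continuity correction
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    mu = na * nb / 2.0
    if var <= 0:  # all observations identical
        return MannWhitneyResult(Ua, Ub, 0.0, 1.0, "asymptotic")
    d = Ua - mu
    cc = 0.5 if d != 0 else 0.0
    Z = (d - math.copysign(cc, d)) / math.sqrt(var)

    ties = counts.size < n
    if min(na, nb) <= exact_max_n and not ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return MannWhitneyResult(Ua, Ub, Z, float(res.pvalue), "exact")
    p = 2.0 * stats.norm.sf(abs(Z))
    return MannWhitneyResult(Ua, Ub, Z, min(1.0, p), "asymptotic")


# ---------------------------------------------------------------------------
# track CSV I/O

TRACK_COLUMNS = ["animal", "time", "x", "y", "source", "burst"]


def read_track_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["time"] = pd.to_datetime(df["time"], format="ISO8601")
    if "source" not in df:
        df["source"] = "observed"
    if "burst" not in df:
        df["burst"] = 0
    if "animal" not in df:
        df["animal"] = "animal"
    return df[[c for c in TRACK_COLUMNS if c in df.columns]]


def write_track_csv(track: pd.DataFrame, path) -> None:
    out = track.copy()
    out["time"] = pd.DatetimeIndex(out["time"]).strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)
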