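"""Configuration-driven orchestration: prepare -> impute -> HMM -> iSSF -> report.

A run is described by a YAML config (see :class:`RunConfig`); outputs are
CSV tables plus a JSON manifest (config, seeds, input checksums, record
accounting), written so that re-running the same config reproduces the
tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tigermove import hmm, issf
from tigermove import landscape as ls
from tigermove import trajectory as tj

__version__ = "0.1.0"

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    tracks: str = "tracks.csv"
    layers: str = "landscape/layers.yaml"
    outdir: str = "out"
    seed: int = 0
    day_start: int = 6
    day_end: int = 18
    max_gap_hours: int = 24
    ctcrw_estimate_obs_sd: bool = False
    ctcrw_obs_sd: float = 20.0
    hmm_covariates: tuple[str, ...] = ("dist_village", "dist_water", "ndvi")
    hmm_initial_emissions: tuple = hmm.DEFAULT_INITIAL_EMISSIONS
    hmm_n_starts: int = 3
    stationary_points: int = 25
    issf_n_random: int = issf.N_RANDOM_DEFAULT
    issf_models: dict = field(default_factory=lambda: dict(issf.DEFAULT_MODELS))
    #: RSS contrasts: (term, value1, value2) in natural units
    rss_contrasts: tuple = (("dist_village", 5000.0, 500.0), ("ndvi", 0.3, 0.0))
    base_dir: Path = Path(".")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key in ("tracks", "layers", "outdir", "seed", "day_start", "day_end",
                    "max_gap_hours", "ctcrw_estimate_obs_sd", "ctcrw_obs_sd",
                    "hmm_covariates", "hmm_initial_emissions", "hmm_n_starts",
                    "stationary_points", "issf_n_random", "issf_models",
                    "rss_contrasts"):
            if key in raw:
                kw[key] = raw[key]
        cfg = cls(**kw)
        cfg.base_dir = path.parent
        cfg.hmm_covariates = tuple(cfg.hmm_covariates)
        cfg.issf_models = {k: tuple(v) for k, v in cfg.issf_models.items()}
        cfg.rss_contrasts = tuple(tuple(c) for c in cfg.rss_contrasts)
        return cfg

    def path(self, rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


def validate_inputs(cfg: RunConfig) -> dict:
    """Schema / alignment / coverage checks; returns {'errors': [...], 'warnings': [...]}."""
    errors, warns = [], []
    tracks_path = cfg.path(cfg.tracks)
    if not tracks_path.exists():
        return {"errors": [f"tracks file missing: {tracks_path}"], "warnings": []}
    try:
        tracks = tj.read_track_csv(tracks_path)
    except Exception as e:  # malformed CSV / timestamps
        return {"errors": [f"cannot read tracks: {e}"], "warnings": []}
    for col in ("animal", "time", "x", "y"):
        if col not in tracks:
            errors.append(f"tracks missing column {col!r}")
    for animal, t in tracks.groupby("animal"):
        if not t["time"].is_monotonic_increasing:
            warns.append(f"animal {animal}: unsorted timestamps (will be sorted)")
    layers_path = cfg.path(cfg.layers)
    if not layers_path.exists():
        errors.append(f"layer config missing: {layers_path}")
        return {"errors": errors, "warnings": warns}
    try:
        stack = ls.read_stack(layers_path)
    except ls.LayerError as e:
        errors.append(str(e))
        return {"errors": errors, "warnings": warns}
    if not errors:
        outside = ~stack.grid.contains(tracks["x"].to_numpy(), tracks["y"].to_numpy())
        if outside.any():
            errors.append(f"{int(outside.sum())} fixes outside the raster extent")
    return {"errors": errors, "warnings": warns}


def prepare_tracks(cfg: RunConfig, tracks: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Regularize + CTCRW-impute every animal; returns (track, accounting)."""
    acct = {}
    out = []
    for animal, raw in tracks.groupby("animal", sort=True):
        reg = tj.regularize(raw, max_gap=pd.Timedelta(hours=cfg.max_gap_hours))
        n_missing = int((reg["source"] == "missing").sum())
        if n_missing:
            params, ll = tj.fit_ctcrw(reg, estimate_obs_sd=cfg.ctcrw_estimate_obs_sd,
                                      obs_sd=cfg.ctcrw_obs_sd)
            reg = tj.impute(reg, params)
            acct[str(animal)] = {"missing_imputed": n_missing,
                                 "ctcrw": {"beta": params.beta, "sigma": params.sigma,
                                           "obs_sd": params.obs_sd, "loglik": ll}}
        else:
            acct[str(animal)] = {"missing_imputed": 0}
        out.append(reg)
    return pd.concat(out, ignore_index=True), acct


def attach_covariates(steps: pd.DataFrame, stack: ls.LandscapeStack) -> pd.DataFrame:
    """Sample the covariate stack at step end points; adds forest label column."""
    cov = ls.sample_covariates(steps["x"].to_numpy(), steps["y"].to_numpy(), stack)
    out = steps.copy()
    for role in ("ndvi", "dist_village", "dist_water", "forest3"):
        out[role] = cov[role].to_numpy()
    out["forest_class"] = out["forest3"].map(ls.FOREST3_LABELS)
    return out


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


ALL_STAGES = ("displacement", "hmm", "issf")


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Execute the analysis; writes tables + manifest under cfg.outdir.

    ``stages`` selects which analysis blocks run after track preparation
    (preparation itself always runs).  Returns a dict of the in-memory
    results keyed by output name.
    """
    report = validate_inputs(cfg)
    if report["errors"]:
        raise RuntimeError(f"input validation failed: {report['errors']}")
    outdir = cfg.path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"validation": report}

    tracks = tj.read_track_csv(cfg.path(cfg.tracks))
    stack = ls.read_stack(cfg.path(cfg.layers))

    # --- prepare: regularize + impute
    track, acct = prepare_tracks(cfg, tracks)
    tj.write_track_csv(track, outdir / "track_imputed.csv")

    # --- steps, diel, covariates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        steps = tj.compute_steps(track)
    steps = tj.assign_diel(steps, cfg.day_start, cfg.day_end)
    steps = attach_covariates(steps, stack)

    if "displacement" in stages:
        _run_displacement(cfg, steps, outdir, results)

    if "hmm" in stages:
        _run_hmm(cfg, steps, outdir, results)

    sacct = {}
    if "issf" in stages:
        sacct = _run_issf(cfg, steps, stack, outdir, results)

    # --- manifest
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(stages),
        "config": {k: v for k, v in vars(cfg).items() if k != "base_dir"},
        "inputs": {
            "tracks": _checksum(cfg.path(cfg.tracks)),
            "layers": _checksum(cfg.path(cfg.layers)),
        },
        "accounting": {
            "animals": acct,
            "issf_strata": sacct,
            "validation_warnings": report["warnings"],
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_jsonable))
    results["manifest"] = manifest
    return results


def _run_displacement(cfg: RunConfig, steps, outdir, results) -> None:
    disp = []
    disp.append(tj.displacement_summary(steps).assign(group="all"))
    disp.append(tj.displacement_summary(steps, by=["diel"]).assign(group="diel"))
    disp.append(tj.displacement_summary(steps, by=["diel", "forest_class"])
                .assign(group="diel_x_forest"))
    displacement = pd.concat(disp, ignore_index=True)[
        ["group", "diel", "forest_class", "n", "mean_step", "se_step"]]
    _write(displacement, outdir / "displacement.csv")
    results["displacement"] = displacement

    mw_rows = []
    day = steps.loc[steps["diel"] == "day", "step"]
    night = steps.loc[steps["diel"] == "night", "step"]
    r = tj.mann_whitney_u(day, night)
    mw_rows.append({"comparison": "day_vs_night", "stratum": "all", "U": r.U_a,
                    "Z": r.Z, "p": r.p, "method": r.method})
    for fc, sub in steps.groupby("forest_class", observed=True):
        d = sub.loc[sub["diel"] == "day", "step"]
        n = sub.loc[sub["diel"] == "night", "step"]
        if len(d) and len(n):
            r = tj.mann_whitney_u(d, n)
            mw_rows.append({"comparison": "day_vs_night", "stratum": fc, "U": r.U_a,
                            "Z": r.Z, "p": r.p, "method": r.method})
    mannwhitney = pd.DataFrame(mw_rows)
    _write(mannwhitney, outdir / "mannwhitney.csv")
    results["mannwhitney"] = mannwhitney


def _run_hmm(cfg: RunConfig, steps, outdir, results):
    fit = hmm.fit_hmm(steps, covariates=cfg.hmm_covariates,
                      initial_emissions=cfg.hmm_initial_emissions,
                      n_starts=cfg.hmm_n_starts, seed=cfg.seed)
    emis = fit.emission_table()
    _write(emis, outdir / "hmm_emissions.csv")
    results["hmm_fit"] = fit
    trans = pd.DataFrame(fit.trans_beta,
                         columns=["intercept", *fit.covariates],
                         index=["encamping_to_travelling", "travelling_to_encamping"])
    trans.insert(0, "transition", trans.index)
    _write(trans.reset_index(drop=True), outdir / "hmm_transitions.csv")

    states = hmm.viterbi(steps, fit)
    steps_out = steps.copy()
    steps_out["state"] = np.array(hmm.STATE_NAMES)[states]
    _write(steps_out.drop(columns=["forest3"]), outdir / "steps_decoded.csv")
    budget = hmm.state_budget(states)
    budget_df = pd.DataFrame({"state": hmm.STATE_NAMES, "proportion": budget})
    _write(budget_df, outdir / "state_budget.csv")
    results["state_budget"] = budget_df

    for covname in cfg.hmm_covariates:
        vals = steps[covname].to_numpy(dtype=float)
        grid = np.linspace(np.nanmin(vals), np.nanmax(vals), cfg.stationary_points)
        curve = hmm.stationary_curve(fit, covname, grid)
        _write(curve, outdir / f"stationary_{covname}.csv")
        results[f"stationary_{covname}"] = curve

    # serialized fit (natural + working scale)
    fit_json = {
        "loglik": fit.loglik, "n_steps": fit.n_steps, "converged": fit.converged,
        "covariates": list(fit.covariates),
        "emissions": {"mu": fit.emissions.mu.tolist(),
                      "sigma": fit.emissions.sigma.tolist(),
                      "zeromass": fit.emissions.zeromass.tolist(),
                      "angle_mean": fit.emissions.angle_mean.tolist(),
                      "rho": fit.emissions.rho.tolist()},
        "trans_beta": fit.trans_beta.tolist(),
        "working_theta": fit.theta.tolist(),
        "working_cov": fit.cov.tolist() if fit.cov is not None else None,
        "standardizer": {"means": fit.standardizer.means, "sds": fit.standardizer.sds}
        if fit.standardizer else None,
    }
    (outdir / "hmm_fit.json").write_text(json.dumps(fit_json, indent=1, sort_keys=True))


def _run_issf(cfg: RunConfig, steps, stack, outdir, results) -> dict:
    kernel = issf.fit_kernel(steps)
    strata, sacct = issf.build_strata(steps, stack, kernel,
                                      n_random=cfg.issf_n_random, seed=cfg.seed)
    _write(strata, outdir / "strata.csv")
    model_tab, fits = issf.compare_models(strata, cfg.issf_models)
    _write(model_tab, outdir / "issf_models.csv")
    results["issf_models"] = model_tab
    best_name = model_tab["model"].iloc[0]
    best = fits[best_name]
    coef_tab = best.table().assign(model=best_name)
    _write(coef_tab, outdir / "issf_coefficients.csv")
    results["issf_fit"] = best
    results["issf_fits"] = fits

    rss_rows = []
    for term, v1, v2 in cfg.rss_contrasts:
        fit_for = best if term in best.coef.index else None
        if fit_for is None:
            for f in fits.values():
                if term in f.coef.index:
                    fit_for = f
                    break
        if fit_for is None:
            continue
        std = fit_for.standardizer
        z1 = float(std.transform_value(term, v1)) if std and term in std.means else v1
        z2 = float(std.transform_value(term, v2)) if std and term in std.means else v2
        val, lo, hi = issf.rss(fit_for, {term: z1}, {term: z2})
        rss_rows.append({"model": fit_for.model, "term": term, "x1": v1, "x2": v2,
                         "rss": val, "lo": lo, "hi": hi})
    rss_tab = pd.DataFrame(rss_rows)
    _write(rss_tab, outdir / "rss.csv")
    results["rss"] = rss_tab
    return sacct


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    return str(o)


def _checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
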