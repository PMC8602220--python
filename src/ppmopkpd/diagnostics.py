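"""Model qualification: goodness-of-fit tables and visual predictive checks.

The VPC simulates replicate datasets at the observed design (same groups,
nominal times and per-cell sample sizes), adds residual error with the fitted
error models, applies the same LOQ rule to simulated and observed values, and
compares observed 10th/50th/90th percentiles per nominal-time bin against the
90% prediction interval of each percentile across simulations. Destructive
sampling yields shared nominal times, so bins are the exact nominal
timepoints.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .estimation import FitResult, _DesignCache

__all__ = ["VPCResult", "gof_table", "vpc", "fit_result_from_params"]

PERCENTILES = (10.0, 50.0, 90.0)


@dataclass
class VPCResult:
    """Binned VPC summary; one table row per (dvid, time, percentile)."""

    table: pd.DataFrame
    nsim: int
    seed: int | None
    loq_rule: str
    warnings: list[str] = field(default_factory=list)

    def outlier_fraction(self) -> float:
        ok = self.table["observed"].notna()
        return float(self.table.loc[ok, "outlier"].mean())


def _row_aligned(cache: _DesignCache) -> tuple[np.ndarray, np.ndarray]:
    """(time_day, group) arrays aligned with the cache's row order."""
    times = np.empty(cache.n)
    groups = np.empty(cache.n, dtype=object)
    for g in cache.groups:
        times[g["rows"]] = g["times"][g["time_idx"]]
        groups[g["rows"]] = g["name"]
    return times, groups


def _predictions(fit: FitResult, ds: Dataset) -> tuple[_DesignCache, np.ndarray]:
    if fit.stage == "plasma":
        sub = ds.subset(dvids=["cp"])
        cache = _DesignCache(sub)
        pred = cache.predict(fit.plasma_params())
    else:
        sub = ds.subset(dvids=["ct", "sk", "dys"])
        cache = _DesignCache(sub)
        params = fit.full_params()
        pred = cache.predict(params.plasma, params.tissue, params.transcript,
                             params.dystrophin,
                             pd_grid=fit.settings.get("pd_grid"))
    return cache, pred


def gof_table(fit: FitResult, ds: Dataset) -> pd.DataFrame:
    """Observed vs predicted with individual weighted residuals (IWRES).

    IWRES = (obs - pred)/sigma(pred) under the fitted error model; censored
    rows are flagged and carry no IWRES.
    """
    cache, pred = _predictions(fit, ds)
    sigma = np.empty_like(pred)
    for dvid in np.unique(cache.dvid):
        m = cache.dvid == dvid
        sigma[m] = fit.error_model(dvid).sigma(pred[m])
    iwres = (cache.dv - pred) / sigma
    iwres[cache.cens] = np.nan
    times, groups = _row_aligned(cache)
    out = pd.DataFrame({
        "group": groups, "time_day": times,
        "dvid": cache.dvid, "observed": cache.dv,
        "predicted": pred, "iwres": iwres,
        "censored": cache.cens.astype(int),
    })
    return out.sort_values(["dvid", "group", "time_day"]).reset_index(drop=True)


def vpc(fit: FitResult, ds: Dataset, nsim: int = 1500,
        seed: int | None = None, loq_rule: str = "drop") -> VPCResult:
    """Visual predictive check against the observed design.

    ``loq_rule="drop"`` removes values below the LOQ from both observed and
    simulated percentile computations (the same exclusion on both sides keeps
    them exchangeable); ``"half_loq"`` substitutes LOQ/2 instead.
    """
    if loq_rule not in ("drop", "half_loq"):
        raise ValueError(f"unknown loq_rule {loq_rule!r}")
    warnings: list[str] = []
    if nsim < 100:
        warnings.append(f"nsim={nsim} is too small for stable prediction intervals")
    cache, pred = _predictions(fit, ds)
    sigma = np.empty_like(pred)
    for dvid in np.unique(cache.dvid):
        m = cache.dvid == dvid
        sigma[m] = fit.error_model(dvid).sigma(pred[m])

    rng = np.random.default_rng(seed)
    sims = pred[None, :] + sigma[None, :] * rng.standard_normal((nsim, pred.size))
    for _ in range(1000):  # truncation at zero, as in the generator
        bad = sims <= 0
        if not bad.any():
            break
        sims[bad] = (np.broadcast_to(pred, sims.shape)[bad]
                     + np.broadcast_to(sigma, sims.shape)[bad]
                     * rng.standard_normal(int(bad.sum())))

    loq = cache.loq
    has_loq = np.isfinite(loq)
    obs_values = cache.dv.astype(float).copy()
    obs_mask = np.ones_like(obs_values, dtype=bool)
    sim_mask = np.ones_like(sims, dtype=bool)
    if loq_rule == "drop":
        obs_mask &= ~cache.cens
        sim_mask &= ~(has_loq[None, :] & (sims < loq[None, :]))
    else:
        obs_values[cache.cens] = loq[cache.cens] / 2.0
        low = has_loq[None, :] & (sims < loq[None, :])
        sims = np.where(low, np.broadcast_to(loq / 2.0, sims.shape), sims)

    times, _ = _row_aligned(cache)
    rows = []
    for dvid in sorted(np.unique(cache.dvid)):
        for t in sorted(np.unique(times[cache.dvid == dvid])):
            bin_rows = (cache.dvid == dvid) & (times == t)
            n_bin = int(bin_rows.sum())
            if n_bin < 10:
                small = True  # 10th/90th percentile extrapolative at this n
            else:
                small = False
            o = obs_values[bin_rows & obs_mask]
            obs_pct = (np.percentile(o, PERCENTILES) if o.size
                       else np.full(3, np.nan))
            sim_bin = sims[:, bin_rows]
            keep = sim_mask[:, bin_rows]
            sim_pct = np.full((nsim, 3), np.nan)
            for i in range(nsim):
                v = sim_bin[i, keep[i]]
                if v.size:
                    sim_pct[i] = np.percentile(v, PERCENTILES)
            valid = np.isfinite(sim_pct[:, 0])
            if valid.any():
                med = np.median(sim_pct[valid], axis=0)
                lo = np.percentile(sim_pct[valid], 5.0, axis=0)
                hi = np.percentile(sim_pct[valid], 95.0, axis=0)
            else:  # every simulation fully censored in this bin
                med = lo = hi = np.full(3, np.nan)
            for j, pct in enumerate(PERCENTILES):
                outlier = bool(np.isfinite(obs_pct[j]) and np.isfinite(lo[j])
                               and np.isfinite(hi[j])
                               and not (lo[j] <= obs_pct[j] <= hi[j]))
                rows.append({"dvid": dvid, "time_day": t, "percentile": pct,
                             "n_obs": int((bin_rows & obs_mask).sum()),
                             "observed": obs_pct[j], "sim_median": med[j],
                             "pi_lower": lo[j], "pi_upper": hi[j],
                             "outlier": outlier,
                             "extrapolative": small and pct != 50.0})
    table = pd.DataFrame(rows)
    return VPCResult(table=table, nsim=nsim, seed=seed, loq_rule=loq_rule,
                     warnings=warnings)


def fit_result_from_params(stage: str, params, error_models: dict,
                           fixed: dict | None = None) -> FitResult:
    """Wrap known parameters as a FitResult (for simulation-based workflows
    such as VPC self-coverage checks, where no fit is performed)."""
    from .params import PKPDParams, PlasmaPKParams

    estimates: dict[str, float] = {}
    fixed_out: dict[str, float] = dict(fixed or {})
    if stage == "plasma":
        assert isinstance(params, PlasmaPKParams)
        estimates.update({"Vc": params.vc, "kel": params.kel,
                          "k12": params.k12, "k21": params.k21,
                          "b_cp": error_models["cp"].b})
    elif stage == "tissue_pd":
        assert isinstance(params, PKPDParams)
        flat = params.to_dict()
        fixed_out.update({k: flat[k] for k in ("Vc", "kel", "k12", "k21",
                                               "skmRNA0", "Dys0")})
        for k in ("kpt", "kt1", "kt2", "k", "Vt", "Smax", "SC50", "kout_s",
                  "gamma_s", "S_Dys", "kout_Dys"):
            estimates[k] = flat[k]
        estimates.update({"b_ct": error_models["ct"].b,
                          "a_sk": error_models["sk"].a,
                          "b_sk": error_models["sk"].b,
                          "b_dys": error_models["dys"].b})
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return FitResult(stage=stage, estimates=estimates, fixed=fixed_out,
                     neg2ll=float("nan"), n_obs=0, converged=True,
                     n_starts=0, seed=0, message="constructed from parameters")
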