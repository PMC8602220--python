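"""Noncompartmental analysis of plasma concentration-time profiles.

AUC/AUMC use the linear log trapezoidal rule: the linear trapezoid on rising
or flat segments (and whenever a concentration is zero), the logarithmic
trapezoid on declining segments. The terminal slope lambda_z comes from an OLS
regression of ln(C) on t over a terminal window chosen by best adjusted R^2
among the last 3..N post-Tmax points. Exposure metrics follow the standard
definitions: AUCinf = AUClast + Clast/lambda_z, CL = Dose/AUCinf,
MRT = AUMCinf/AUCinf, Vss = CL*MRT.

Because sampling is destructive (one animal per datapoint), group profiles are
means per nominal timepoint; :func:`nca_by_group` applies that convention to a
long-format dataset.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = ["ConcProfile", "NCAResult", "auc_linlog", "terminal_slope",
           "run_nca", "nca_by_group", "NCAError", "NoTerminalPhaseError"]


class NCAError(ValueError):
    """Profile unsuitable for the requested NCA computation."""


class NoTerminalPhaseError(NCAError):
    """No declining terminal phase could be identified."""


@dataclass(frozen=True)
class ConcProfile:
    """A concentration-time profile (times in hours) with its dose amount.

    Units are the caller's responsibility; outputs are consistent with the
    inputs (e.g. ng + ng/mL + h gives CL in mL/h).
    """

    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    dose: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        c = np.asarray(self.concentrations, float)
        if t.size != c.size:
            raise NCAError("times and concentrations differ in length")
        if t.size and np.any(np.diff(t) <= 0):
            raise NCAError("times must be strictly increasing")
        if np.any(c < 0):
            raise NCAError("concentrations must be non-negative")
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "concentrations", tuple(c))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times, float), np.asarray(self.concentrations, float)


@dataclass(frozen=True)
class NCAResult:
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    aumc_inf: float
    t_half: float
    lambda_z: float
    cl: float
    vss: float
    mrt: float
    n_terminal_points: int
    r2_adj: float


def auc_linlog(profile: ConcProfile) -> tuple[float, float]:
    """(AUClast, AUMClast) by the linear log trapezoidal method."""
    t, c = profile.arrays()
    if t.size < 2:
        raise NCAError("at least 2 points are required for AUC")
    auc = 0.0
    aumc = 0.0
    for (t1, c1), (t2, c2) in zip(zip(t[:-1], c[:-1]), zip(t[1:], c[1:])):
        dt = t2 - t1
        if c2 < c1 and c1 > 0 and c2 > 0:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / (k * k)
        else:
            auc += dt * (c1 + c2) / 2.0
            aumc += dt * (t1 * c1 + t2 * c2) / 2.0
    return auc, aumc


def terminal_slope(profile: ConcProfile,
                   min_points: int = 3) -> tuple[float, float, int, float]:
    """(lambda_z, T_half, n_points, adjusted R^2) of the terminal phase.

    Candidate windows are the last m = min_points..N positive-concentration
    points after Tmax (Tmax itself included only when it is the first sample,
    i.e. an IV-bolus profile declining from the start); the window with the
    best adjusted R^2 of the ln(C)-vs-t regression wins. Raises
    :class:`NoTerminalPhaseError` when no window yields a negative slope.
    """
    t, c = profile.arrays()
    i_max = int(np.argmax(c))
    first = i_max if i_max == 0 else i_max + 1
    mask = (np.arange(t.size) >= first) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    if tt.size < min_points:
        raise NoTerminalPhaseError(
            f"need >= {min_points} positive post-Tmax points, have {tt.size}")
    best: tuple[float, float, int, float] | None = None
    for m in range(min_points, tt.size + 1):
        x, y = tt[-m:], cc[-m:]
        slope, intercept = np.polyfit(x, y, 1)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if slope >= 0 or ss_tot <= 0:  # flat or rising window: no decay signal
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(np.sum(resid ** 2))
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2) if m > 2 else r2
        if best is None or r2_adj > best[3]:
            best = (-slope, math.log(2.0) / -slope, m, r2_adj)
    if best is None:
        raise NoTerminalPhaseError("no candidate window has a negative slope")
    return best


def extrapolate_c0(profile: ConcProfile) -> float:
    """IV-bolus concentration at t=0 by log-linear back-extrapolation.

    Uses the first two positive concentrations; falls back to the first
    observed concentration when they are not declining (WinNonlin convention).
    """
    t, c = profile.arrays()
    pos = np.nonzero(c > 0)[0]
    if pos.size == 0:
        raise NCAError("no quantifiable concentrations in profile")
    if pos.size >= 2:
        i, j = pos[0], pos[1]
        if c[j] < c[i]:
            slope = (math.log(c[j]) - math.log(c[i])) / (t[j] - t[i])
            return float(c[i] * math.exp(-slope * t[i]))
    return float(c[pos[0]])


def run_nca(profile: ConcProfile, dose: float | None = None,
            iv_bolus: bool = True) -> NCAResult:
    """All standard exposure metrics of one profile.

    ``dose`` overrides the profile's own dose amount when given. With
    ``iv_bolus`` (default), a back-extrapolated C0 is prepended when the first
    sample is post-dose, so AUC/AUMC cover the unobserved initial segment;
    Cmax/Tmax remain the maximum *observed* concentration.
    """
    t, c = profile.arrays()
    dose = profile.dose if dose is None else dose
    if not np.any(c > 0):
        raise NCAError("no quantifiable concentrations in profile")
    if not (dose > 0):
        raise NCAError("a positive dose amount is required for CL and Vss")
    auc_profile = profile
    if iv_bolus and t[0] > 0:
        c0 = extrapolate_c0(profile)
        auc_profile = ConcProfile(times=(0.0, *t), concentrations=(c0, *c),
                                  dose=dose)
    auc_last, aumc_last = auc_linlog(auc_profile)
    lambda_z, t_half, n_term, r2_adj = terminal_slope(profile)
    pos = np.nonzero(c > 0)[0]
    t_last, c_last = t[pos[-1]], c[pos[-1]]
    auc_inf = auc_last + c_last / lambda_z
    aumc_inf = (aumc_last + c_last * t_last / lambda_z
                + c_last / (lambda_z ** 2))
    mrt = aumc_inf / auc_inf
    cl = dose / auc_inf
    vss = cl * mrt
    i_max = int(np.argmax(c))
    return NCAResult(cmax=float(c[i_max]), tmax=float(t[i_max]),
                     auc_last=auc_last, auc_inf=auc_inf, aumc_inf=aumc_inf,
                     t_half=t_half, lambda_z=lambda_z, cl=cl, vss=vss, mrt=mrt,
                     n_terminal_points=n_term, r2_adj=r2_adj)


def nca_by_group(ds: Dataset, bql: str = "exclude") -> pd.DataFrame:
    """NCA of the mean plasma profile per dose group (one row per group).

    BQL rows are excluded by default; ``bql="zero_before_tmax"`` substitutes 0
    for censored values collected before the group's observed Tmax. Times are
    converted from days to hours; CL and Vss are additionally scaled per kg
    using the group regimen's body weight.
    """
    if bql not in ("exclude", "zero_before_tmax"):
        raise ValueError(f"unknown BQL policy {bql!r}")
    rows = []
    for group in ds.groups():
        sub = ds.subset(dvids=["cp"], groups=[group])
        obs = sub.observations
        if obs.empty:
            continue
        regimen = sub.regimen(group)
        events = regimen.amounts_ng()
        if len(events) != 1:
            raise NCAError("NCA applies to single-dose profiles only")
        dose_ng = events[0][1]
        obs = obs.copy()
        if bql == "zero_before_tmax":
            means0 = obs[obs["cens"] == 0].groupby("time_day")["dv"].mean()
            tmax = means0.idxmax()
            obs.loc[(obs["cens"] == 1) & (obs["time_day"] <= tmax), "dv"] = 0.0
            obs = obs[(obs["cens"] == 0) | (obs["time_day"] <= tmax)]
        else:
            obs = obs[obs["cens"] == 0]
        means = obs.groupby("time_day")["dv"].mean()
        profile = ConcProfile(times=tuple(means.index * 24.0),
                              concentrations=tuple(means.to_numpy()),
                              dose=dose_ng)
        res = run_nca(profile)
        bw = regimen.body_weight_kg
        rows.append({
            "group": group, "dose_mgkg": float(sub.dose_rows["dose_mgkg"].iloc[0]),
            "t_half_h": res.t_half, "cmax_ng_ml": res.cmax,
            "auc_inf_h_ng_ml": res.auc_inf, "cl_ml_h": res.cl,
            "cl_ml_h_kg": res.cl / bw, "vss_ml": res.vss, "vss_ml_kg": res.vss / bw,
            "mrt_h": res.mrt, "lambda_z_1_h": res.lambda_z,
            "n_terminal": res.n_terminal_points, "r2_adj": res.r2_adj,
        })
    return pd.DataFrame(rows)
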