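"""Naive-pooled maximum-likelihood estimation with interval-censored BQL data.

Destructive sampling leaves one observation per animal, so inter-individual
variability is not estimable: all animals in a dose group are pooled as if they
were a single subject and the likelihood has no latent random effects. Direct
maximization of the pooled likelihood therefore replaces stochastic EM.

Residual error is proportional (sigma = b*pred) for plasma, tissue and
dystrophin data and combined (sigma = sqrt(a^2 + (b*pred)^2)) for the skipped
transcript. Observations below the limit of quantification enter the
likelihood as interval-censored: P(0 < Y < LOQ). Quantifiable observations
are, symmetrically, conditioned on being positive (truncated-normal
normalizer); a flag disables that conditioning for comparison.

Estimation is sequential: the plasma block is fit first on plasma data alone,
then fixed while the tissue PK and both indirect-response blocks are fit
jointly to tissue concentration, skipped transcript and dystrophin data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import qmc

from .data import DVIDS, Dataset
from .model import simulate_full, simulate_plasma
from .params import (
    DystrophinPDParams,
    PKPDParams,
    PlasmaPKParams,
    TissuePKParams,
    TranscriptPDParams,
)

__all__ = [
    "ErrorModel", "Observation", "FitSettings", "FitResult",
    "EstimationError", "NonIdentifiableError", "UncertaintyUnavailableError",
    "obs_loglik", "total_negloglik", "predict_dataset",
    "fit_plasma", "fit_tissue_pd", "compute_rse",
    "DEFAULT_ERROR_MODELS", "PLASMA_STRUCTURAL", "TISSUE_STRUCTURAL",
]

SIGMA_FLOOR = 1e-10

PLASMA_STRUCTURAL = ("Vc", "kel", "k12", "k21")
TISSUE_STRUCTURAL = ("kpt", "kt1", "kt2", "k", "Vt", "Smax", "SC50",
                     "kout_s", "gamma_s", "S_Dys", "kout_Dys")

#: Hill-coefficient box; unbounded exponents destabilize small-n fits.
GAMMA_BOUNDS = (0.1, 10.0)

# grid used inside likelihood evaluations; coarser than the simulation default
# but still ~3e-5 relative accuracy, far below residual noise
FIT_PD_GRID = {"h_early": 0.005, "early_span": 0.5, "h_late": 0.02}


class EstimationError(RuntimeError):
    """Likelihood maximization failed or the data carry no information."""


class NonIdentifiableError(EstimationError):
    """The dataset structurally cannot identify a requested parameter block."""


class UncertaintyUnavailableError(EstimationError):
    """The observed Fisher information is singular and no fallback was enabled."""


@dataclass(frozen=True)
class ErrorModel:
    """Residual error model: proportional (b) or combined (a, b)."""

    kind: str = "proportional"
    b: float = 0.2
    a: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "combined"):
            raise ValueError(f"unknown error model kind {self.kind!r}")
        if not (self.b > 0):
            raise ValueError("proportional CV b must be > 0")
        if self.kind == "proportional" and self.a != 0.0:
            raise ValueError("proportional error model must have a = 0")
        if self.a < 0:
            raise ValueError("additive SD a must be >= 0")

    def sigma(self, pred: np.ndarray) -> np.ndarray:
        pred = np.asarray(pred, dtype=float)
        if self.kind == "proportional":
            s = self.b * np.abs(pred)
        else:
            s = np.sqrt(self.a ** 2 + (self.b * pred) ** 2)
        return np.maximum(s, SIGMA_FLOOR)


DEFAULT_ERROR_MODELS: dict[str, ErrorModel] = {
    "cp": ErrorModel("proportional", b=0.2),
    "ct": ErrorModel("proportional", b=0.2),
    "sk": ErrorModel("combined", a=0.1, b=0.2),
    "dys": ErrorModel("proportional", b=0.2),
}


@dataclass(frozen=True)
class Observation:
    """A single measurement (or BQL bound) from one animal."""

    animal: str
    group: str
    time_day: float
    dvid: str
    value: float
    censored: bool = False
    loq: float | None = None


def _loglik_terms(dv: np.ndarray, pred: np.ndarray, cens: np.ndarray,
                  loq: np.ndarray, sigma: np.ndarray,
                  truncate: bool = True) -> np.ndarray:
    """Per-observation log-likelihood contributions (vectorized)."""
    dv = np.asarray(dv, float)
    pred = np.asarray(pred, float)
    sigma = np.asarray(sigma, float)
    cens = np.asarray(cens, bool)
    out = np.empty_like(dv)

    unc = ~cens
    z = (dv[unc] - pred[unc]) / sigma[unc]
    ll = -0.5 * z * z - np.log(sigma[unc]) - 0.5 * math.log(2.0 * math.pi)
    if truncate:
        ll -= log_ndtr(pred[unc] / sigma[unc])
    out[unc] = ll

    if cens.any():
        lo = ndtr(-pred[cens] / sigma[cens])
        hi = ndtr((np.asarray(loq, float)[cens] - pred[cens]) / sigma[cens])
        prob = np.clip(hi - lo, 1e-300, None)
        if truncate:
            prob = prob / np.clip(1.0 - lo, 1e-300, None)
        out[cens] = np.log(prob)
    return out


def obs_loglik(observed: Observation, pred: float, em: ErrorModel,
               truncate: bool = True) -> float:
    """Log-likelihood contribution of one observation given its prediction."""
    if pred < 0:
        raise ValueError("model prediction must be non-negative")
    sigma = em.sigma(np.array([pred]))
    loq = observed.loq if observed.loq is not None else np.nan
    if observed.censored and not np.isfinite(loq):
        raise ValueError("censored observation requires a finite LOQ")
    return float(_loglik_terms(
        np.array([observed.value]), np.array([pred]),
        np.array([observed.censored]), np.array([loq]), sigma,
        truncate=truncate)[0])


# ---------------------------------------------------------------------------
# dataset predictions

class _DesignCache:
    """Pre-extracted per-group arrays so likelihood evaluations avoid pandas."""

    def __init__(self, ds: Dataset):
        obs = ds.observations
        self.dv = obs["dv"].to_numpy(float)
        self.cens = obs["cens"].to_numpy(int).astype(bool)
        self.loq = obs["loq"].to_numpy(float)
        self.dvid = obs["dvid"].to_numpy()
        self.n = len(obs)
        self.groups = []
        rows = np.arange(self.n)
        group_values = obs["group"].to_numpy()
        times_all = obs["time_day"].to_numpy(float)
        for g in np.unique(group_values):
            mask = group_values == g
            times = np.unique(times_all[mask])
            time_idx = np.searchsorted(times, times_all[mask])
            self.groups.append({
                "name": g,
                "regimen": ds.regimen(g),
                "times": times,
                "rows": rows[mask],
                "time_idx": time_idx,
                "dvid": self.dvid[mask],
            })

    def predict(self, plasma: PlasmaPKParams,
                tissue: TissuePKParams | None = None,
                transcript: TranscriptPDParams | None = None,
                dystrophin: DystrophinPDParams | None = None,
                pd_grid: dict | None = None, method: str = "fast") -> np.ndarray:
        pred = np.empty(self.n)
        plasma_only = tissue is None
        for g in self.groups:
            if plasma_only:
                traj = simulate_plasma(plasma, g["regimen"], g["times"])
            else:
                traj = simulate_full(plasma, tissue, transcript, dystrophin,
                                     g["regimen"], g["times"], method=method,
                                     pd_grid=pd_grid)
            for dvid in DVIDS:
                m = g["dvid"] == dvid
                if m.any():
                    pred[g["rows"][m]] = traj.observable(dvid)[g["time_idx"][m]]
        return pred

    def negloglik(self, pred: np.ndarray, ems: Mapping[str, ErrorModel],
                  truncate: bool = True) -> float:
        sigma = np.empty(self.n)
        for dvid in np.unique(self.dvid):
            m = self.dvid == dvid
            sigma[m] = ems[dvid].sigma(pred[m])
        return -float(np.sum(_loglik_terms(self.dv, pred, self.cens, self.loq,
                                           sigma, truncate=truncate)))


def predict_dataset(ds: Dataset, plasma: PlasmaPKParams,
                    tissue: TissuePKParams | None = None,
                    transcript: TranscriptPDParams | None = None,
                    dystrophin: DystrophinPDParams | None = None,
                    pd_grid: dict | None = None, method: str = "fast") -> np.ndarray:
    """Model predictions aligned with ``ds.observations`` rows.

    With only plasma parameters, the dataset must contain cp observations only.
    """
    if tissue is None and set(ds.dvids()) - {"cp"}:
        raise ValueError("tissue/PD parameters required for non-plasma observations")
    return _DesignCache(ds).predict(plasma, tissue, transcript, dystrophin,
                                    pd_grid=pd_grid, method=method)


def total_negloglik(ds: Dataset, params: PKPDParams,
                    ems: Mapping[str, ErrorModel] | None = None,
                    truncate: bool = True, pd_grid: dict | None = None,
                    method: str = "fast") -> float:
    """-sum of per-observation log-likelihood over the whole dataset."""
    if len(ds) == 0:
        return 0.0
    ems = dict(DEFAULT_ERROR_MODELS, **(ems or {}))
    cache = _DesignCache(ds)
    pred = cache.predict(params.plasma, params.tissue, params.transcript,
                         params.dystrophin, pd_grid=pd_grid, method=method)
    return cache.negloglik(pred, ems, truncate=truncate)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitSettings:
    """Optimizer controls for the naive-pooled maximum-likelihood fits."""

    n_starts: int = 5
    seed: int = 12345
    maxiter: int = 1000
    ftol: float = 1e-9
    gtol: float = 1e-7
    spread: float = 3.0          # multiplicative LHS half-range around init
    truncate: bool = True        # condition quantifiable data on Y > 0
    log_bound_width: float = 7.0  # +- bound (natural log) around init
    pd_grid: dict = field(default_factory=lambda: dict(FIT_PD_GRID))


@dataclass
class FitResult:
    """Estimates with provenance; rate constants in 1/day, volumes in mL."""

    stage: str
    estimates: dict[str, float]
    fixed: dict[str, float]
    neg2ll: float
    n_obs: int
    converged: bool
    n_starts: int
    seed: int
    message: str = ""
    rse: dict[str, float] | None = None
    settings: dict = field(default_factory=dict)

    def error_model(self, dvid: str) -> ErrorModel:
        values = {**self.fixed, **self.estimates}
        if dvid == "sk":
            return ErrorModel("combined", a=values["a_sk"], b=values["b_sk"])
        return ErrorModel("proportional", b=values[f"b_{dvid}"])

    def plasma_params(self) -> PlasmaPKParams:
        v = {**self.fixed, **self.estimates}
        return PlasmaPKParams(vc=v["Vc"], kel=v["kel"], k12=v["k12"], k21=v["k21"])

    def full_params(self) -> PKPDParams:
        """Full cascade parameters (tissue-stage fits only)."""
        v = {**self.fixed, **self.estimates}
        keys = ("Vc", "kel", "k12", "k21", "kpt", "kt1", "kt2", "k", "Vt", "Smax",
                "SC50", "kout_s", "gamma_s", "skmRNA0", "S_Dys", "kout_Dys", "Dys0")
        return PKPDParams.from_dict({k: v[k] for k in keys})


def _multistart_minimize(objective: Callable[[np.ndarray], float],
                         x0: np.ndarray, bounds: list[tuple[float, float]],
                         settings: FitSettings) -> tuple[optimize.OptimizeResult, int]:
    """L-BFGS-B from the supplied start plus latin-hypercube perturbations."""
    starts = [x0]
    if settings.n_starts > 1:
        sampler = qmc.LatinHypercube(d=x0.size, seed=settings.seed)
        u = sampler.random(settings.n_starts - 1)
        half = math.log(settings.spread)
        lo = np.maximum(x0 - half, [b[0] for b in bounds])
        hi = np.minimum(x0 + half, [b[1] for b in bounds])
        starts.extend(lo + u_i * (hi - lo) for u_i in u)
    best = None
    for start in starts:
        res = optimize.minimize(
            objective, start, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": settings.maxiter, "ftol": settings.ftol,
                     "gtol": settings.gtol})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise EstimationError("all optimizer starts failed to produce a finite "
                              "likelihood")
    return best, len(starts)


_OBJ_CAP = 1e8


def _guarded(objective: Callable[[np.ndarray], float]) -> Callable[[np.ndarray], float]:
    """Numerical armour for the optimizer: failures map to a large value and
    astronomically bad points are soft-capped (log-compressed above 1e8) so
    the L-BFGS-B line search can still interpolate back into the basin."""
    def wrapped(theta: np.ndarray) -> float:
        try:
            value = objective(theta)
        except (FloatingPointError, np.linalg.LinAlgError, OverflowError):
            return 2.0 * _OBJ_CAP
        if not np.isfinite(value):
            return 2.0 * _OBJ_CAP
        if value > _OBJ_CAP:
            return _OBJ_CAP * (1.0 + math.log(value / _OBJ_CAP))
        return value
    return wrapped


def fit_plasma(ds: Dataset, init: PlasmaPKParams,
               settings: FitSettings | None = None,
               b_init: float = 0.2, fix_b: float | None = None) -> FitResult:
    """Stage 1: fit (Vc, kel, k12, k21) + proportional error to plasma data.

    Parameters are optimized on the natural-log scale; the proportional CV is
    estimated jointly unless pinned via ``fix_b`` (useful for noise-free
    identifiability checks). Raises :class:`EstimationError` when every
    observation is BQL-censored.
    """
    settings = settings or FitSettings()
    ds_cp = ds.subset(dvids=["cp"])
    if len(ds_cp) == 0:
        raise EstimationError("no plasma (cp) observations in dataset")
    cache = _DesignCache(ds_cp)
    if cache.cens.all():
        raise EstimationError("all plasma observations are censored; "
                              "no quantifiable information")
    names = ["Vc", "kel", "k12", "k21"]
    x0_values = [init.vc, init.kel, init.k12, init.k21]
    if fix_b is None:
        names.append("b_cp")
        x0_values.append(b_init)
    x0 = np.log(x0_values)
    w = settings.log_bound_width
    bounds = [(xi - w, xi + w) for xi in x0]

    def objective(theta: np.ndarray) -> float:
        v = dict(zip(names, np.exp(theta)))
        b = fix_b if fix_b is not None else v["b_cp"]
        pred = cache.predict(PlasmaPKParams(vc=v["Vc"], kel=v["kel"],
                                            k12=v["k12"], k21=v["k21"]))
        return cache.negloglik(pred, {"cp": ErrorModel("proportional", b=b)},
                               truncate=settings.truncate)

    best, n_starts = _multistart_minimize(_guarded(objective), x0, bounds, settings)
    estimates = dict(zip(names, np.exp(best.x)))
    fixed = {} if fix_b is None else {"b_cp": fix_b}
    return FitResult(
        stage="plasma", estimates=estimates, fixed=fixed,
        neg2ll=2.0 * best.fun, n_obs=cache.n, converged=bool(best.success),
        n_starts=n_starts, seed=settings.seed, message=str(best.message),
        settings={"truncate": settings.truncate, "ftol": settings.ftol},
    )


def fit_tissue_pd(ds: Dataset, plasma: PlasmaPKParams, init: PKPDParams,
                  settings: FitSettings | None = None,
                  fixed: Mapping[str, float] | None = None,
                  error_init: Mapping[str, ErrorModel] | None = None) -> FitResult:
    """Stage 2: joint fit of tissue PK and both indirect-response blocks.

    The plasma block is immutable (sequential approach); the transcript and
    dystrophin baselines are fixed (skmRNA0 = 1.3 copies/30 ng RNA,
    Dys0 = 0.10 %WT) unless overridden via ``fixed``. ``fixed`` may also pin
    any structural or error parameter (e.g. ``{"Vt": 0.21}``): the tissue
    observables constrain kpt and Vt only through their ratio, so fixing one
    of the pair restores an invertible information matrix.
    """
    settings = settings or FitSettings()
    fixed = dict({"skmRNA0": init.transcript.skmrna0, "Dys0": init.dystrophin.dys0},
                 **(fixed or {}))
    ds_t = ds.subset(dvids=["ct", "sk", "dys"])
    present = set(ds_t.dvids())
    required = {"ct": "tissue PK block", "sk": "transcript stimulation block",
                "dys": "dystrophin block"}
    for dvid, block in required.items():
        if dvid not in present:
            raise NonIdentifiableError(
                f"dataset lacks dvid={dvid!r}; the {block} is not identifiable")
    cache = _DesignCache(ds_t)
    if cache.cens.all():
        raise EstimationError("all tissue/PD observations are censored")

    ems0 = dict(DEFAULT_ERROR_MODELS, **(error_init or {}))
    all_names = list(TISSUE_STRUCTURAL) + ["b_ct", "a_sk", "b_sk", "b_dys"]
    t, s, d = init.tissue, init.transcript, init.dystrophin
    init_values = {
        "kpt": t.kpt, "kt1": t.kt1, "kt2": t.kt2, "k": t.k, "Vt": t.vt,
        "Smax": s.smax, "SC50": s.sc50, "kout_s": s.kout_s, "gamma_s": s.gamma_s,
        "S_Dys": d.s_dys, "kout_Dys": d.kout_dys,
        "b_ct": ems0["ct"].b, "a_sk": max(ems0["sk"].a, 1e-3),
        "b_sk": ems0["sk"].b, "b_dys": ems0["dys"].b,
    }
    pinned = {n: float(fixed[n]) for n in all_names if n in fixed}
    names = [n for n in all_names if n not in pinned]
    x0 = np.log([init_values[n] for n in names])
    w = settings.log_bound_width
    bounds = [(xi - w, xi + w) for xi in x0]
    if "gamma_s" in names:
        bounds[names.index("gamma_s")] = (math.log(GAMMA_BOUNDS[0]),
                                          math.log(GAMMA_BOUNDS[1]))
    sk0 = fixed["skmRNA0"]
    dys0 = fixed["Dys0"]

    def objective(theta: np.ndarray) -> float:
        v = dict(pinned, **dict(zip(names, np.exp(theta))))
        tissue = TissuePKParams(kpt=v["kpt"], kt1=v["kt1"], kt2=v["kt2"],
                                k=v["k"], vt=v["Vt"])
        transcript = TranscriptPDParams(smax=v["Smax"], sc50=v["SC50"],
                                        kout_s=v["kout_s"], gamma_s=v["gamma_s"],
                                        skmrna0=sk0)
        dystrophin = DystrophinPDParams(s_dys=v["S_Dys"], kout_dys=v["kout_Dys"],
                                        dys0=dys0)
        pred = cache.predict(plasma, tissue, transcript, dystrophin,
                             pd_grid=settings.pd_grid)
        ems = {"ct": ErrorModel("proportional", b=v["b_ct"]),
               "sk": ErrorModel("combined", a=v["a_sk"], b=v["b_sk"]),
               "dys": ErrorModel("proportional", b=v["b_dys"])}
        return cache.negloglik(pred, ems, truncate=settings.truncate)

    best, n_starts = _multistart_minimize(_guarded(objective), x0, bounds, settings)
    estimates = dict(zip(names, np.exp(best.x)))
    fixed_out = dict(fixed)
    fixed_out.update({"Vc": plasma.vc, "kel": plasma.kel,
                      "k12": plasma.k12, "k21": plasma.k21})
    return FitResult(
        stage="tissue_pd", estimates=estimates, fixed=fixed_out,
        neg2ll=2.0 * best.fun, n_obs=cache.n, converged=bool(best.success),
        n_starts=n_starts, seed=settings.seed, message=str(best.message),
        settings={"truncate": settings.truncate, "ftol": settings.ftol,
                  "pd_grid": dict(settings.pd_grid)},
    )


def _rebuild_objective(fit: FitResult, ds: Dataset,
                       truncate: bool | None = None
                       ) -> tuple[Callable[[np.ndarray], float], list[str], np.ndarray]:
    """Negative log-likelihood as a function of the fit's free log-parameters."""
    truncate = fit.settings.get("truncate", True) if truncate is None else truncate
    names = list(fit.estimates)
    theta_hat = np.log([fit.estimates[n] for n in names])
    if fit.stage == "plasma":
        cache = _DesignCache(ds.subset(dvids=["cp"]))

        def objective(theta: np.ndarray) -> float:
            v = dict(zip(names, np.exp(theta)))
            b = fit.fixed.get("b_cp", v.get("b_cp"))
            pred = cache.predict(PlasmaPKParams(vc=v["Vc"], kel=v["kel"],
                                                k12=v["k12"], k21=v["k21"]))
            return cache.negloglik(pred, {"cp": ErrorModel("proportional", b=b)},
                                   truncate=truncate)
    elif fit.stage == "tissue_pd":
        cache = _DesignCache(ds.subset(dvids=["ct", "sk", "dys"]))
        plasma = fit.plasma_params()
        sk0, dys0 = fit.fixed["skmRNA0"], fit.fixed["Dys0"]
        pd_grid = fit.settings.get("pd_grid") or dict(FIT_PD_GRID)
        pinnable = set(TISSUE_STRUCTURAL) | {"b_ct", "a_sk", "b_sk", "b_dys"}
        pinned = {k: v for k, v in fit.fixed.items() if k in pinnable}

        def objective(theta: np.ndarray) -> float:
            v = dict(pinned, **dict(zip(names, np.exp(theta))))
            pred = cache.predict(
                plasma,
                TissuePKParams(kpt=v["kpt"], kt1=v["kt1"], kt2=v["kt2"],
                               k=v["k"], vt=v["Vt"]),
                TranscriptPDParams(smax=v["Smax"], sc50=v["SC50"],
                                   kout_s=v["kout_s"], gamma_s=v["gamma_s"],
                                   skmrna0=sk0),
                DystrophinPDParams(s_dys=v["S_Dys"], kout_dys=v["kout_Dys"],
                                   dys0=dys0),
                pd_grid=pd_grid)
            ems = {"ct": ErrorModel("proportional", b=v["b_ct"]),
                   "sk": ErrorModel("combined", a=v["a_sk"], b=v["b_sk"]),
                   "dys": ErrorModel("proportional", b=v["b_dys"])}
            return cache.negloglik(pred, ems, truncate=truncate)
    else:
        raise ValueError(f"unknown fit stage {fit.stage!r}")
    return _guarded(objective), names, theta_hat


def compute_rse(fit: FitResult, ds: Dataset,
                bootstrap: int | None = None,
                seed: int | None = None) -> dict[str, float]:
    """Relative standard errors (%) from the observed Fisher information.

    The Hessian of the negative log-likelihood is taken with respect to the
    log-transformed parameters, so sqrt(diag(H^-1)) is directly the relative
    SE (delta method); RSE% = 100 * SE / estimate. Fixed parameters carry no
    RSE. If the Hessian is not positive definite, a nonparametric bootstrap
    (resampling animals within design cells) is used when ``bootstrap`` is a
    replicate count, otherwise :class:`UncertaintyUnavailableError` is raised.
    """
    from statsmodels.tools.numdiff import approx_hess

    objective, names, theta_hat = _rebuild_objective(fit, ds)
    hess = approx_hess(theta_hat, objective)
    rse: dict[str, float] | None = None
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.all(diag > 0):
            rse = {n: 100.0 * math.sqrt(v) for n, v in zip(names, diag)}
    except np.linalg.LinAlgError:
        rse = None
    if rse is None:
        if not bootstrap:
            raise UncertaintyUnavailableError(
                "observed information matrix is not positive definite; "
                "pass bootstrap=<n> to enable the resampling fallback")
        rse = _bootstrap_rse(fit, ds, n_boot=bootstrap, seed=seed)
    fit.rse = rse
    return rse


def _bootstrap_rse(fit: FitResult, ds: Dataset, n_boot: int,
                   seed: int | None) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    obs = ds.observations
    dose = ds.dose_rows
    draws: list[np.ndarray] = []
    settings = FitSettings(n_starts=1, seed=int(rng.integers(2 ** 31)))
    for _ in range(n_boot):
        parts = [dose]
        for _, cell in obs.groupby(["group", "time_day", "dvid"], sort=False):
            parts.append(cell.sample(n=len(cell), replace=True,
                                     random_state=int(rng.integers(2 ** 31))))
        import pandas as pd
        boot = Dataset(pd.concat(parts, ignore_index=True), dict(ds.metadata))
        try:
            if fit.stage == "plasma":
                refit = fit_plasma(boot, fit.plasma_params(), settings,
                                   b_init=fit.estimates["b_cp"])
            else:
                refit = fit_tissue_pd(boot, fit.plasma_params(),
                                      fit.full_params(), settings)
        except EstimationError:
            continue
        draws.append(np.log([refit.estimates[n] for n in fit.estimates]))
    if len(draws) < 2:
        raise UncertaintyUnavailableError("bootstrap produced too few successful fits")
    sd = np.std(np.vstack(draws), axis=0, ddof=1)
    return {n: 100.0 * s for n, s in zip(fit.estimates, sd)}
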