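"""Dose-proportionality assessment of plasma exposure.

Two complementary analyses:

* Power model y = alpha * dose^beta, fit by OLS on the log-log scale. PK is
  declared dose-proportional when the 90% CI of beta contains 1 and lies
  inside a prespecified equivalence interval scaled to the tested dose range
  (the Hummel criterion): (betaL, betaU) = 1 + ln(phi)/ln(r) with default
  equivalence bounds phi = (0.5, 2) and r the highest/lowest dose ratio.
* One-way ANOVA on dose-normalized exposures with pairwise comparisons
  (unadjusted pooled-variance t tests; Tukey HSD behind a flag).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["PowerModelResult", "AnovaResult", "fit_power_model",
           "hummel_interval", "assess_linearity", "anova_dose_normalized"]


@dataclass(frozen=True)
class PowerModelResult:
    alpha: float
    beta: float
    ci90: tuple[float, float]
    se_beta: float
    n: int
    hci: tuple[float, float] | None = None
    verdict: str | None = None
    reason: str | None = None


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    pairwise: dict[tuple[float, float], float]
    method: str


def fit_power_model(doses: Sequence[float],
                    exposures: Sequence[float]) -> PowerModelResult:
    """OLS of ln(exposure) on ln(dose); 90% CI on beta from the t(n-2) quantile."""
    d = np.asarray(doses, float)
    y = np.asarray(exposures, float)
    if d.size != y.size or d.size < 3:
        raise ValueError("need >= 3 paired (dose, exposure) observations")
    if np.any(d <= 0) or np.any(y <= 0):
        raise ValueError("doses and exposures must be positive for the log-log fit")
    if np.unique(d).size < 2:
        raise ValueError("power model is rank-deficient with a single dose level")
    import statsmodels.api as sm

    x = sm.add_constant(np.log(d))
    res = sm.OLS(np.log(y), x).fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    if np.isnan(se):  # zero-residual (exactly proportional) degenerate fit
        se = 0.0
    ci = res.conf_int(alpha=0.10)  # t-quantile based, n-2 df
    lo = beta - 0.0 if np.isnan(ci[1, 0]) else float(ci[1, 0])
    hi = beta + 0.0 if np.isnan(ci[1, 1]) else float(ci[1, 1])
    return PowerModelResult(alpha=math.exp(float(res.params[0])), beta=beta,
                            ci90=(lo, hi), se_beta=se, n=int(d.size))


def hummel_interval(r: float, phi_l: float = 0.5,
                    phi_u: float = 2.0) -> tuple[float, float]:
    """Prespecified equivalence interval for beta scaled to the dose ratio r."""
    if not (r > 1):
        raise ValueError(f"dose ratio r must exceed 1, got {r!r}")
    if not (0 < phi_l < 1 < phi_u):
        raise ValueError("equivalence bounds must satisfy 0 < phi_l < 1 < phi_u")
    lr = math.log(r)
    return (1.0 + math.log(phi_l) / lr, 1.0 + math.log(phi_u) / lr)


def assess_linearity(pm: PowerModelResult,
                     hci: tuple[float, float]) -> PowerModelResult:
    """Attach the equivalence verdict: linear, nonlinear, or inconclusive.

    linear        CI inside the equivalence interval and containing 1
    nonlinear     CI not contained in the equivalence interval
    inconclusive  CI inside the interval but excluding 1 (equivalent to
                  proportional within the prespecified margin, yet the point
                  estimate is significantly off unity)
    """
    lo, hi = pm.ci90
    contained = hci[0] <= lo and hi <= hci[1]
    includes_one = lo <= 1.0 <= hi
    if contained and includes_one:
        verdict, reason = "linear", "90% CI within equivalence interval and contains 1"
    elif not contained:
        side = []
        if lo < hci[0]:
            side.append(f"lower CI {lo:.3g} < {hci[0]:.3g}")
        if hi > hci[1]:
            side.append(f"upper CI {hi:.3g} > {hci[1]:.3g}")
        verdict, reason = "nonlinear", "containment failed: " + "; ".join(side)
    else:
        verdict, reason = "inconclusive", "CI within equivalence interval but excludes 1"
    return replace(pm, hci=tuple(hci), verdict=verdict, reason=reason)


def anova_dose_normalized(exposures_by_dose: Mapping[float, Sequence[float]],
                          tukey: bool = False) -> AnovaResult:
    """One-way ANOVA on exposure/dose with all pairwise dose comparisons.

    Pairwise p-values are unadjusted two-sample pooled-variance t tests by
    default; ``tukey=True`` switches to Tukey HSD.
    """
    groups = {float(d): np.asarray(v, float) / float(d)
              for d, v in exposures_by_dose.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 dose groups")
    if any(g.size < 2 for g in groups.values()):
        raise ValueError("need >= 2 animals per group")
    if all(np.allclose(g, g[0]) for g in groups.values()):
        raise ValueError("zero within-group variance in every group: "
                         "ANOVA is degenerate")
    values = list(groups.values())
    f, p = stats.f_oneway(*values)
    pairwise: dict[tuple[float, float], float] = {}
    if tukey:
        doses = sorted(groups)
        res = stats.tukey_hsd(*(groups[d] for d in doses))
        for i, j in combinations(range(len(doses)), 2):
            pairwise[(doses[i], doses[j])] = float(res.pvalue[i, j])
        method = "tukey_hsd"
    else:
        for d1, d2 in combinations(sorted(groups), 2):
            _, pt = stats.ttest_ind(groups[d1], groups[d2], equal_var=True)
            pairwise[(d1, d2)] = float(pt)
        method = "unadjusted_t"
    return AnovaResult(f=float(f), p=float(p), pairwise=pairwise, method=method)
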