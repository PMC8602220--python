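"""Noncompartmental analysis and dose-proportionality of plasma exposure.

Generates the single-dose plasma study (10/40/80 mg/kg, n=3 per timepoint,
destructive sampling), runs NCA on the mean profile per dose group, then asks
whether exposure grows proportionally with dose using the power model with the
Hummel equivalence interval and ANOVA on dose-normalized Cmax.
"""
import numpy as np

from ppmopkpd import (
    anova_dose_normalized,
    assess_linearity,
    fit_power_model,
    generate_study,
    hummel_interval,
    nca_by_group,
    study_designs,
    reference_estimates,
)

params = reference_estimates()
design = study_designs()["plasma_single"]
ds = generate_study(design, params, seed=2024)

table = nca_by_group(ds)
print("NCA per dose group (mean profile, linear log trapezoidal):")
cols = ["dose_mgkg", "t_half_h", "cmax_ng_ml", "auc_inf_h_ng_ml", "cl_ml_h_kg",
        "vss_ml_kg"]
print(table[cols].round(2).to_string(index=False))

doses = table["dose_mgkg"].to_numpy()
hci = hummel_interval(doses.max() / doses.min())
print(f"\nHummel equivalence interval for r={doses.max() / doses.min():g}: "
      f"({hci[0]:.2f}, {hci[1]:.2f})")
for metric in ("cmax_ng_ml", "auc_inf_h_ng_ml"):
    pm = assess_linearity(fit_power_model(doses, table[metric]), hci)
    print(f"  {metric:16s} beta={pm.beta:5.2f}  90% CI "
          f"({pm.ci90[0]:5.2f}, {pm.ci90[1]:5.2f})  -> {pm.verdict} "
          f"({pm.reason})")
print("  (group means from n=3 give wide CIs; individual-animal exposures "
      "sharpen the verdict)")

obs = ds.observations
cmax_rows = obs[obs["time_day"] == obs["time_day"].min()]  # 5 min samples
groups = {d: g["dv"].to_numpy() for d, g in cmax_rows.groupby("dose_mgkg")}
res = anova_dose_normalized(groups)
print(f"\nANOVA on dose-normalized 5-min concentration: "
      f"F={res.f:.2f}, p={res.p:.3f}")
for pair, p in res.pairwise.items():
    print(f"  {pair[0]:g} vs {pair[1]:g} mg/kg: p={p:.3f}")
verdict = ("no significant departure from dose proportionality"
           if res.p >= 0.05 else "significant departure flagged")
print(f"overall ANOVA at the 5% level: {verdict} "
      "(the generating model is linear; n=3/group keeps power low and "
      "individual pairwise p-values noisy)")
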