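# Methods

## The model

`ppmopkpd` implements a semi-mechanistic cascade linking IV bolus dosing of a
peptide-conjugated phosphorodiamidate morpholino oligomer (PPMO) in mdx mice to
dystrophin restoration in skeletal muscle. Four linear drug states (amounts in
ng) feed two nonlinear turnover states:

```
dAc/dt   = k21·Aper − (kel + k12)·Ac          Ac(0)  = Dose
dAper/dt = k12·Ac − k21·Aper                  Aper(0) = 0
Cp = Ac/Vc

dAt/dt   = kpt·Ac + kt2·A1 − (kt1 + k)·At     At(0)  = 0
dA1/dt   = kt1·At − kt2·A1                    A1(0)  = 0
Ct = At/Vt        C1 = A1·kt1/(kt2·Vt)

d[sk]/dt  = kin_s·(1 + Smax·C1^γ/(SC50^γ + C1^γ)) − kout_s·[sk]
d[Dys]/dt = kin_Dys·(1 + S_Dys·([sk] − skmRNA0)) − kout_Dys·[Dys]
kin_s = skmRNA0·kout_s        kin_Dys = Dys0·kout_Dys
```

Assumptions worth spelling out:

- **One-way biophase.** The transfer `kpt·Ac` into muscle has no matching loss
  term in the plasma equation. Plasma PPMO dissipates within hours (terminal
  half-life 0.70 h) while muscle stays quantifiable for a month, so tissue acts
  as a depot with negligible back-flux; the plasma model is closed and mass
  entering the muscle subsystem is *not* debited from plasma. Consequently
  total drug amount is conserved within each subsystem separately, not
  jointly — the mass-balance tests check `Ac+Aper` against the cumulative dose
  (kel = 0) and `At+A1` against `kpt·∫Ac dt` (k = 0).
- **Peripheral tissue concentration drives PD.** Exon skipping lags measured
  tissue concentration (hysteresis); C1, the concentration in the slow tissue
  sub-compartment, is the Hill-function driver of transcript synthesis.
- **Turnover (indirect-response) PD with stimulation of synthesis.** Both PD
  states are stationary at their baselines in the absence of drug because the
  synthesis rates are tied to the baselines. Skipped transcript stimulates
  dystrophin synthesis linearly in its excess over baseline.
- **Naive pooling.** Sampling is destructive (one observation per animal), so
  inter-individual variability is not estimable; each dose group is treated as
  a single subject and the likelihood has no random effects. Direct
  quasi-Newton maximization therefore replaces stochastic-EM machinery.

## Parameters, units, defaults

The canonical time unit is days; plasma rate constants published per hour are
converted on ingestion (`PlasmaPKParams.from_hourly`). Volumes are mL with the
convention 1 g tissue = 1 mL, so `Ct = At/Vt` is ng/g. `SC50` is interpreted
on the C1 scale (ng/g). `reference_estimates()` returns the published
naive-pooled estimates used as defaults throughout:

| block | parameter (unit) | value |
|---|---|---|
| plasma | Vc (mL), kel, k12, k21 (1/day) | 5.86, 102.72, 21.53, 30.24 |
| muscle | kpt, kt1, kt2, k (1/day), Vt (mL) | 0.023, 0.37, 0.26, 0.13, 0.21 |
| transcript | Smax, SC50 (ng/g), kout_s (1/day), γ, skmRNA0 | 1.41e4, 795.28, 3.17, 1.16, 1.3 (fixed) |
| dystrophin | S_Dys (per copy), kout_Dys (1/day), Dys0 (%WT) | 0.093, 0.044, 0.10 (fixed) |

Derived quantities: CL = kel·Vc, CLd = k12·Vc (reported in mL/h), V2 = CLd/k21;
half-lives ln2/k ≈ 5.3 d (tissue), ln2/kout_s ≈ 5.2 h (transcript),
ln2/kout_Dys ≈ 15.75 d (dystrophin). Body weight is not a model parameter of
record; regimens default to 0.025 kg (typical adult mouse) and it is
configurable per `DoseRegimen`.

Note on repeat-dose accumulation: the tissue *terminal* decay is governed by
the slow hybrid eigenvalue of the (kt1, kt2, k) block, ≈ 0.047/day (half-life
≈ 14.6 d), not by k alone. The trough accumulation ratio over q28d dosing is
therefore 1/(1 − e^(−0.047·28)) ≈ 1.36 — still limited, and well below the
≈1.8-fold dystrophin accumulation whose 16-day turnover integrates across
doses. A single-rate intuition using k = 0.13/day would predict ≈1.03 and
underestimates the simulated ratio.

## Numerics

- **Drug states are solved analytically.** The 4×4 rate matrix is constant and
  block-triangular with non-negative off-diagonal 2×2 blocks, so its spectrum
  is real; states under impulse dosing are sums of matrix-exponential
  responses evaluated by eigendecomposition. Doses superpose exactly
  (linearity), and a value requested at a dose time is the post-dose state.
- **PD states use an exponential-trapezoidal integrator** on a fixed refined
  grid: step 0.002 day during the first day after each dose (the biophase
  input varies on the ~0.01-day plasma time scale), 0.01 day elsewhere. The
  scheme is the exact solution of `y' = g(t) − r·y` for piecewise-linear
  forcing, unconditionally stable, and exactly stationary at the undosed
  baseline. Against LSODA at rtol 1e-8/atol 1e-10 it agrees to ≲4e-6 relative
  on the study horizons. The motivation is throughput: a likelihood fit needs
  on the order of 10^3–10^4 cascade evaluations, and this path runs a
  single-dose 28-day simulation in well under a millisecond. `method="ode"`
  (LSODA on all six states) is retained as the reference route and is
  cross-checked in the test suite; likelihood evaluations use a slightly
  coarsened grid (0.005/0.02 day, ~3e-5 relative error — far below the
  residual noise).
- **Censored likelihood.** Residual error is proportional (σ = b·f) for
  plasma, tissue and dystrophin and combined (σ = √(a² + b²f²)) for the
  transcript. BQL observations contribute P(0 < Y < LOQ); quantified
  observations use a normal density conditioned on Y > 0 (the truncation
  normalizer is negligible except when f ≲ 2σ; a flag disables it). A σ floor
  of 1e-10 in observation units guards proportional error at zero predictions.
  Φ differences are clipped at 1e-300 before taking logs.
- **Optimization** is bounded L-BFGS-B on log-transformed parameters
  (relative ftol 1e-9), with the first start at the supplied initial values
  and additional latin-hypercube starts (default 5 total) within a ×3 band.
  The Hill coefficient is boxed to (0.1, 10): unbounded exponents destabilize
  small-n fits. The objective is soft-capped (log-compressed above 1e8) so
  that line searches probing the edge of the log-parameter box, where the
  misfit can reach 1e30, can still interpolate back into the basin.
- **Uncertainty.** RSE% comes from the observed Fisher information: the
  numerical Hessian of the negative log-likelihood in log-parameters, whose
  inverse diagonal is directly the squared relative SE (delta method). A
  nonparametric bootstrap (resampling animals within design cells) is the
  fallback when the Hessian is not positive definite.

## Identifiability

Two exact flat directions exist by construction and are handled explicitly:

1. **kpt–Vt ridge.** All tissue observables depend on (kpt, Vt) only through
   kpt/Vt: scaling both leaves Ct and C1 invariant because the only tissue
   input is kpt·Ac and both outputs divide by Vt. Only the ratio is estimable
   from concentration data. `fit_tissue_pd(..., fixed={"Vt": ...})` pins one
   coordinate and restores a full-rank information matrix; the recovery
   studies fix Vt at its nominal value and re-estimate kpt.
2. **Transcript additive error.** With the default generator settings the
   simulated transcript stays in the hundreds-to-thousands range, so the
   additive SD a (default 0.1 copies/30 ng RNA) is likelihood-flat over many
   orders of magnitude. It is kept in the error model for datasets that do
   approach baseline and pinned in the recovery studies.

Smax and SC50 are structurally identifiable but soft: peak C1 reaches only
0.8×SC50 (40 mg/kg) to 1.6×SC50 (80 mg/kg), so the data sit mostly below the
Hill inflection and the two parameters are strongly correlated at n = 6 per
timepoint with 20% CV. Their replicate-median RSE stays below the 50% accuracy
rule, but individual replicates can exceed it — a property of the design, not
of the estimator.

## Synthetic data

`study_designs()` returns the three study layouts: single-dose plasma
(10/40/80 mg/kg; 5 and 30 min, 2–24 h; n = 3), single-dose tissue PK/PD
(40/80 mg/kg; days 1–28; n = 6; tissue, transcript, dystrophin) and
repeat-dose (q28d ×6; sacrifices days 28–168; tissue measured after the first
and last dose only). The generator simulates the noise-free trajectory per
dose group, draws one observation per synthetic animal with the dvid's error
model (redrawing non-positive values, matching the likelihood's Y > 0
conditioning), and censors below the LOQ (plasma 10 ng/mL, tissue 60 ng/g),
recording the LOQ as the interval bound. Error magnitudes default to b = 0.2
(and a = 0.1 for the transcript); the original residual-error estimates are
not published, so these are declared defaults, not inferred values.

What the generator does *not* emulate: inter-animal parameter variability,
assay-specific error structure (e.g. heavier tails near the LOQ), model
misspecification, wild-type/vehicle control arms, or cross-muscle differences
(tissue PK is generated for the same simulated animal that provides PD, per
the quadriceps-to-biceps linkage assumption). Passing parameter recovery
therefore demonstrates correctness of the simulation–estimation machinery
under the model's own assumptions — not robustness to real-data violations of
them.

## NCA, dose proportionality, VPC

- NCA uses the linear log trapezoidal rule (log rule on declining segments
  with positive endpoints, linear otherwise), a best-adjusted-R² terminal
  window over the last 3..N points after Tmax (Tmax included when the profile
  declines from the first sample, i.e. IV bolus), and IV-bolus C0
  back-extrapolation so AUC covers the unobserved initial segment — without
  it, the 5-min first sample misses ≈35% of the true AUC at these rate
  constants. Group NCA averages uncensored values per nominal time
  (destructive sampling); BQL rows are excluded by default, with a
  zero-before-Tmax option.
- Dose proportionality: OLS of ln(exposure) on ln(dose) with a t-based 90% CI;
  the prespecified equivalence interval is (1 + ln(0.5)/ln r, 1 + ln(2)/ln r)
  for dose ratio r. Verdicts: *linear* (CI inside the interval and containing
  1), *nonlinear* (containment fails), *inconclusive* (contained but excluding
  1). ANOVA on dose-normalized exposure reports unadjusted pooled-variance
  pairwise t tests by default (Tukey HSD behind a flag).
- VPC bins are the exact nominal timepoints (shared by design). Simulated
  replicates use the fitted error models with the same truncation and the same
  below-LOQ rule as the observed data (drop by default, LOQ/2 optional), so
  observed and simulated percentiles are exchangeable. With n = 6 per bin the
  10th/90th percentiles are extrapolative under the linear-interpolation
  convention and are flagged. Results are bit-reproducible given (fit, data,
  nsim, seed).

## Problem sizes used in the shipped checks

The recovery study runs 20 replicates of the full sequential pipeline
(plasma fit on 63 observations; joint tissue/PD fit on 420 observations over
four dose-group regimens), initialized at the generating values with a single
start per replicate — the standard simulation–reestimation layout, which
probes the estimator rather than global search (multi-start remains the
default for real fits). VPC self-coverage pools 5 replicate datasets at
nsim = 300; the example scripts use nsim = 1500.

## Known limitations

- No saturable plasma elimination variant and no tissue-to-plasma
  redistribution; no mixed-effects machinery, covariates, or Bayesian
  inference.
- The power-model β from published group means (~0.97 for Cmax) cannot
  reproduce analyses that used individual-animal exposures; per-animal tables
  were never published.
- NCA on the sparse 7-point design carries a few-percent quadrature bias even
  noise-free; the dense-grid tests quantify convergence.
- `fit_tissue_pd` estimates 11 structural + up to 4 error parameters from 420
  observations; with the default noise level, SC50/Smax/kout_s estimates are
  correlated and individual-replicate dispersion is substantial (medians are
  tight — see the acceptance suite).
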