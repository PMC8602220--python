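# ppmopkpd

Semi-mechanistic PK/PD modeling of peptide-conjugated phosphorodiamidate
morpholino oligomer (PPMO) exon-skipping therapy in the mdx mouse model of
Duchenne muscular dystrophy.

PPMOs induce skipping of the mutated exon 23 in the dystrophin pre-mRNA,
restoring the reading frame and producing functional (truncated) dystrophin.
The pharmacology spans four time scales — plasma clearance in under an hour,
muscle exposure over weeks, transcript turnover in hours, dystrophin turnover
over weeks — and this package models the whole chain:

```
IV dose → plasma (2-compartment: Vc, kel, k12, k21)
        → muscle biophase, one-way uptake (2-compartment: kpt, kt1, kt2, k, Vt)
        → skipped transcript (indirect response, Hill stimulation of
          synthesis by the peripheral tissue concentration C1:
          d[sk]/dt = kin_s·(1 + Smax·C1^γ/(SC50^γ + C1^γ)) − kout_s·[sk])
        → dystrophin (linear stimulation of synthesis by transcript excess:
          d[Dys]/dt = kin_Dys·(1 + S_Dys·([sk] − sk0)) − kout_Dys·[Dys])
```

It is written for pharmacometricians and modelers who need to simulate these
cascades, generate realistic synthetic studies (destructive sampling, BQL
censoring), fit them by naive-pooled censored maximum likelihood, and qualify
fits with NCA, dose-proportionality equivalence testing, goodness-of-fit
tables and visual predictive checks. See `docs/methods.md` for the full model
account and numerical choices.

## Worked example

`examples/` contains one narrative script per capability. The first simulates
the cascade at the published parameter estimates:

```bash
$ python examples/01_simulate_cascade.py
single 40 mg/kg dose (sampling days 1-28):
  muscle Ct:   peak    685.3 ng/g at day 1, day 28   90.4 ng/g (still above the 60 ng/g LOQ)
  transcript:  peak     8060 copies/30 ng RNA (baseline 1.3)
  dystrophin:  day 28  35.7 %WT (baseline 0.1)

repeat 40 mg/kg q28d x 6 (trough values):
  day   :     28      56      84     112     140     168
  Ct    :   90.4   114.3   120.6   122.3   122.8   122.9 ng/g
  Dys   :   35.7    53.5    60.5    63.0    63.9    64.1 %WT

  tissue trough accumulation (dose 6 vs 1): 1.36x  -> limited, set by the slow tissue eigenvalue
  dystrophin accumulation (dose 6 vs 1):    1.80x  -> ~2-fold, approaching steady state by the 6th dose
```

Reading the numbers: plasma PPMO is gone within a day (terminal half-life
0.70 h), but the one-way muscle depot holds drug above the 60 ng/g
quantification limit through day 28. The skipped transcript (5 h turnover)
tracks the slow biophase compartment with little carry-over between monthly
doses, while dystrophin (16-day turnover) integrates across doses and roughly
doubles from the first to the sixth monthly dose — the mechanistic basis for
infrequent dosing despite the short plasma half-life.

The other scripts: `02_nca_and_dose_proportionality.py` (NCA per dose group,
power-model exponent against the Hummel equivalence interval 0.67–1.33 for
the 8-fold dose range, ANOVA on dose-normalized exposure),
`03_sequential_fit.py` (two-stage censored maximum likelihood with RSE%),
`04_vpc.py` (1500-simulation visual predictive check).

A thin CLI mirrors the library for shell pipelines:

```bash
ppmopkpd generate --design plasma_single --seed 1 --out plasma.csv
ppmopkpd nca --data plasma.csv --out nca.csv
ppmopkpd doseprop --nca-table nca.csv --out doseprop.json
ppmopkpd fit-plasma --data plasma.csv --out fit.json
ppmopkpd vpc --fit fit.json --data plasma.csv --nsim 1500 --seed 7 --out vpc.csv
```

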