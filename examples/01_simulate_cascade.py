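"""Simulate the full PK/PD cascade after single and repeated IV dosing.

Prints the milestones that characterize PPMO exon-skipping kinetics: muscle
exposure peaks within days and stays quantifiable for a month, the skipped
transcript tracks the slow biophase compartment, and dystrophin accumulates
over repeated monthly doses because its ~16-day turnover outlives the dosing
interval.
"""
import numpy as np

from ppmopkpd import DoseRegimen, reference_estimates, simulate_full

params = reference_estimates()


def cascade(regimen, times):
    return simulate_full(params.plasma, params.tissue, params.transcript,
                         params.dystrophin, regimen, times)


days = np.array([1.0, 2, 5, 7, 10, 14, 28])
single = cascade(DoseRegimen.single(40.0), days)
print("single 40 mg/kg dose (sampling days 1-28):")
print(f"  muscle Ct:   peak {single.ct.max():8.1f} ng/g at day "
      f"{days[np.argmax(single.ct)]:g}, day 28 {single.ct[-1]:6.1f} ng/g "
      "(still above the 60 ng/g LOQ)")
print(f"  transcript:  peak {single.skmrna.max():8.0f} copies/30 ng RNA "
      f"(baseline {params.transcript.skmrna0})")
print(f"  dystrophin:  day 28 {single.dys[-1]:5.1f} %WT "
      f"(baseline {params.dystrophin.dys0})")

troughs = np.array([28.0, 56, 84, 112, 140, 168])
repeat = cascade(DoseRegimen.repeated(40.0, 28.0, 6), troughs)
print("\nrepeat 40 mg/kg q28d x 6 (trough values):")
print("  day   :", "  ".join(f"{t:6.0f}" for t in troughs))
print("  Ct    :", "  ".join(f"{v:6.1f}" for v in repeat.ct), "ng/g")
print("  Dys   :", "  ".join(f"{v:6.1f}" for v in repeat.dys), "%WT")
print(f"\n  tissue trough accumulation (dose 6 vs 1): "
      f"{repeat.ct[-1] / repeat.ct[0]:.2f}x  -> limited, "
      "set by the slow tissue eigenvalue")
print(f"  dystrophin accumulation (dose 6 vs 1):    "
      f"{repeat.dys[-1] / repeat.dys[0]:.2f}x  -> ~2-fold, "
      "approaching steady state by the 6th dose")
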