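"""Synthetic study generator reproducing the mdx-mouse PPMO study designs.

Three designs are emulated:

* ``plasma_single`` — single IV bolus at 10/40/80 mg/kg; blood at 5 and 30 min
  and 2, 4, 8, 12, 24 h post-dose; n = 3 per dose per timepoint; plasma
  concentration only (LOQ 10 ng/mL).
* ``pkpd_single`` — single dose at 40/80 mg/kg; terminal sampling on days
  1, 2, 5, 7, 10, 14, 28; n = 6; tissue concentration (LOQ 60 ng/g), skipped
  transcript, dystrophin.
* ``pkpd_repeat`` — dosing every 28 days x 6 (days 0..140) at 40/80 mg/kg;
  sacrifices on days 28..168; n = 6; tissue concentration measured after the
  first and last dose (days 28, 168) only, transcript and dystrophin at every
  sacrifice.

Sampling is destructive: each synthetic animal contributes exactly one
observation row. Tissue concentration is generated from the muscle central
compartment (quadriceps-equivalent) and the PD observables from the same
simulated trajectory, mirroring the cross-muscle linkage of the original
studies. Noise draws that would be non-positive are redrawn (truncation at
zero, matching the estimation module's conditioning); values below the LOQ are
flagged censored with the LOQ recorded as the interval bound.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .data import COLUMNS, DVID_UNITS, Dataset
from .estimation import DEFAULT_ERROR_MODELS, ErrorModel
from .model import simulate_full
from .params import DoseRegimen, PKPDParams, dose_amount_ng

__all__ = ["StudyDesign", "study_designs", "generate_study", "generate_all_studies"]

MIN_5 = 5.0 / (24 * 60)
MIN_30 = 30.0 / (24 * 60)
H = 1.0 / 24


@dataclass(frozen=True)
class StudyDesign:
    """A destructive-sampling study arm layout.

    ``observables`` maps each measured dvid to the days on which it is
    collected; ``n_per_cell`` animals are sampled per dose per timepoint.
    """

    name: str
    doses_mgkg: tuple[float, ...]
    dose_times: tuple[float, ...]
    observables: Mapping[str, tuple[float, ...]]
    n_per_cell: int
    loq: Mapping[str, float | None]
    body_weight_kg: float = 0.025

    def __post_init__(self) -> None:
        problems = []
        if not self.doses_mgkg or any(d <= 0 for d in self.doses_mgkg):
            problems.append("doses must be positive (control arms are not simulated)")
        if self.n_per_cell < 1:
            problems.append("n_per_cell must be >= 1")
        horizon = max((t for ts in self.observables.values() for t in ts), default=0.0)
        for dvid, ts in self.observables.items():
            if dvid not in DVID_UNITS:
                problems.append(f"unknown observable {dvid!r}")
            if any(t < 0 for t in ts):
                problems.append(f"negative sampling time for {dvid!r}")
        if any(t < 0 for t in self.dose_times):
            problems.append("negative dose time")
        if list(self.dose_times) != sorted(set(self.dose_times)):
            problems.append("dose times must be strictly increasing")
        if any(t > horizon for t in self.dose_times):
            problems.append("dose after the last sampling time")
        if problems:
            raise ValueError("invalid study design: " + "; ".join(problems))

    def regimen(self, dose_mgkg: float) -> DoseRegimen:
        return DoseRegimen(events=tuple((t, dose_mgkg) for t in self.dose_times),
                           body_weight_kg=self.body_weight_kg)

    def n_observation_slots(self) -> int:
        per_dose = sum(len(ts) for ts in self.observables.values())
        return per_dose * self.n_per_cell * len(self.doses_mgkg)


def study_designs() -> dict[str, StudyDesign]:
    """The three mdx-mouse study designs, validated."""
    plasma_times = (MIN_5, MIN_30, 2 * H, 4 * H, 8 * H, 12 * H, 24 * H)
    single_days = (1.0, 2.0, 5.0, 7.0, 10.0, 14.0, 28.0)
    repeat_days = (28.0, 56.0, 84.0, 112.0, 140.0, 168.0)
    return {
        "plasma_single": StudyDesign(
            name="plasma_single",
            doses_mgkg=(10.0, 40.0, 80.0),
            dose_times=(0.0,),
            observables={"cp": plasma_times},
            n_per_cell=3,
            loq={"cp": 10.0},
        ),
        "pkpd_single": StudyDesign(
            name="pkpd_single",
            doses_mgkg=(40.0, 80.0),
            dose_times=(0.0,),
            observables={"ct": single_days, "sk": single_days, "dys": single_days},
            n_per_cell=6,
            loq={"ct": 60.0, "sk": None, "dys": None},
        ),
        "pkpd_repeat": StudyDesign(
            name="pkpd_repeat",
            doses_mgkg=(40.0, 80.0),
            dose_times=(0.0, 28.0, 56.0, 84.0, 112.0, 140.0),
            observables={"ct": (28.0, 168.0), "sk": repeat_days, "dys": repeat_days},
            n_per_cell=6,
            loq={"ct": 60.0, "sk": None, "dys": None},
        ),
    }


def _draw_truncated(rng: np.random.Generator, pred: np.ndarray,
                    em: ErrorModel) -> np.ndarray:
    """pred + sigma*eps with non-positive draws rejected and redrawn."""
    sigma = em.sigma(pred)
    values = pred + sigma * rng.standard_normal(pred.shape)
    for _ in range(1000):
        bad = values <= 0
        if not bad.any():
            return values
        values[bad] = pred[bad] + sigma[bad] * rng.standard_normal(int(bad.sum()))
    raise RuntimeError("rejection sampling failed: predictions are too close to zero")


def generate_study(design: StudyDesign, params: PKPDParams,
                   ems: Mapping[str, ErrorModel] | None = None,
                   seed: int | None = None) -> Dataset:
    """Simulate one study arm into a long-format :class:`Dataset`.

    ``seed`` is mandatory for reproducibility (pass an int). With all error
    magnitudes at zero the generator is not defined (sigma must be positive);
    to obtain noise-free records use the simulation API directly, or an
    arbitrarily small ``b``.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible generation")
    ems = dict(DEFAULT_ERROR_MODELS, **(ems or {}))
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for dose in design.doses_mgkg:
        group = f"{design.name}:{dose:g}"
        regimen = design.regimen(dose)
        all_times = np.unique(np.concatenate(
            [np.asarray(ts, float) for ts in design.observables.values()]))
        traj = simulate_full(params.plasma, params.tissue, params.transcript,
                             params.dystrophin, regimen, all_times)
        for t_day, dose_mgkg in regimen:
            rows.append({
                "id": group, "group": group, "study": design.name,
                "time_day": t_day, "dvid": "", "dv": np.nan, "cens": 0,
                "loq": np.nan, "dose_mgkg": dose,
                "evid": 1, "amt_ng": dose_amount_ng(dose_mgkg,
                                                    design.body_weight_kg),
            })
        for dvid, ts in design.observables.items():
            curve = traj.observable(dvid)
            loq = design.loq.get(dvid)
            for t in ts:
                pred = curve[np.searchsorted(all_times, t)]
                draws = _draw_truncated(
                    rng, np.full(design.n_per_cell, pred), ems[dvid])
                for i, value in enumerate(draws):
                    censored = loq is not None and value < loq
                    rows.append({
                        "id": f"{group}:{dvid}:d{t:g}:a{i + 1}",
                        "group": group, "study": design.name, "time_day": t,
                        "dvid": dvid,
                        "dv": float(loq) if censored else float(value),
                        "cens": int(censored),
                        "loq": float(loq) if loq is not None else np.nan,
                        "dose_mgkg": dose, "evid": 0, "amt_ng": np.nan,
                    })
    df = pd.DataFrame(rows, columns=COLUMNS)
    metadata = {"design": design.name, "seed": int(seed),
                "params": params.to_dict(),
                "error_models": {k: asdict(v) for k, v in ems.items()
                                 if k in design.observables}}
    return Dataset(df, metadata)


def generate_all_studies(params: PKPDParams,
                         ems: Mapping[str, ErrorModel] | None = None,
                         seed: int = 0) -> dict[str, Dataset]:
    """All three designs with per-design seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    return {name: generate_study(design, params, ems,
                                 seed=int(rng.integers(2 ** 31)))
            for name, design in study_designs().items()}
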