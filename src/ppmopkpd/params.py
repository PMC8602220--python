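"""Parameter containers, units, and dose bookkeeping for the PPMO PK/PD cascade.

The model is parameterized the way pharmacometric software reports it: rate
constants in 1/day (plasma estimates published per hour are converted on
ingestion), volumes in mL, tissue concentrations in ng/g with the convention
1 g tissue = 1 mL, transcript in copies per 30 ng total RNA, and dystrophin
in percent of the wild-type western-blot standard (%WT).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping

HOURS_PER_DAY = 24.0

#: Units of the flat parameter dictionary (canonical names used in config files).
PARAM_UNITS: dict[str, str] = {
    "Vc": "mL",
    "kel": "1/day",
    "k12": "1/day",
    "k21": "1/day",
    "kpt": "1/day",
    "kt1": "1/day",
    "kt2": "1/day",
    "k": "1/day",
    "Vt": "mL",
    "Smax": "",
    "SC50": "ng/g",
    "kout_s": "1/day",
    "gamma_s": "",
    "skmRNA0": "copies/30 ng RNA",
    "S_Dys": "1/(copies/30 ng RNA)",
    "kout_Dys": "1/day",
    "Dys0": "%WT",
}


class InvalidParameterError(ValueError):
    """A parameter value violates its positivity/ordering invariant."""


def _check_positive(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not (value > 0) or not math.isfinite(value):
            raise InvalidParameterError(
                f"{type(obj).__name__}.{name} must be strictly positive and finite, "
                f"got {value!r}"
            )


@dataclass(frozen=True)
class PlasmaPKParams:
    """Linear two-compartment IV-bolus plasma disposition.

    Attributes
    ----------
    vc : central volume of distribution (mL)
    kel : first-order elimination rate constant from the central compartment (1/day)
    k12, k21 : central<->peripheral distribution rate constants (1/day)
    """

    vc: float
    kel: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        _check_positive(self, "vc", "kel", "k12", "k21")

    @classmethod
    def from_hourly(cls, vc: float, kel: float, k12: float, k21: float) -> "PlasmaPKParams":
        """Build from rate constants expressed per hour (converted to 1/day)."""
        return cls(vc=vc, kel=kel * HOURS_PER_DAY, k12=k12 * HOURS_PER_DAY,
                   k21=k21 * HOURS_PER_DAY)


@dataclass(frozen=True)
class DerivedPlasmaParams:
    """Secondary plasma parameters: clearances in mL/h, peripheral volume in mL."""

    cl: float
    cld: float
    v2: float


def derived_plasma_params(p: PlasmaPKParams) -> DerivedPlasmaParams:
    """CL = kel*Vc, CLd = k12*Vc, V2 = CLd/k21, clearances reported in mL/h."""
    cl = p.kel * p.vc / HOURS_PER_DAY
    cld = p.k12 * p.vc / HOURS_PER_DAY
    v2 = p.k12 * p.vc / p.k21  # hour/day conversions cancel
    return DerivedPlasmaParams(cl=cl, cld=cld, v2=v2)


def half_life(rate: float) -> float:
    """ln(2)/rate, in the time base of ``rate`` (e.g. days for 1/day)."""
    if not (rate > 0) or not math.isfinite(rate):
        raise InvalidParameterError(f"rate constant must be > 0, got {rate!r}")
    return math.log(2.0) / rate


@dataclass(frozen=True)
class TissuePKParams:
    """One-way biophase: plasma feeds a two-compartment skeletal-muscle model.

    ``kpt`` moves drug from the plasma central compartment into muscle without a
    matching loss term in the plasma equations (distribution to tissue is minor
    relative to the rapid plasma clearance, so the plasma model is closed).

    Attributes
    ----------
    kpt : plasma-central -> tissue-central distribution rate constant (1/day)
    kt1, kt2 : tissue central<->peripheral rate constants (1/day)
    k : first-order elimination rate constant from tissue (1/day)
    vt : tissue central volume (mL; 1 g tissue = 1 mL, so Ct = At/Vt is ng/g)
    """

    kpt: float
    kt1: float
    kt2: float
    k: float
    vt: float

    def __post_init__(self) -> None:
        _check_positive(self, "kpt", "kt1", "kt2", "k", "vt")


@dataclass(frozen=True)
class TranscriptPDParams:
    """Indirect-response (stimulation of synthesis) model of the skipped transcript.

    The tissue peripheral concentration C1 drives a Hill stimulation of the
    zero-order transcript synthesis rate. kin_s is never stored: it is tied to
    the baseline by kin_s = skmRNA0 * kout_s.
    """

    smax: float
    sc50: float
    kout_s: float
    gamma_s: float
    skmrna0: float

    def __post_init__(self) -> None:
        _check_positive(self, "smax", "sc50", "kout_s", "gamma_s", "skmrna0")

    @property
    def kin_s(self) -> float:
        return self.skmrna0 * self.kout_s


@dataclass(frozen=True)
class DystrophinPDParams:
    """Linear indirect-response model of dystrophin (%WT).

    Synthesis is stimulated linearly by the skipped transcript excess over its
    baseline; kin_Dys = Dys0 * kout_Dys keeps the undosed system stationary.
    """

    s_dys: float
    kout_dys: float
    dys0: float

    def __post_init__(self) -> None:
        _check_positive(self, "s_dys", "kout_dys", "dys0")

    @property
    def kin_dys(self) -> float:
        return self.dys0 * self.kout_dys


@dataclass(frozen=True)
class PKPDParams:
    """Full parameter bundle for the plasma -> tissue -> transcript -> dystrophin cascade."""

    plasma: PlasmaPKParams
    tissue: TissuePKParams
    transcript: TranscriptPDParams
    dystrophin: DystrophinPDParams

    def to_dict(self) -> dict[str, float]:
        """Flat canonical-name dictionary (see :data:`PARAM_UNITS`)."""
        p, t, s, d = self.plasma, self.tissue, self.transcript, self.dystrophin
        return {
            "Vc": p.vc, "kel": p.kel, "k12": p.k12, "k21": p.k21,
            "kpt": t.kpt, "kt1": t.kt1, "kt2": t.kt2, "k": t.k, "Vt": t.vt,
            "Smax": s.smax, "SC50": s.sc50, "kout_s": s.kout_s,
            "gamma_s": s.gamma_s, "skmRNA0": s.skmrna0,
            "S_Dys": d.s_dys, "kout_Dys": d.kout_dys, "Dys0": d.dys0,
        }

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "PKPDParams":
        v = dict(values)
        missing = set(PARAM_UNITS) - set(v)
        if missing:
            raise InvalidParameterError(f"missing parameters: {sorted(missing)}")
        return cls(
            plasma=PlasmaPKParams(vc=v["Vc"], kel=v["kel"], k12=v["k12"], k21=v["k21"]),
            tissue=TissuePKParams(kpt=v["kpt"], kt1=v["kt1"], kt2=v["kt2"],
                                  k=v["k"], vt=v["Vt"]),
            transcript=TranscriptPDParams(smax=v["Smax"], sc50=v["SC50"],
                                          kout_s=v["kout_s"], gamma_s=v["gamma_s"],
                                          skmrna0=v["skmRNA0"]),
            dystrophin=DystrophinPDParams(s_dys=v["S_Dys"], kout_dys=v["kout_Dys"],
                                          dys0=v["Dys0"]),
        )


def reference_estimates() -> PKPDParams:
    """Published naive-pooled estimates for the mouse-surrogate PPMO RC-1001 in mdx mice.

    Plasma rate constants are stored in 1/day (converted from the per-hour fit).
    Baselines skmRNA0 = 1.3 copies/30 ng RNA and Dys0 = 0.10 %WT were fixed in
    the original analysis and are flagged as fixed by the estimation stage here.
    """
    return PKPDParams(
        plasma=PlasmaPKParams(vc=5.86, kel=102.72, k12=21.53, k21=30.24),
        tissue=TissuePKParams(kpt=0.023, kt1=0.37, kt2=0.26, k=0.13, vt=0.21),
        transcript=TranscriptPDParams(smax=1.41e4, sc50=795.28, kout_s=3.17,
                                      gamma_s=1.16, skmrna0=1.3),
        dystrophin=DystrophinPDParams(s_dys=0.093, kout_dys=0.044, dys0=0.10),
    )


#: Parameters that were fixed (not estimated) in the reference analysis.
REFERENCE_FIXED = ("skmRNA0", "Dys0")


def dose_amount_ng(dose_mgkg: float, bw_kg: float) -> float:
    """Convert a weight-normalized dose (mg/kg) to an absolute amount in ng."""
    if not (bw_kg > 0):
        raise InvalidParameterError(f"body weight must be > 0 kg, got {bw_kg!r}")
    if dose_mgkg < 0:
        raise InvalidParameterError(f"dose must be non-negative, got {dose_mgkg!r}")
    return dose_mgkg * bw_kg * 1e6


@dataclass(frozen=True)
class DoseRegimen:
    """IV bolus dosing events: (time in days, dose in mg/kg) with a body weight.

    Event times must be non-negative and strictly increasing. The default body
    weight of 25 g is a typical adult mouse.
    """

    events: tuple[tuple[float, float], ...]
    body_weight_kg: float = 0.025

    def __post_init__(self) -> None:
        if not (self.body_weight_kg > 0):
            raise InvalidParameterError("body_weight_kg must be > 0")
        events = tuple((float(t), float(d)) for t, d in self.events)
        object.__setattr__(self, "events", events)
        prev = -math.inf
        for t, d in events:
            if t < 0:
                raise InvalidParameterError(f"dose time {t} is negative")
            if t <= prev:
                raise InvalidParameterError("dose times must be strictly increasing")
            if d < 0:
                raise InvalidParameterError(f"dose {d} mg/kg is negative")
            prev = t

    @classmethod
    def single(cls, dose_mgkg: float, time: float = 0.0,
               body_weight_kg: float = 0.025) -> "DoseRegimen":
        return cls(events=((time, dose_mgkg),), body_weight_kg=body_weight_kg)

    @classmethod
    def repeated(cls, dose_mgkg: float, interval_days: float, n_doses: int,
                 body_weight_kg: float = 0.025) -> "DoseRegimen":
        events = tuple((i * interval_days, dose_mgkg) for i in range(n_doses))
        return cls(events=events, body_weight_kg=body_weight_kg)

    def amounts_ng(self) -> tuple[tuple[float, float], ...]:
        """Dosing events as (time in days, amount in ng)."""
        return tuple((t, dose_amount_ng(d, self.body_weight_kg)) for t, d in self.events)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.events)
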