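"""Long-format observation datasets shared by all pipeline stages.

One row per observation or dosing event, NONMEM-style. Destructive sampling
means each animal contributes a single observation row; dosing rows are stored
once per dose group. Canonical (lowercase) columns:

    id         animal or group identifier
    group      dose group ("<study>:<dose mg/kg>")
    study      study/design name
    time_day   time in days (canonical unit throughout the package)
    dvid       observable: cp (ng/mL), ct (ng/g), sk (copies/30 ng RNA), dys (%WT)
    dv         measured value; for censored rows the LOQ bound; NaN on dose rows
    cens       1 if below the limit of quantification (interval-censored), else 0
    loq        limit of quantification in dvid units (NaN when not applicable)
    dose_mgkg  nominal dose level of the group
    evid       0 = observation, 1 = dosing event
    amt_ng     administered amount in ng (dosing rows only)
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import DoseRegimen

DVIDS = ("cp", "ct", "sk", "dys")

DVID_UNITS = {"cp": "ng/mL", "ct": "ng/g", "sk": "copies/30 ng RNA", "dys": "%WT"}

COLUMNS = ["id", "group", "study", "time_day", "dvid", "dv", "cens", "loq",
           "dose_mgkg", "evid", "amt_ng"]


class DatasetFormatError(ValueError):
    """The observation table violates the dataset dialect."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        preview = "; ".join(self.violations[:10])
        more = "" if len(self.violations) <= 10 else f" (+{len(self.violations) - 10} more)"
        super().__init__(f"invalid dataset: {preview}{more}")


def validate_frame(df: pd.DataFrame) -> list[str]:
    """Return a list of invariant violations (empty when the frame is valid)."""
    problems: list[str] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    df = df.copy()
    for col in ("time_day", "dv", "cens", "loq", "dose_mgkg", "evid", "amt_ng"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        for i in bad:
            problems.append(f"row {i}: non-numeric {col}={df.at[i, col]!r}")
        df[col] = coerced
    if problems:
        return problems
    evid = df["evid"].fillna(0).astype(int)
    if not evid.isin([0, 1]).all():
        problems.append("evid must be 0 or 1")
    obs = df[evid == 0]
    dose = df[evid == 1]
    for i in obs.index[~obs["dvid"].isin(DVIDS)]:
        problems.append(f"row {i}: unknown dvid {df.at[i, 'dvid']!r}")
    for i in obs.index[obs["dv"].isna()]:
        problems.append(f"row {i}: observation row with empty DV")
    for i in obs.index[obs["time_day"] < 0]:
        problems.append(f"row {i}: negative time")
    cens = obs[obs["cens"].fillna(0).astype(int) == 1]
    mismatch = cens.index[~np.isclose(cens["dv"], cens["loq"], rtol=1e-9, atol=0.0)]
    for i in mismatch:
        problems.append(
            f"row {i}: censored row must carry DV = LOQ "
            f"(DV={df.at[i, 'dv']}, LOQ={df.at[i, 'loq']})")
    for i in dose.index[dose["dv"].notna()]:
        problems.append(f"row {i}: dosing row must have empty DV")
    for i in dose.index[dose["amt_ng"].isna() | (dose["amt_ng"] < 0)]:
        problems.append(f"row {i}: dosing row needs a non-negative AMT_NG")
    return problems


@dataclass
class Dataset:
    """Validated long-format dataset plus provenance metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df.copy()
        problems = validate_frame(df)
        if problems:
            raise DatasetFormatError(problems)
        df["evid"] = df["evid"].astype(int)
        df["cens"] = df["cens"].fillna(0).astype(int)
        for col in ("time_day", "dv", "loq", "dose_mgkg", "amt_ng"):
            df[col] = pd.to_numeric(df[col])
        # canonical time resolution: days to 6 decimals (5 min = 0.003472)
        df["time_day"] = df["time_day"].round(6)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return int((self.df["evid"] == 0).sum())

    @property
    def observations(self) -> pd.DataFrame:
        return self.df[self.df["evid"] == 0]

    @property
    def dose_rows(self) -> pd.DataFrame:
        return self.df[self.df["evid"] == 1]

    def groups(self) -> list[str]:
        return sorted(self.observations["group"].unique())

    def dvids(self) -> list[str]:
        return sorted(self.observations["dvid"].unique())

    def subset(self, dvids: Iterable[str] | None = None,
               groups: Iterable[str] | None = None) -> "Dataset":
        """Restrict observations (dose rows for retained groups are kept)."""
        df = self.df
        keep = df["evid"] == 1
        obs = df["evid"] == 0
        if dvids is not None:
            obs = obs & df["dvid"].isin(list(dvids))
        if groups is not None:
            sel = df["group"].isin(list(groups))
            obs = obs & sel
            keep = keep & sel
        return Dataset(df[keep | obs].reset_index(drop=True), dict(self.metadata))

    def regimen(self, group: str) -> DoseRegimen:
        """Rebuild the dosing regimen of a group from its dosing rows."""
        rows = self.dose_rows[self.dose_rows["group"] == group].sort_values("time_day")
        if rows.empty:
            raise KeyError(f"group {group!r} has no dosing rows")
        doses = rows["dose_mgkg"].to_numpy(float)
        amts = rows["amt_ng"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            bw = np.where(doses > 0, amts / (doses * 1e6), np.nan)
        bw = bw[np.isfinite(bw)]
        body_weight = float(bw[0]) if bw.size else 0.025
        events = tuple(zip(rows["time_day"].to_numpy(float), doses))
        return DoseRegimen(events=events, body_weight_kg=body_weight)

    def concat(self, other: "Dataset") -> "Dataset":
        meta = {"combined": [self.metadata, other.metadata]}
        return Dataset(pd.concat([self.df, other.df], ignore_index=True), meta)
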