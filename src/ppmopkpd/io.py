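"""Readers/writers for the shared CSV dataset dialect, parameter files and fits.

The dataset file is RFC-4180 CSV with uppercase NONMEM-style headers
(ID, GROUP, STUDY, TIME_DAY, DVID, DV, CENS, LOQ, DOSE_MGKG, EVID, AMT_NG) and
a leading ``#`` comment line recording the per-DVID units. Time is stored in
days rounded to 6 decimals so that minute-scale plasma sampling survives the
round trip. Parameter files are flat YAML mappings name -> {value, unit};
fit results serialize to JSON with estimates, fixed values, RSE, -2LL and the
settings/seed needed to reproduce them.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .data import COLUMNS, Dataset, DatasetFormatError
from .estimation import FitResult
from .params import PARAM_UNITS, PKPDParams

__all__ = ["read_dataset", "write_dataset", "read_params", "write_params",
           "read_fit", "write_fit"]

FILE_COLUMNS = [c.upper() for c in COLUMNS]

_UNITS_COMMENT = ("# units: cp=ng/mL ct=ng/g sk=copies/30ngRNA dys=%WT; "
                  "TIME_DAY=day AMT_NG=ng")


def write_dataset(ds: Dataset, path: str | Path) -> None:
    df = ds.df.copy()
    df["time_day"] = df["time_day"].round(6)
    df.columns = [c.upper() for c in df.columns]
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(_UNITS_COMMENT + "\n")
        df.to_csv(fh, index=False)


def read_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype={"ID": str, "GROUP": str,
                                               "STUDY": str, "DVID": str})
    missing = [c for c in FILE_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError([f"missing columns: {missing}"])
    df.columns = [c.lower() for c in df.columns]
    df["dvid"] = df["dvid"].fillna("")
    return Dataset(df, metadata={"source": str(path)})


def write_params(params: PKPDParams, path: str | Path) -> None:
    payload = {name: {"value": float(value), "unit": PARAM_UNITS[name]}
               for name, value in params.to_dict().items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_params(path: str | Path) -> PKPDParams:
    payload = yaml.safe_load(Path(path).read_text())
    values = {}
    for name, entry in payload.items():
        values[name] = float(entry["value"] if isinstance(entry, dict) else entry)
    return PKPDParams.from_dict(values)


def write_fit(fit: FitResult, path: str | Path) -> None:
    payload = asdict(fit)
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def read_fit(path: str | Path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    return FitResult(**payload)
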