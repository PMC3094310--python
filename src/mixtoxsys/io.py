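"""Readers and writers for the plain-text table dialects used across stages.

All tabular inputs are TSV/CSV with a header row, decimal point, UTF-8; the
separator is sniffed.  The literal ``N.A.`` (and the usual NA spellings) is
recognized as missing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseData
from .exceptions import ValidationError
from .health_status import BiomarkerRecord
from .toxicokinetics import EliminationSeries

_NA = ["N.A.", "NA", "NaN", ""]

__all__ = [
    "read_table",
    "load_dose_response",
    "load_mixture_points",
    "load_elimination",
    "load_biomarker_panel",
    "load_deg_table",
    "load_ct_table",
    "load_efficiencies",
    "load_ecx_table",
    "write_json",
]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", na_values=_NA, keep_default_na=True)


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")


def load_dose_response(path) -> Dict[str, DoseResponseData]:
    """``chemical,concentration,response[,replicate]`` -> one table per chemical."""
    df = read_table(path)
    _require(df, ("chemical", "concentration", "response"), path)
    out = {}
    for chem, grp in df.groupby("chemical"):
        out[str(chem)] = DoseResponseData(
            chemical_id=str(chem),
            concentrations=grp["concentration"].to_numpy(float),
            responses=grp["response"].to_numpy(float),
            replicate_id=grp["replicate"].tolist() if "replicate" in grp else None,
        )
    return out


def load_mixture_points(path) -> pd.DataFrame:
    """``c1,c2,response``; axis data are rows with one concentration = 0."""
    df = read_table(path)
    _require(df, ("c1", "c2", "response"), path)
    return df[["c1", "c2", "response"]].astype(float)


def load_elimination(path) -> List[EliminationSeries]:
    """``chemical,time_days,concentration`` -> one series per chemical."""
    df = read_table(path)
    _require(df, ("chemical", "time_days", "concentration"), path)
    out = []
    for chem, grp in df.groupby("chemical", sort=False):
        grp = grp.sort_values("time_days")
        out.append(
            EliminationSeries(
                chemical_id=str(chem),
                times=grp["time_days"].to_numpy(float),
                concentrations=grp["concentration"].to_numpy(float),
            )
        )
    return out


def load_biomarker_panel(path) -> List[BiomarkerRecord]:
    """Long format ``biomarker,level,group,value`` with optional
    ``harmful_direction``, ``severity_threshold`` and ``guide`` columns."""
    df = read_table(path)
    _require(df, ("biomarker", "level", "group", "value"), path)
    records = []
    for name, grp in df.groupby("biomarker", sort=False):
        exposed = grp.loc[grp["group"] == "exposed", "value"].to_numpy(float)
        control = grp.loc[grp["group"] == "control", "value"].to_numpy(float)
        kwargs = {}
        if "harmful_direction" in grp:
            kwargs["harmful_direction"] = str(grp["harmful_direction"].iloc[0])
        if "severity_threshold" in grp:
            kwargs["severity_threshold"] = float(grp["severity_threshold"].iloc[0])
        if "guide" in grp:
            kwargs["guide"] = bool(grp["guide"].iloc[0])
        records.append(
            BiomarkerRecord(
                name=str(name),
                level=str(grp["level"].iloc[0]),
                exposed=exposed,
                control=control,
                **kwargs,
            )
        )
    return records


def load_deg_table(path) -> pd.DataFrame:
    """``gene_id,M,B`` per condition; ``N.A.`` recognized as missing."""
    df = read_table(path)
    _require(df, ("gene_id", "M", "B"), path)
    return df


def load_ct_table(path) -> pd.DataFrame:
    """``gene_id,group,replicate,Ct``."""
    df = read_table(path)
    _require(df, ("gene_id", "group", "replicate", "Ct"), path)
    return df


def load_efficiencies(path) -> Dict[str, float]:
    """``gene_id,efficiency``."""
    df = read_table(path)
    _require(df, ("gene_id", "efficiency"), path)
    return dict(zip(df["gene_id"].astype(str), df["efficiency"].astype(float)))


def load_ecx_table(path) -> Dict[str, Dict[float, float]]:
    """``chemical,x,concentration`` -> {chemical: {x: concentration}}."""
    df = read_table(path)
    _require(df, ("chemical", "x", "concentration"), path)
    out: Dict[str, Dict[float, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chemical), {})[float(row.x)] = float(row.concentration)
    return out


def _default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict

        return asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
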