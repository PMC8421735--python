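"""Readers and writers: event-record dataset CSV dialect and flat
key-value parameter/config files.

Dataset columns: ID, TIME (h), EVID (1=dose, 0=observation), AMT (mg),
RATE (mg/h), DV (mg/L), CMT (1=plasma, 2=effluent), BLQ (0/1), LLOQ,
BW, ECRCL, CRRT, ECMO, AGE, SEX, plus optional covariate columns
(ALB, GLB, ALT, AST, TBIL, DBIL, HT, WAZ, LIZ, VANC).  Missing covariates
are empty cells.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .nlme import EventRecord, PKDataset, ModelDataError, LLOQ_DEFAULT
from .pk_core import PatientCovariates, PopulationParams

__all__ = [
    "load_params",
    "save_params",
    "final_params",
    "read_dataset",
    "write_dataset",
    "read_config",
]

_REQUIRED_COLUMNS = ["ID", "TIME", "EVID", "AMT", "RATE", "DV", "CMT", "BLQ"]
_LAB_COLUMNS = ["ALB", "GLB", "ALT", "AST", "TBIL", "DBIL", "HT", "WAZ", "LIZ", "VANC"]

PathLike = Union[str, Path]


def read_config(path: PathLike) -> Dict[str, float]:
    """Parse a flat ``key = value`` text config; '#' starts a comment."""
    out: Dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        out[key.strip()] = float(val.strip())
    return out


def load_params(path: PathLike) -> PopulationParams:
    """Load population parameters from a flat key-value file."""
    cfg = read_config(path)
    valid = {f.name for f in dataclasses.fields(PopulationParams)}
    unknown = set(cfg) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return PopulationParams(**cfg)


def save_params(p: PopulationParams, path: PathLike) -> None:
    lines = []
    for f in dataclasses.fields(p):
        v = getattr(p, f.name)
        if v is None:
            continue
        lines.append(f"{f.name} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def final_params() -> PopulationParams:
    """The packaged final-model parameter estimates."""
    ref = resources.files("meropk.data") / "final_model_params.cfg"
    with resources.as_file(ref) as path:
        return load_params(path)


# ---------------------------------------------------------------------------
# dataset dialect


def write_dataset(ds: PKDataset, path: PathLike) -> None:
    def fmt(x) -> str:
        # full-precision text so a write/read cycle is bit-exact
        return repr(float(x))

    rows = []
    for r in ds.records:
        cov = ds.covariates.get(r.subject_id)
        row = {
            "ID": r.subject_id,
            "TIME": fmt(r.time),
            "EVID": 1 if r.kind == "dose" else 0,
            "AMT": fmt(r.amount) if r.kind == "dose" else "",
            "RATE": fmt(r.rate) if r.kind == "dose" else "",
            "DV": "" if (r.kind == "dose" or r.value is None) else fmt(r.value),
            "CMT": 2 if r.kind == "effluent_obs" else 1,
            "BLQ": int(r.blq),
            "LLOQ": fmt(r.lloq),
        }
        if cov is not None:
            row.update(
                BW=cov.bodyweight,
                ECRCL=cov.ecrcl,
                CRRT=int(cov.on_crrt),
                ECMO=int(cov.on_ecmo),
                AGE=cov.age,
                SEX=cov.sex,
            )
            for lab in _LAB_COLUMNS:
                if lab in cov.labs:
                    row[lab] = cov.labs[lab]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset(path: PathLike) -> PKDataset:
    """Read and validate an event-record CSV.

    Parse errors carry 1-based data row numbers (header excluded).
    """
    df = pd.read_csv(path, dtype={"ID": str, "SEX": str}, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ModelDataError(f"{path}: missing required columns {missing}")
    records: List[EventRecord] = []
    covariates: Dict[str, PatientCovariates] = {}
    for i, row in enumerate(df.itertuples(index=False), 1):
        d = row._asdict()
        sid = str(d["ID"])
        lloq = float(d.get("LLOQ", LLOQ_DEFAULT) or LLOQ_DEFAULT)
        try:
            if int(d["EVID"]) == 1:
                rec = EventRecord(
                    subject_id=sid,
                    time=float(d["TIME"]),
                    kind="dose",
                    amount=float(d["AMT"]),
                    rate=float(d["RATE"]),
                    lloq=lloq,
                )
            else:
                blq = bool(int(d["BLQ"])) if not _isna(d["BLQ"]) else False
                dv = d["DV"]
                rec = EventRecord(
                    subject_id=sid,
                    time=float(d["TIME"]),
                    kind="effluent_obs" if int(d["CMT"]) == 2 else "plasma_obs",
                    value=None if (_isna(dv) or blq) else float(dv),
                    blq=blq,
                    lloq=lloq,
                )
        except (TypeError, ValueError) as exc:
            raise ModelDataError(f"{path}: row {i}: {exc}") from exc
        records.append(rec)
        if sid not in covariates and "BW" in d and not _isna(d.get("BW")):
            labs = {
                lab: float(d[lab])
                for lab in _LAB_COLUMNS
                if lab in d and not _isna(d[lab])
            }
            covariates[sid] = PatientCovariates(
                bodyweight=float(d["BW"]),
                ecrcl=float(d.get("ECRCL", 0.0) or 0.0),
                on_crrt=bool(int(d.get("CRRT", 0) or 0)),
                on_ecmo=bool(int(d.get("ECMO", 0) or 0)),
                age=float(d.get("AGE", 0.0) or 0.0),
                sex=str(d.get("SEX", "F") or "F"),
                labs=labs,
            )
    try:
        return PKDataset(records=records, covariates=covariates)
    except ModelDataError as exc:
        raise ModelDataError(f"{path}: {exc}") from exc


def _isna(v) -> bool:
    try:
        return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""
    except (TypeError, ValueError):
        return False
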