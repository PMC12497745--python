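"""Event-record CSV interface.

Datasets travel as NONMEM-convention rectangular tables: one row per dose
(EVID=1) or observation (EVID=0), columns ID, TIME, AMT, II, DV, EVID, MDV,
WT, ZOP plus optional extra covariate columns.  Units are fixed: time h,
amount mg, concentration ng/mL, weight kg.  Missing covariates are errors,
not imputed.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import CovariateVector, Dataset, DoseEvent, Observation, SubjectRecord

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "WT", "ZOP"]
STANDARD_COLUMNS = ["ID", "TIME", "AMT", "II", "DV", "EVID", "MDV", "WT", "ZOP", "TROUGH"]


class ParseError(ValueError):
    """A malformed event record; the message names the offending row."""


def dataset_to_frame(dataset: Dataset) -> pd.DataFrame:
    rows = []
    extra_names = sorted({k for s in dataset.subjects for k in s.cov.extras})
    for s in dataset.subjects:
        base = {"ID": s.id, "WT": s.cov.weight, "ZOP": s.cov.zop}
        base.update({name.upper(): s.cov.extras[name] for name in extra_names})
        for ev in s.doses:
            rows.append(
                {**base, "TIME": ev.time, "AMT": ev.amount,
                 "II": np.nan if ev.interval is None else ev.interval,
                 "DV": np.nan, "EVID": 1, "MDV": 1, "TROUGH": np.nan}
            )
        for o in s.obs:
            rows.append(
                {**base, "TIME": o.time, "AMT": np.nan, "II": np.nan,
                 "DV": o.conc, "EVID": 0, "MDV": 0, "TROUGH": int(o.is_trough)}
            )
    cols = STANDARD_COLUMNS + [n.upper() for n in extra_names]
    return pd.DataFrame(rows)[cols]


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    # %.17g keeps the write -> read round trip bit-exact
    dataset_to_frame(dataset).to_csv(path, index=False, float_format="%.17g")


def _require(cond: bool, row: int, msg: str) -> None:
    if not cond:
        # +2: header line plus 1-based counting, matching the file on disk
        raise ParseError(f"row {row + 2}: {msg}")


def dataset_from_frame(df: pd.DataFrame, source: str = "<frame>") -> Dataset:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    extra_cols = [
        c for c in df.columns if c not in STANDARD_COLUMNS and not c.startswith("Unnamed")
    ]
    for c in ["TIME", "AMT", "DV", "EVID", "MDV", "WT", "ZOP"] + extra_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad.any():
            _require(False, int(np.nonzero(bad.to_numpy())[0][0]), f"non-numeric value in {c}")
        df = df.assign(**{c: coerced})
    if "II" in df.columns:
        df = df.assign(II=pd.to_numeric(df["II"], errors="coerce"))

    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        wt = grp["WT"].to_numpy(dtype=float)
        _require(np.all(wt == wt[0]), int(grp.index[0]), f"WT varies within subject {sid}")
        zop = grp["ZOP"].to_numpy(dtype=float)
        _require(np.all(zop == zop[0]), int(grp.index[0]), f"ZOP varies within subject {sid}")
        extras = {}
        for c in extra_cols:
            v = grp[c].to_numpy(dtype=float)
            _require(np.all(v == v[0]), int(grp.index[0]), f"covariate {c} varies within subject {sid}")
            extras[c.lower()] = float(v[0])
        doses, obs = [], []
        for i, row in grp.iterrows():
            evid = row["EVID"]
            _require(evid in (0, 1), int(i), f"EVID must be 0 or 1, got {evid}")
            if evid == 1:
                _require(not pd.isna(row["AMT"]) and row["AMT"] >= 0, int(i),
                         "dose row (EVID=1) needs AMT >= 0")
                _require(pd.isna(row["DV"]), int(i), "dose row (EVID=1) must have blank DV")
                ii = row.get("II", np.nan)
                doses.append(
                    DoseEvent(
                        time=float(row["TIME"]),
                        amount=float(row["AMT"]),
                        interval=None if pd.isna(ii) else float(ii),
                    )
                )
            else:
                _require(not pd.isna(row["DV"]), int(i), "observation row (EVID=0) needs DV")
                _require(row["MDV"] == 0, int(i), "observation row (EVID=0) must have MDV=0")
                trough = row.get("TROUGH", np.nan)
                obs.append(
                    Observation(
                        time=float(row["TIME"]),
                        conc=float(row["DV"]),
                        is_trough=bool(trough) if not pd.isna(trough) else False,
                    )
                )
        obs.sort(key=lambda o: o.time)
        cov = CovariateVector(weight=float(wt[0]), zop=int(zop[0]), extras=extras)
        subjects.append(SubjectRecord(str(sid), cov, doses, obs))
    return Dataset(subjects, meta={"source": source})


def read_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    return dataset_from_frame(df, source=str(path))
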