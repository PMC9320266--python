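"""NONMEM-style tabular dataset I/O for virtual TDM courses.

Layout (one header line, comma-separated, missing numeric = "."):

    ID,TIME,AMT,RATE,DUR,DV,EVID,MDV,AGE,SEX,WT,SCR,DIAL,ICU,MODE,PAIR

EVID=1 rows are zero-order dosing events (AMT mg over DUR h, RATE=AMT/DUR);
EVID=0 rows are observations (DV mg/L, MDV=0).  TIME is hours from the
first dose.  SEX: 1=male, 0=female.  MODE: 1=intermittent, 2=continuous.
PAIR marks selected analysis pairs (1 or 2) on observation rows, 0
otherwise.  Floats are serialized as shortest round-trip reprs so that
write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, ConcentrationPair, StudyDataset, VirtualPatient
from .engine import DoseEvent
from .models import CovariateRecord

__all__ = ["dataset_to_frame", "write_dataset", "read_dataset"]

COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "DUR", "DV", "EVID", "MDV",
    "AGE", "SEX", "WT", "SCR", "DIAL", "ICU", "MODE", "PAIR",
]

_MODE_CODE = {"intermittent": 1, "continuous": 2}
_MODE_NAME = {v: k for k, v in _MODE_CODE.items()}


def dataset_to_frame(ds: StudyDataset) -> pd.DataFrame:
    rows = []
    for pidx, p in enumerate(ds.patients, start=1):
        pair_mark = {}
        for pair in ds.pairs:
            if pair.patient_id == p.patient_id:
                k = int(pair.pair_id.rsplit("p", 1)[-1])
                pair_mark[pair.first_index] = k
                pair_mark[pair.second_index] = k
        base = {
            "ID": pidx,
            "AGE": p.cov.age,
            "SEX": 1 if p.cov.sex == "male" else 0,
            "WT": p.cov.total_body_weight,
            "SCR": p.cov.serum_creatinine,
            "DIAL": int(p.cov.dialysis),
            "ICU": int(p.cov.icu),
            "MODE": _MODE_CODE[p.mode],
        }
        for e in p.events:
            rows.append({**base, "TIME": e.start_time, "AMT": e.amount,
                         "RATE": e.rate, "DUR": e.duration, "DV": np.nan,
                         "EVID": 1, "MDV": 1, "PAIR": 0})
        for i, (t, y) in enumerate(zip(p.obs_times, p.obs_values)):
            rows.append({**base, "TIME": float(t), "AMT": np.nan, "RATE": np.nan,
                         "DUR": np.nan, "DV": float(y), "EVID": 0, "MDV": 0,
                         "PAIR": pair_mark.get(i, 0)})
    df = pd.DataFrame(rows, columns=COLUMNS)
    # observations before doses at equal times (trough sampled pre-dose)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


def write_dataset(ds: StudyDataset | pd.DataFrame, path: str | Path) -> None:
    df = ds if isinstance(ds, pd.DataFrame) else dataset_to_frame(ds)
    # default float formatting = shortest round-trip repr, so parsed values
    # are bit-identical and write -> read -> write is byte-stable
    df.to_csv(path, index=False, na_rep=".")


def read_dataset(path: str | Path, config: CohortConfig | None = None) -> StudyDataset:
    """Reconstruct a StudyDataset (without simulation truth: true_eta is
    None) from the CSV dialect written by :func:`write_dataset`."""
    df = pd.read_csv(path, na_values=["."], float_precision="round_trip")
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset missing columns {sorted(missing)}")
    patients: list[VirtualPatient] = []
    pairs: list[ConcentrationPair] = []
    for pid, g in df.groupby("ID", sort=True):
        first = g.iloc[0]
        cov = CovariateRecord(
            age=float(first["AGE"]),
            sex="male" if int(first["SEX"]) == 1 else "female",
            total_body_weight=float(first["WT"]),
            serum_creatinine=float(first["SCR"]),
            dialysis=bool(int(first["DIAL"])),
            icu=bool(int(first["ICU"])),
        )
        mode = _MODE_NAME[int(first["MODE"])]
        doses = g[g["EVID"] == 1]
        events = [
            DoseEvent(float(r["TIME"]), float(r["AMT"]), float(r["DUR"]))
            for _, r in doses.iterrows()
        ]
        interval = inf_dur = None
        if mode == "intermittent":
            starts = doses["TIME"].to_numpy(dtype=float)
            if len(starts) > 1:
                gaps = np.diff(starts)
                interval = float(np.median(gaps))
            inf_dur = float(doses["DUR"].iloc[-1])
        obs = g[g["EVID"] == 0]
        patient_id = f"pt{int(pid):03d}"
        patient = VirtualPatient(
            patient_id=patient_id,
            cov=cov,
            mode=mode,
            true_model_id="",
            true_eta=None,
            events=events,
            interval=interval,
            inf_duration=inf_dur,
            obs_times=obs["TIME"].to_numpy(dtype=float),
            obs_values=obs["DV"].to_numpy(dtype=float),
        )
        patients.append(patient)
        marks = obs["PAIR"].to_numpy(dtype=int)
        for k in (1, 2):
            idx = np.flatnonzero(marks == k)
            if len(idx) != 2:
                continue
            i, j = int(idx[0]), int(idx[1])
            pairs.append(
                ConcentrationPair(
                    pair_id=f"{patient_id}-p{k}",
                    patient_id=patient_id,
                    first_index=i,
                    second_index=j,
                    t_first=float(patient.obs_times[i]),
                    y_first=float(patient.obs_values[i]),
                    t_second=float(patient.obs_times[j]),
                    y_second=float(patient.obs_values[j]),
                )
            )
    return StudyDataset(patients=patients, pairs=pairs,
                        config=config or CohortConfig(), seed=None)
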