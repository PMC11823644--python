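"""NONMEM-convention longitudinal dataset reading and writing.

One CSV row per event: dose rows (EVID=1) carry AMT (mg) and RATE (mg/h),
so the infusion duration is AMT/RATE; observation rows (EVID=0) carry DV
(mg/L) or, when censored, BLQ=1 with MDV=1 and the assay LLOQ. Covariate
columns (WT, HT, AGE, SEX, SCR, CRCL) repeat on every row of a course. An
optional II column gives the scheduled dosing interval; without it the
interval falls back to the spacing between consecutive doses, then 24 h.

Simulated and real data share this schema so both flow through identical
estimation code paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .llr import Observation
from .pk import DoseEvent, Regimen

__all__ = ["Course", "read_dataset", "write_dataset", "courses_to_dataframe"]

MANDATORY = ["ID", "TIME", "EVID"]
COVARIATE_COLS = ["WT", "HT", "AGE", "SEX", "SCR", "CRCL"]
ALL_COLS = [
    "ID",
    "PATID",
    "TIME",
    "EVID",
    "AMT",
    "RATE",
    "DV",
    "MDV",
    "BLQ",
    "LLOQ",
    "II",
] + COVARIATE_COLS


@dataclass
class Course:
    """One treatment course: covariates, dose events and observations."""

    course_id: str
    patient_id: str
    covariates: dict[str, float]
    regimen: Regimen
    observations: list[Observation]

    def n_doses(self) -> int:
        return len(self.regimen.doses)

    def n_observations(self) -> int:
        return len(self.observations)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""


def read_dataset(path) -> list[Course]:
    """Parse a dataset CSV into typed, time-sorted courses.

    Malformed rows raise with their (1-based, header-inclusive) line number.
    Observations before any dose are retained with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing mandatory column(s): {missing}")
    courses: list[Course] = []
    for cid, sub in df.groupby("ID", sort=False):
        sub = sub.sort_values("TIME", kind="stable")
        doses: list[tuple[int, float, float, float]] = []  # line, time, amt, rate
        obs_rows: list[tuple[int, pd.Series]] = []
        for idx, row in sub.iterrows():
            line = int(idx) + 2
            evid = int(row["EVID"])
            if evid == 1:
                if _is_missing(row.get("AMT")) or _is_missing(row.get("RATE")):
                    raise ValueError(
                        f"line {line}: dose row (EVID=1) requires AMT and RATE"
                    )
                rate = float(row["RATE"])
                if rate <= 0:
                    raise ValueError(f"line {line}: RATE must be positive")
                doses.append((line, float(row["TIME"]), float(row["AMT"]), rate))
            elif evid == 0:
                obs_rows.append((line, row))
            else:
                raise ValueError(f"line {line}: unsupported EVID {evid}")
        if not doses:
            raise ValueError(f"course {cid!r} has no dose events")
        # scheduled interval: II column, else spacing to the next dose, else 24 h
        dose_events = []
        for j, (line, t, amt, rate) in enumerate(doses):
            row = sub[(sub["EVID"] == 1)].iloc[j]
            ii = row.get("II")
            if not _is_missing(ii):
                tint = float(ii)
            elif j + 1 < len(doses):
                tint = doses[j + 1][1] - t
            elif j > 0:
                tint = t - doses[j - 1][1]
            else:
                tint = 24.0
            dose_events.append(DoseEvent(amount=amt, time=t, tinf=amt / rate, tinterval=tint))
        regimen = Regimen(tuple(dose_events))
        observations: list[Observation] = []
        first_dose_t = dose_events[0].time
        for line, row in obs_rows:
            t = float(row["TIME"])
            blq = int(row.get("BLQ", 0) or 0)
            lloq = None if _is_missing(row.get("LLOQ")) else float(row["LLOQ"])
            if blq:
                observations.append(Observation(time=t, value=None, bloq=True, loq=lloq))
            else:
                if _is_missing(row.get("DV")):
                    raise ValueError(
                        f"line {line}: observation row (EVID=0) requires DV or BLQ=1"
                    )
                observations.append(
                    Observation(time=t, value=float(row["DV"]), bloq=False, loq=lloq)
                )
            if t < first_dose_t:
                warnings.warn(
                    f"line {line}: observation at {t} h precedes the first dose; retained",
                    RuntimeWarning,
                )
        cov_row = sub.iloc[0]
        covariates = {
            c: float(cov_row[c]) for c in COVARIATE_COLS if c in sub.columns
            and not _is_missing(cov_row[c])
        }
        patid = str(cov_row["PATID"]) if "PATID" in sub.columns else str(cid)
        courses.append(
            Course(
                course_id=str(cid),
                patient_id=patid,
                covariates=covariates,
                regimen=regimen,
                observations=observations,
            )
        )
    return courses


def courses_to_dataframe(courses: list[Course]) -> pd.DataFrame:
    rows = []
    for c in courses:
        base = {"ID": c.course_id, "PATID": c.patient_id}
        base.update({k: c.covariates.get(k) for k in COVARIATE_COLS})
        for d in c.regimen.doses:
            rows.append(
                base
                | {
                    "TIME": d.time,
                    "EVID": 1,
                    "AMT": d.amount,
                    "RATE": d.rate,
                    "DV": None,
                    "MDV": 1,
                    "BLQ": 0,
                    "LLOQ": None,
                    "II": d.tinterval,
                }
            )
        for o in c.observations:
            rows.append(
                base
                | {
                    "TIME": o.time,
                    "EVID": 0,
                    "AMT": None,
                    "RATE": None,
                    "DV": o.value,
                    "MDV": 1 if o.bloq else 0,
                    "BLQ": int(o.bloq),
                    "LLOQ": o.loq,
                    "II": None,
                }
            )
    df = pd.DataFrame(rows, columns=ALL_COLS)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable", ascending=[True, True, False]).reset_index(
        drop=True
    )


def write_dataset(courses: list[Course], path) -> None:
    courses_to_dataframe(courses).to_csv(path, index=False)
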