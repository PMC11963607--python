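"""NONMEM-style event-list CSV reading and writing.

One row per dose or observation, columns::

    ID, TIME, AMT, DUR, DV, MDV, BLQ, GA, PNA, BBW, CBW, IBU

Dose rows carry AMT > 0, DUR (infusion duration, h) and MDV = 1; observation
rows carry DV (mg/L), MDV = 0 and a BLQ flag that must be consistent with
the 0.8 mg/L limit of quantification.  Covariates repeat on every row of a
subject.  The format round-trips losslessly through ``write_dataset`` /
``read_dataset``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import DoseEvent, LLOQ_MG_L, NeonateCovariates
from .estimation import ConcentrationObservation, Subject, TDMDataset

__all__ = ["COLUMNS", "SchemaError", "read_dataset", "write_dataset"]

COLUMNS = ["ID", "TIME", "AMT", "DUR", "DV", "MDV", "BLQ", "GA", "PNA", "BBW", "CBW", "IBU"]


class SchemaError(ValueError):
    """Raised when a dataset file violates the event-list schema."""


def write_dataset(dataset: TDMDataset, path: str | Path) -> None:
    rows = []
    for s in dataset:
        base = {
            "ID": s.subject_id,
            "GA": s.covariates.ga_weeks,
            "PNA": s.covariates.pna_days,
            "BBW": s.covariates.bw_birth_g,
            "CBW": s.covariates.bw_current_g,
            "IBU": int(s.covariates.ibuprofen),
        }
        events = [("dose", d.start_time_h, d) for d in s.doses] + [
            ("obs", o.time_h, o) for o in s.observations
        ]
        # doses sort before observations at equal times
        for kind, t, ev in sorted(events, key=lambda e: (e[1], e[0] != "dose")):
            if kind == "dose":
                rows.append(
                    {**base, "TIME": t, "AMT": ev.amount_mg, "DUR": ev.infusion_duration_h,
                     "DV": "", "MDV": 1, "BLQ": 0}
                )
            else:
                rows.append(
                    {**base, "TIME": t, "AMT": 0.0, "DUR": "", "DV": ev.value_mg_L,
                     "MDV": 0, "BLQ": int(ev.blq)}
                )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)


def read_dataset(path: str | Path) -> TDMDataset:
    """Parse and validate an event-list CSV into a :class:`TDMDataset`.

    Raises :class:`SchemaError` naming the offending row for a missing
    column, non-monotone times within a subject, an observation before any
    dose, or a BLQ flag inconsistent with DV < 0.8 mg/L.
    """
    df = pd.read_csv(path, dtype={"ID": str}, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    subjects: list[Subject] = []
    for sid, grp in df.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(float)
        if (times[1:] < times[:-1]).any():
            row = int(grp.index[1:][times[1:] < times[:-1]][0]) + 2  # 1-based + header
            raise SchemaError(f"{path}: non-monotone TIME for subject {sid} at file row {row}")
        first = grp.iloc[0]
        cov = NeonateCovariates(
            ga_weeks=float(first["GA"]),
            pna_days=float(first["PNA"]),
            bw_birth_g=float(first["BBW"]),
            bw_current_g=float(first["CBW"]),
            ibuprofen=bool(int(first["IBU"])),
        )
        doses: list[DoseEvent] = []
        observations: list[ConcentrationObservation] = []
        seen_dose = False
        for idx, rec in grp.iterrows():
            file_row = int(idx) + 2
            if int(rec["MDV"]) == 1:
                doses.append(
                    DoseEvent(
                        start_time_h=float(rec["TIME"]),
                        amount_mg=float(rec["AMT"]),
                        infusion_duration_h=float(rec["DUR"]),
                    )
                )
                seen_dose = True
            else:
                if not seen_dose:
                    raise SchemaError(
                        f"{path}: observation before any dose for subject {sid} at file row {file_row}"
                    )
                dv = float(rec["DV"])
                blq = bool(int(rec["BLQ"]))
                if blq != (dv < LLOQ_MG_L):
                    raise SchemaError(
                        f"{path}: BLQ flag inconsistent with DV={dv} at file row {file_row} "
                        f"(limit {LLOQ_MG_L} mg/L)"
                    )
                occ = len(doses)
                observations.append(
                    ConcentrationObservation(time_h=float(rec["TIME"]), value_mg_L=dv, blq=blq, occasion=occ)
                )
        subjects.append(Subject(subject_id=str(sid), covariates=cov, doses=doses, observations=observations))
    return TDMDataset(subjects)
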