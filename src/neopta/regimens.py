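"""Deterministic neonatal amikacin dosing-regimen engines.

Two regimens are implemented from their published lookup tables, shipped as
CSV data files and loaded row-for-row:

* the *complex* regimen: ten dosing categories by postnatal-age band
  (< 14 vs >= 14 days) and current-weight band, doses 15-20 mg/kg at
  intervals 20-48 h, with the dosing interval prolonged by 10 h under
  ibuprofen co-administration;
* the *simplified* regimen: two categories by gestational age
  (< 30 vs >= 30 weeks), 15 mg/kg every 36 or 24 h.

Weight bands are printed with shared edges in the source table; this engine
adopts lower-inclusive / upper-exclusive bands ([800, 1200), [1200, 2000),
[2000, 2800), plus < 800 and >= 2800) — the convention is centralized in the
CSV so it can be flipped by editing band edges.  Postnatal ages above
30 days are outside both regimens' scope.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .model import DoseEvent, NeonateCovariates

__all__ = [
    "EligibilityError",
    "RegimenAssignment",
    "assign_complex",
    "assign_simplified",
    "build_dose_events",
]

_BASE_DOSES = {15.0, 16.0, 18.0, 20.0}
_BASE_INTERVALS = {20.0, 24.0, 30.0, 36.0, 42.0, 48.0}
IBUPROFEN_INTERVAL_EXTENSION_H = 10.0


class EligibilityError(ValueError):
    """Covariates outside the scope of the dosing regimens (e.g. PNA > 30 d)."""


@dataclass(frozen=True)
class RegimenAssignment:
    dose_mg_per_kg: float
    interval_h: float
    category_id: str
    ibuprofen_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg not in _BASE_DOSES:
            raise ValueError(f"dose {self.dose_mg_per_kg} mg/kg not in the regimen tables")
        base = self.interval_h - (IBUPROFEN_INTERVAL_EXTENSION_H if self.ibuprofen_adjusted else 0.0)
        if base not in _BASE_INTERVALS:
            raise ValueError(f"interval {self.interval_h} h not in the regimen tables")


def _read_table(name: str) -> tuple[dict, ...]:
    text = resources.files("neopta").joinpath(f"data/{name}").read_text()
    return tuple(csv.DictReader(text.splitlines()))


@lru_cache(maxsize=None)
def _complex_table():
    rows = []
    for r in _read_table("regimen_complex.csv"):
        rows.append(
            {
                "pna_min": float(r["pna_min_days"]),
                "pna_max": float(r["pna_max_days"]),
                "w_min": float(r["weight_min_g"]),
                "w_max": float(r["weight_max_g"]) if r["weight_max_g"] else math.inf,
                "category": r["category"],
                "dose": float(r["dose_mg_per_kg"]),
                "interval": float(r["interval_h"]),
            }
        )
    return tuple(rows)


@lru_cache(maxsize=None)
def _simplified_table():
    rows = []
    for r in _read_table("regimen_simplified.csv"):
        rows.append(
            {
                "ga_min": float(r["ga_min_weeks"]),
                "ga_max": float(r["ga_max_weeks"]) if r["ga_max_weeks"] else math.inf,
                "category": r["category"],
                "dose": float(r["dose_mg_per_kg"]),
                "interval": float(r["interval_h"]),
            }
        )
    return tuple(rows)


def _check_pna(pna_days: float) -> None:
    if pna_days > 30:
        raise EligibilityError(f"postnatal age {pna_days} days exceeds the regimens' 30-day scope")
    if pna_days < 0:
        raise EligibilityError("negative postnatal age")


def assign_complex(cov: NeonateCovariates) -> RegimenAssignment:
    """Category, dose and interval per the ten-category complex regimen.

    Bands are lower-inclusive / upper-exclusive on PNA (at 14 days) and
    current weight.  Under ibuprofen the interval is prolonged by 10 h; the
    alternative +6 h interval suggested elsewhere for categories 7 and 9 is
    deliberately not applied.
    """
    _check_pna(cov.pna_days)
    for row in _complex_table():
        if row["pna_min"] <= cov.pna_days < row["pna_max"] and row["w_min"] <= cov.bw_current_g < row["w_max"]:
            interval = row["interval"]
            if cov.ibuprofen:
                interval += IBUPROFEN_INTERVAL_EXTENSION_H
            return RegimenAssignment(
                dose_mg_per_kg=row["dose"],
                interval_h=interval,
                category_id=row["category"],
                ibuprofen_adjusted=cov.ibuprofen,
            )
    raise EligibilityError(f"no complex-regimen category for PNA {cov.pna_days} d, weight {cov.bw_current_g} g")


def assign_simplified(cov: NeonateCovariates) -> RegimenAssignment:
    """15 mg/kg every 36 h below 30 weeks' gestation, every 24 h at or above.

    The simplified table carries no ibuprofen rule; the 10 h prolongation
    belongs to the complex regimen only.
    """
    _check_pna(cov.pna_days)
    for row in _simplified_table():
        if row["ga_min"] <= cov.ga_weeks < row["ga_max"]:
            return RegimenAssignment(
                dose_mg_per_kg=row["dose"],
                interval_h=row["interval"],
                category_id=row["category"],
                ibuprofen_adjusted=False,
            )
    raise EligibilityError(f"no simplified-regimen category for GA {cov.ga_weeks} weeks")


def build_dose_events(
    assignment: RegimenAssignment,
    bw_current_g: float,
    n_doses: int = 2,
    infusion_duration_h: float = 0.5,
) -> list[DoseEvent]:
    """Expand an assignment into dose events at 0, tau, 2*tau, ...

    The absolute amount is dose (mg/kg) x current weight (kg), rounded to
    0.1 mg as prepared at the bedside.
    """
    if n_doses < 1:
        raise ValueError("n_doses must be at least 1")
    amount = round(assignment.dose_mg_per_kg * bw_current_g / 1000.0, 1)
    return [
        DoseEvent(
            start_time_h=k * assignment.interval_h,
            amount_mg=amount,
            infusion_duration_h=infusion_duration_h,
        )
        for k in range(n_doses)
    ]
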