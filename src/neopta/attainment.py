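"""PK/PD target evaluation and cohort-level attainment summaries.

Targets follow aminoglycoside practice for neonatal sepsis:

* efficacy peaks: Cmax >= 15, >= 24 mg/L (and >= 35 mg/L to flag
  overexposure), evaluated 1 h after the start of the first infusion;
* toxicity troughs: Cmin <= 3 and <= 5 mg/L just before the second dose;
* exposure: AUC0-tau/MIC >= 21.4 for bacteriostasis and >= 62.5 for a
  1-log10 CFU/mL reduction of Enterobacterales, over the MIC grid
  {2, 4, 8} mg/L (8 mg/L is the E. coli wild-type ECOFF).

All inequalities are inclusive.  Attainment of >= 90% of a cohort is deemed
adequate.  AUC/MIC uses the AUC over the actual first dosing interval; a
per-24 h normalization is available but off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import PKAssessment

logger = logging.getLogger(__name__)

__all__ = ["AttainmentSummary", "TargetSet", "classify_sample", "evaluate_targets", "summarize_cohort"]


@dataclass(frozen=True)
class TargetSet:
    cmax_thresholds_mg_L: tuple[float, ...] = (15.0, 24.0, 35.0)
    cmin_thresholds_mg_L: tuple[float, ...] = (3.0, 5.0)
    auc_mic_bacteriostasis: float = 21.4
    auc_mic_onelog: float = 62.5
    mic_grid_mg_L: tuple[float, ...] = (2.0, 4.0, 8.0)
    adequacy_fraction: float = 0.90

    def __post_init__(self) -> None:
        values = (
            *self.cmax_thresholds_mg_L,
            *self.cmin_thresholds_mg_L,
            self.auc_mic_bacteriostasis,
            self.auc_mic_onelog,
            *self.mic_grid_mg_L,
        )
        if any(v <= 0 for v in values):
            raise ValueError("all thresholds must be positive")
        if not 0 < self.adequacy_fraction <= 1:
            raise ValueError("adequacy fraction must be in (0, 1]")


def _fmt(x: float) -> str:
    return f"{x:g}"


def evaluate_targets(
    assessment: PKAssessment,
    targets: TargetSet = TargetSet(),
    normalize_auc_per_24h: bool = False,
    tau_h: float | None = None,
) -> dict[str, bool]:
    """Boolean attainment of every target for one neonate (inclusive bounds)."""
    auc = assessment.auc_0_tau_mg_h_L
    if normalize_auc_per_24h:
        if tau_h is None:
            raise ValueError("tau_h is required for per-24 h AUC normalization")
        auc = auc * 24.0 / tau_h
    out: dict[str, bool] = {}
    for g in targets.cmax_thresholds_mg_L:
        out[f"cmax_ge_{_fmt(g)}"] = assessment.cmax_mg_L >= g
    for g in targets.cmin_thresholds_mg_L:
        out[f"cmin_le_{_fmt(g)}"] = assessment.cmin_mg_L <= g
    for mic in targets.mic_grid_mg_L:
        ratio = auc / mic
        out[f"auc_mic_stasis_mic{_fmt(mic)}"] = ratio >= targets.auc_mic_bacteriostasis
        out[f"auc_mic_1log_mic{_fmt(mic)}"] = ratio >= targets.auc_mic_onelog
    return out


@dataclass
class AttainmentSummary:
    """Tidy per-(regimen, category, target) attainment table."""

    table: pd.DataFrame = field(repr=False)

    def percent(self, target: str, category: str = "all") -> float:
        rows = self.table[(self.table["target"] == target) & (self.table["category"] == category)]
        if rows.empty:
            raise KeyError(f"no attainment row for target {target!r}, category {category!r}")
        return float(rows["percent"].iloc[0])

    def adequate(self, target: str, category: str = "all") -> bool:
        rows = self.table[(self.table["target"] == target) & (self.table["category"] == category)]
        return bool(rows["adequate"].iloc[0])


def summarize_cohort(
    assessments: list[PKAssessment],
    categories: list[str],
    targets: TargetSet = TargetSet(),
    regimen: str = "",
) -> AttainmentSummary:
    """Attainment percentages per dosing category and pooled ('all').

    The inclusive-threshold construction guarantees the monotone chains
    %(Cmax>=15) >= %(Cmax>=24) >= %(Cmax>=35), %(Cmin<=5) >= %(Cmin<=3) and
    AUC/MIC attainment non-increasing in MIC on every cohort.
    """
    if not assessments:
        raise ValueError("at least one assessment is required")
    if len(assessments) != len(categories):
        raise ValueError("assessments and categories must align")
    flags = pd.DataFrame([evaluate_targets(a, targets) for a in assessments])
    flags["category"] = [str(c) for c in categories]

    rows = []
    target_names = [c for c in flags.columns if c != "category"]
    groups = [("all", flags)]
    for cat, grp in flags.groupby("category", sort=True):
        if cat == "all":  # reserved for the pooled summary
            logger.info("summarize_cohort: category label 'all' folded into the pooled rows")
            continue
        groups.append((cat, grp))
    for cat, grp in groups:
        n = len(grp)
        if n == 0:
            continue
        for name in target_names:
            n_meet = int(grp[name].sum())
            pct = 100.0 * n_meet / n
            rows.append(
                {
                    "regimen": regimen,
                    "category": cat,
                    "target": name,
                    "n": n,
                    "n_meeting": n_meet,
                    "percent": pct,
                    "adequate": pct >= 100.0 * targets.adequacy_fraction,
                }
            )
    return AttainmentSummary(table=pd.DataFrame(rows))


def classify_sample(time_after_dose_h: float) -> str:
    """Peak (< 2 h after a dose), trough (> 20 h), or neither."""
    if time_after_dose_h < 0:
        raise ValueError("negative time after dose")
    if time_after_dose_h < 2.0:
        return "peak"
    if time_after_dose_h > 20.0:
        return "trough"
    return "neither"
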