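"""Synthetic neonatal cohorts and TDM datasets emulating the two study sites.

No patient data ship with this package.  Instead, two site profiles generate
virtual cohorts whose covariate distributions are moment-matched to the
published demographic summaries (medians and ranges of gestational age,
postnatal age, birth and current weight, and ibuprofen prevalence):

* **site A** — the simplified-regimen site: predominantly premature
  (median GA ~28.7 weeks, 2% ibuprofen, median PNA 9 days); TDM scheme is a
  trough just before dose 2 and a peak 1 h after the start of dose 1.
* **site B** — the complex-regimen site: median GA ~34 weeks, 5% ibuprofen,
  median PNA 2 days; trough just before dose 2 and peak 1 h after the start
  of dose 2.

Gestational age is drawn from a truncated preterm bulk plus a term tail;
birth weight follows a log-linear gestational growth curve with lognormal
spread; current weight applies an early loss / later gain postnatal factor.
This is a calibration to summary statistics, not a model of real neonatal
demographics.  Ground-truth random effects and noise-free exposure metrics
are stored alongside every simulated dataset so that downstream estimators
can be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .model import (
    NeonateCovariates,
    PopulationParameters,
    assess_first_interval,
    concentration,
    individual_parameters,
    simulate_observation,
)
from .estimation import ConcentrationObservation, Subject, TDMDataset
from .regimens import RegimenAssignment, assign_complex, assign_simplified, build_dose_events

__all__ = [
    "SITE_A",
    "SITE_B",
    "SiteProfile",
    "assign_for_site",
    "generate_covariates",
    "simulate_tdm",
]


@dataclass(frozen=True)
class SiteProfile:
    """Statistical recipe for one site's virtual cohort and sampling scheme."""

    name: str
    # GA mixture: preterm bulk N(mu, sd) truncated to [ga_min, term_cut),
    # term tail Uniform[term_cut, ga_max] with weight term_weight
    ga_mu: float
    ga_sd: float
    ga_min: float
    ga_max: float
    term_cut: float
    term_weight: float
    # PNA: lognormal around the published median, truncated integer days
    pna_median_d: float
    pna_sigma: float
    pna_min_d: int
    pna_max_d: int
    # birth weight: exp(a + b*GA) with lognormal spread, clipped to range
    bw_log_a: float
    bw_log_b: float
    bw_sigma: float
    bw_range_g: tuple[float, float]
    cw_range_g: tuple[float, float]
    ibuprofen_prevalence: float
    scr_median_umol_L: float
    peak_after_dose: int  # 1-based index of the dose whose peak is sampled
    regimen: str  # "simplified" or "complex"


# log-linear growth: ~1100 g at 28.7 weeks, ~3500 g at 40 weeks
_BW_B = math.log(3500.0 / 1100.0) / (40.0 - 28.7)
_BW_A = math.log(1100.0) - _BW_B * 28.7

SITE_A = SiteProfile(
    name="A",
    ga_mu=28.5,
    ga_sd=2.5,
    ga_min=24.0,
    ga_max=42.1,
    term_cut=37.0,
    term_weight=0.125,
    pna_median_d=9.0,
    pna_sigma=0.75,
    pna_min_d=0,
    pna_max_d=30,
    bw_log_a=_BW_A,
    bw_log_b=_BW_B,
    bw_sigma=0.15,
    bw_range_g=(440.0, 5200.0),
    cw_range_g=(455.0, 5500.0),
    ibuprofen_prevalence=0.02,
    scr_median_umol_L=42.0,
    peak_after_dose=1,
    regimen="simplified",
)

SITE_B = SiteProfile(
    name="B",
    ga_mu=33.0,
    ga_sd=3.0,
    ga_min=24.0,
    ga_max=41.0,
    term_cut=37.0,
    term_weight=0.30,
    pna_median_d=2.0,
    pna_sigma=0.8,
    pna_min_d=1,
    pna_max_d=30,
    bw_log_a=_BW_A,
    bw_log_b=_BW_B,
    bw_sigma=0.15,
    bw_range_g=(420.0, 4850.0),
    cw_range_g=(420.0, 5040.0),
    ibuprofen_prevalence=0.05,
    scr_median_umol_L=88.0,
    peak_after_dose=2,
    regimen="complex",
)


def _truncated_normal(rng: np.random.Generator, mu, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are a few SDs wide here)."""
    out = rng.normal(mu, sd, size=size)
    bad = (out < lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        bad = (out < lo) | (out >= hi)
    return out


def _postnatal_weight_factor(pna_days: float) -> float:
    """Physiological loss of ~7% by day 4, regained then ~1.2%/day after day 7."""
    loss = 0.07 * min(pna_days, 4.0) / 4.0
    regain = 0.07 * min(max(pna_days - 4.0, 0.0), 6.0) / 6.0
    gain = 0.012 * max(pna_days - 10.0, 0.0)
    return 1.0 - loss + regain + gain


def generate_covariates(profile: SiteProfile, n: int, seed: int | None = None) -> list[NeonateCovariates]:
    """Draw ``n`` virtual neonates from a site profile (reproducible by seed)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    is_term = rng.random(n) < profile.term_weight
    ga = np.empty(n)
    n_term = int(is_term.sum())
    ga[is_term] = rng.uniform(profile.term_cut, profile.ga_max, size=n_term)
    ga[~is_term] = _truncated_normal(
        rng, profile.ga_mu, profile.ga_sd, profile.ga_min, profile.term_cut, n - n_term
    )
    pna = np.clip(
        np.round(np.exp(rng.normal(math.log(profile.pna_median_d + 0.5), profile.pna_sigma, size=n)) - 0.5),
        profile.pna_min_d,
        profile.pna_max_d,
    )
    bw = np.exp(profile.bw_log_a + profile.bw_log_b * ga + rng.normal(0.0, profile.bw_sigma, size=n))
    bw = np.clip(bw, *profile.bw_range_g)
    cw = bw * np.array([_postnatal_weight_factor(p) for p in pna]) * np.exp(
        rng.normal(0.0, 0.05, size=n)
    )
    cw = np.clip(cw, *profile.cw_range_g)
    ibu = rng.random(n) < profile.ibuprofen_prevalence
    scr = np.exp(rng.normal(math.log(profile.scr_median_umol_L), 0.5, size=n))
    return [
        NeonateCovariates(
            ga_weeks=float(ga[i]),
            pna_days=float(pna[i]),
            bw_birth_g=float(bw[i]),
            bw_current_g=float(cw[i]),
            ibuprofen=bool(ibu[i]),
            scr_umol_L=float(scr[i]),
        )
        for i in range(n)
    ]


def assign_for_site(profile: SiteProfile, cov: NeonateCovariates) -> RegimenAssignment:
    """The regimen assignment a neonate receives at the given site."""
    return assign_simplified(cov) if profile.regimen == "simplified" else assign_complex(cov)


def simulate_tdm(
    cohort: list[NeonateCovariates],
    pop: PopulationParameters,
    profile: SiteProfile,
    seed: int | None = None,
    sampling_jitter: bool = False,
    id_prefix: str | None = None,
) -> TDMDataset:
    """Simulate a site's TDM dataset for a virtual cohort.

    Per neonate: draw eta from the IIV distribution, expand the site's
    regimen into dose events, sample a trough just before dose 2 and a peak
    1 h after the start of the profile's peak dose, apply residual error and
    BLQ censoring at 0.8 mg/L.  Optional uniform +/-15 min sampling-time
    jitter mimics clinical imprecision (off by default).  Ground truth
    (eta, noise-free metrics and concentrations) is stored per subject.
    """
    rng = np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else profile.name
    subjects: list[Subject] = []
    for i, cov in enumerate(cohort):
        assignment = assign_for_site(profile, cov)
        n_doses = max(2, profile.peak_after_dose)
        doses = build_dose_events(assignment, cov.bw_current_g, n_doses=n_doses)
        eta = (
            float(rng.normal(0.0, pop.omega_CL)) if pop.omega_CL > 0 else 0.0,
            float(rng.normal(0.0, pop.omega_V1)) if pop.omega_V1 > 0 else 0.0,
        )
        ip = individual_parameters(pop, cov, eta)
        tau = assignment.interval_h
        t_trough = tau - 1.0 / 60.0
        t_peak = doses[profile.peak_after_dose - 1].start_time_h + 1.0
        if sampling_jitter:
            t_trough += float(rng.uniform(-0.25, 0.0))
            t_peak += float(rng.uniform(-0.25, 0.25))
        times = [t_trough, t_peak]
        occasions = [1, profile.peak_after_dose]
        observations = []
        true_concs = []
        for t, occ in zip(times, occasions):
            c_true = float(concentration(t, doses, ip))
            y, blq = simulate_observation(c_true, pop, rng)
            true_concs.append(c_true)
            observations.append(
                ConcentrationObservation(time_h=t, value_mg_L=y, blq=blq, occasion=occ)
            )
        truth_assessment = assess_first_interval(doses, ip, tau)
        subjects.append(
            Subject(
                subject_id=f"{prefix}{i + 1:04d}",
                covariates=cov,
                doses=doses,
                observations=observations,
                assignment=assignment,
                truth={
                    "eta": eta,
                    "cmax_mg_L": truth_assessment.cmax_mg_L,
                    "cmin_mg_L": truth_assessment.cmin_mg_L,
                    "auc_0_tau_mg_h_L": truth_assessment.auc_0_tau_mg_h_L,
                    "true_concs": true_concs,
                },
            )
        )
    return TDMDataset(subjects)
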