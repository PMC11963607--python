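"""Structural and stochastic population PK model for amikacin in neonates.

The structural model is a linear two-compartment model with zero-order
(infusion) input, parameterized by clearance (CL, L/h), central volume
(V1, L), inter-compartmental clearance (Q, L/h) and peripheral volume
(V2, L).  Setting ``Q = 0`` or ``V2 = 0`` reduces the engine exactly to the
one-compartment closed form, so a one-compartment configuration is a valid
special case.

Typical (population) values of CL and V1 are modulated by a configurable
product of covariate terms (power, linear slope, or fractional change) on
neonatal covariates such as birth weight, current weight, postnatal age and
ibuprofen co-administration.  Inter-individual variability (IIV) enters as
log-normal random effects on CL and V1 only.  Residual variability is a
combined proportional + additive error with censoring below the assay's
lower limit of quantification (0.8 mg/L).

Time is measured in hours with t = 0 at the start of the first infusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LLOQ_MG_L",
    "ConfigurationError",
    "CovariateTerm",
    "DoseEvent",
    "IndividualParameters",
    "NeonateCovariates",
    "PKAssessment",
    "PopulationParameters",
    "assess_first_interval",
    "auc_to",
    "concentration",
    "concentration_profile",
    "individual_parameters",
    "simulate_observation",
    "typical_values",
]

#: Lower limit of quantification of the amikacin immunoassays (mg/L).
LLOQ_MG_L = 0.8


class ConfigurationError(ValueError):
    """Raised for an inconsistent population-model configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateTerm:
    """One multiplicative covariate factor on a typical PK parameter.

    kind:
        ``power``             -> (cov / reference) ** coefficient
        ``linear_slope``      -> 1 + coefficient * (cov - reference)
        ``fractional_change`` -> 1 + coefficient * flag   (binary covariate)
    """

    target: str
    kind: str
    covariate: str
    coefficient: float
    reference: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in ("CL", "V1"):
            raise ConfigurationError(f"covariate terms may target CL or V1, not {self.target!r}")
        if self.kind not in ("power", "linear_slope", "fractional_change"):
            raise ConfigurationError(f"unknown covariate term kind {self.kind!r}")
        if self.kind == "power" and self.reference <= 0:
            raise ConfigurationError("power terms require a positive reference value")
        if self.kind == "fractional_change" and self.coefficient <= -1:
            raise ConfigurationError("fractional_change coefficient must exceed -1")

    def factor(self, value: float) -> float:
        if self.kind == "power":
            return (value / self.reference) ** self.coefficient
        if self.kind == "linear_slope":
            return 1.0 + self.coefficient * (value - self.reference)
        return 1.0 + self.coefficient * float(bool(value))


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, covariate model, IIV and residual error.

    ``omega_CL`` / ``omega_V1`` are standard deviations of the log-normal
    random effects; ``omega_V1`` defaults to 0.30, the value fixed when it
    cannot be estimated from sparse neonatal TDM data.  ``fixed`` names the
    components an estimation step must never update.
    """

    theta_CL: float
    theta_V1: float
    theta_Q: float = 0.0
    theta_V2: float = 0.0
    covariate_terms: tuple[CovariateTerm, ...] = ()
    omega_CL: float = 0.0
    omega_V1: float = 0.30
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    scale_q_with_v1: bool = False
    scale_v2_with_v1: bool = False
    fixed: frozenset[str] = frozenset({"omega_V1"})

    def __post_init__(self) -> None:
        if self.theta_CL <= 0 or self.theta_V1 <= 0:
            raise ConfigurationError("theta_CL and theta_V1 must be positive")
        if self.theta_Q < 0 or self.theta_V2 < 0:
            raise ConfigurationError("theta_Q and theta_V2 must be non-negative")
        if self.omega_CL < 0 or self.omega_V1 < 0:
            raise ConfigurationError("omegas must be non-negative")
        if self.sigma_prop <= 0 and self.sigma_add <= 0:
            raise ConfigurationError("at least one residual SD must be positive")
        object.__setattr__(self, "covariate_terms", tuple(self.covariate_terms))
        object.__setattr__(self, "fixed", frozenset(self.fixed))

    def with_updates(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NeonateCovariates:
    """Demographics of one (virtual or observed) neonate.

    Postmenstrual age is derived: PMA = GA + PNA / 7 (weeks).  Serum
    creatinine is carried for reporting only; it is not a model covariate.
    """

    ga_weeks: float
    pna_days: float
    bw_birth_g: float
    bw_current_g: float
    ibuprofen: bool = False
    scr_umol_L: float | None = None

    def __post_init__(self) -> None:
        if not 22.0 <= self.ga_weeks <= 45.0:
            raise ValueError(f"gestational age {self.ga_weeks} weeks outside [22, 45]")
        if not 0.0 <= self.pna_days <= 31.0:
            raise ValueError(f"postnatal age {self.pna_days} days outside [0, 31]")
        if self.bw_birth_g <= 0 or self.bw_current_g <= 0:
            raise ValueError("weights must be positive")

    @property
    def pma_weeks(self) -> float:
        return self.ga_weeks + self.pna_days / 7.0


@dataclass(frozen=True)
class IndividualParameters:
    """Realized PK parameters of one neonate (typical value x exp(eta))."""

    CL: float
    V1: float
    Q: float = 0.0
    V2: float = 0.0
    eta_CL: float = 0.0
    eta_V1: float = 0.0

    def __post_init__(self) -> None:
        if self.CL <= 0 or self.V1 <= 0:
            raise ValueError("individual CL and V1 must be positive")
        if self.Q < 0 or self.V2 < 0:
            raise ValueError("individual Q and V2 must be non-negative")


@dataclass(frozen=True)
class DoseEvent:
    """One intravenous amikacin infusion."""

    start_time_h: float
    amount_mg: float
    infusion_duration_h: float = 0.5

    def __post_init__(self) -> None:
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be positive")
        if self.infusion_duration_h <= 0:
            raise ValueError("infusion duration must be positive")


@dataclass(frozen=True)
class PKAssessment:
    """First-interval exposure metrics for one neonate.

    cmax: concentration 1 h after the start of the first infusion (mg/L);
    cmin: concentration immediately before the second dose (mg/L);
    auc:  exact AUC over the first dosing interval (mg*h/L).
    """

    cmax_mg_L: float
    cmin_mg_L: float
    auc_0_tau_mg_h_L: float

    def __post_init__(self) -> None:
        if min(self.cmax_mg_L, self.cmin_mg_L, self.auc_0_tau_mg_h_L) < 0:
            raise ValueError("PK metrics must be non-negative")
        if self.cmin_mg_L > self.cmax_mg_L * (1 + 1e-12):
            raise ValueError("cmin exceeds cmax")


# ---------------------------------------------------------------------------
# Covariate model
# ---------------------------------------------------------------------------


def _covariate_value(cov: NeonateCovariates, name: str) -> float:
    try:
        value = getattr(cov, name)
    except AttributeError:
        raise ConfigurationError(f"unknown covariate {name!r} in covariate model") from None
    return float(value)


def typical_values(pop: PopulationParameters, cov: NeonateCovariates) -> tuple[float, float, float, float]:
    """Typical (CL, V1, Q, V2) at the given covariates.

    Each covariate term multiplies its target parameter.  When the
    corresponding scale flags are set, Q and V2 are size-scaled by the same
    factor as V1 so that distribution kinetics stay proportionate across the
    neonatal weight range (Q and V2 carry no covariate terms of their own).
    """
    cl_factor = 1.0
    v1_factor = 1.0
    for term in pop.covariate_terms:
        f = term.factor(_covariate_value(cov, term.covariate))
        if term.target == "CL":
            cl_factor *= f
        else:
            v1_factor *= f
    cl = pop.theta_CL * cl_factor
    v1 = pop.theta_V1 * v1_factor
    q = pop.theta_Q * (v1_factor if pop.scale_q_with_v1 else 1.0)
    v2 = pop.theta_V2 * (v1_factor if pop.scale_v2_with_v1 else 1.0)
    if cl <= 0 or v1 <= 0:
        raise ArithmeticError("covariate model produced a non-positive typical parameter")
    return cl, v1, q, v2


def individual_parameters(
    pop: PopulationParameters,
    cov: NeonateCovariates,
    eta: tuple[float, float] = (0.0, 0.0),
) -> IndividualParameters:
    """Individual parameters: typical value times exp(eta) on CL and V1."""
    eta_cl, eta_v1 = float(eta[0]), float(eta[1])
    cl, v1, q, v2 = typical_values(pop, cov)
    return IndividualParameters(
        CL=cl * math.exp(eta_cl),
        V1=v1 * math.exp(eta_v1),
        Q=q,
        V2=v2,
        eta_CL=eta_cl,
        eta_V1=eta_v1,
    )


# ---------------------------------------------------------------------------
# Concentration-time solution
# ---------------------------------------------------------------------------


def _disposition(CL, V1, Q, V2):
    """Macro constants of the bi-exponential unit disposition function.

    Returns (alpha, beta, A, B) with the unit-bolus response
    ``C(t) = (1/V1) * (A e^{-alpha t} + B e^{-beta t})`` and A + B = 1.
    A one-compartment configuration (Q*V2 == 0) is returned as
    (k10, 0, 1, 0).
    """
    CL, V1, Q, V2 = np.broadcast_arrays(
        np.asarray(CL, float), np.asarray(V1, float), np.asarray(Q, float), np.asarray(V2, float)
    )
    k10 = CL / V1
    two_cpt = (Q > 0) & (V2 > 0)
    # guard the degenerate branch so the vectorized algebra stays finite
    Qs = np.where(two_cpt, Q, 1.0)
    V2s = np.where(two_cpt, V2, 1.0)
    k12 = Qs / V1
    k21 = Qs / V2s
    a = k10 + k12 + k21
    disc = np.sqrt(np.maximum(a * a - 4.0 * k10 * k21, 0.0))
    alpha2 = (a + disc) / 2.0
    beta2 = (a - disc) / 2.0
    A2 = (alpha2 - k21) / np.where(disc > 0, disc, 1.0)
    B2 = 1.0 - A2
    alpha = np.where(two_cpt, alpha2, k10)
    beta = np.where(two_cpt, beta2, 0.0)
    A = np.where(two_cpt, A2, 1.0)
    B = np.where(two_cpt, B2, 0.0)
    return alpha, beta, A, B


def _infusion_terms(tp, T, lam, coef):
    """Contribution of one exponential mode to an infusion of duration T.

    ``coef`` is A/(V1*lam) style; handles the lam -> 0 mode by its analytic
    limit (which carries coefficient 0 here, so the value is irrelevant but
    must be finite).
    """
    lam_s = np.where(lam > 0, lam, 1.0)
    tp_pos = np.maximum(tp, 0.0)
    during = coef * (1.0 - np.exp(-lam_s * np.minimum(tp_pos, T)))
    after = np.exp(-lam_s * np.maximum(tp_pos - T, 0.0))
    return during * after


def concentration_profile(times, doses: Sequence[DoseEvent], CL, V1, Q=0.0, V2=0.0):
    """Plasma concentration (mg/L) at ``times`` under superposed infusions.

    ``times`` is scalar or array (hours); CL/V1/Q/V2 are scalars or arrays of
    a common shape P (e.g. per-draw parameter vectors).  The result has shape
    ``P + times.shape`` (parameter axes first), squeezed to ``times.shape``
    for scalar parameters.  Exact analytic superposition; linear in dose.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    alpha, beta, A, B = _disposition(CL, V1, Q, V2)
    v1 = np.broadcast_to(np.asarray(V1, float), alpha.shape)
    pshape = alpha.shape
    # parameter axes first, then time axes
    al = alpha.reshape(pshape + (1,) * t.ndim)
    be = beta.reshape(pshape + (1,) * t.ndim)
    Ar = A.reshape(pshape + (1,) * t.ndim)
    Br = B.reshape(pshape + (1,) * t.ndim)
    v1r = v1.reshape(pshape + (1,) * t.ndim)
    be_s = np.where(be > 0, be, 1.0)
    out = np.zeros(pshape + t.shape)
    for d in doses:
        tp = t - d.start_time_h
        rate = d.amount_mg / d.infusion_duration_h
        c_a = _infusion_terms(tp, d.infusion_duration_h, al, Ar / (v1r * al))
        # the beta mode has coefficient B = 0 in the one-compartment branch
        c_b = _infusion_terms(tp, d.infusion_duration_h, be_s, Br / (v1r * be_s))
        out += np.where(tp > 0, rate * (c_a + c_b), 0.0)
    if pshape == ():
        return out if t.ndim else float(out)
    return out


def concentration(t, doses: Sequence[DoseEvent], ip: IndividualParameters):
    """Concentration at time(s) ``t`` (hours) for one individual."""
    return concentration_profile(t, doses, ip.CL, ip.V1, ip.Q, ip.V2)


def _auc_mode(t_end, start, T, lam, coef):
    """Integral of one exponential mode from dose start to ``t_end``."""
    tp = max(t_end - start, 0.0)
    if tp <= 0:
        return 0.0
    t_in = min(tp, T)
    during = coef * (t_in - (1.0 - math.exp(-lam * t_in)) / lam)
    if tp <= T:
        return during
    tail = coef * (1.0 - math.exp(-lam * T)) * (1.0 - math.exp(-lam * (tp - T))) / lam
    return during + tail


def auc_to(t_end: float, doses: Sequence[DoseEvent], ip: IndividualParameters) -> float:
    """Exact analytic AUC (mg*h/L) from t = 0 to ``t_end``.

    Pass ``t_end = math.inf`` for the total AUC, which equals
    total dose / CL by linear-PK mass balance.
    """
    if t_end < 0:
        raise ValueError("negative time")
    alpha, beta, A, B = _disposition(ip.CL, ip.V1, ip.Q, ip.V2)
    alpha, beta, A, B = float(alpha), float(beta), float(A), float(B)
    total = 0.0
    for d in doses:
        rate = d.amount_mg / d.infusion_duration_h
        T = d.infusion_duration_h
        if math.isinf(t_end):
            dose_total = d.amount_mg / ip.CL
            total += dose_total
            continue
        val = _auc_mode(t_end, d.start_time_h, T, alpha, A / (ip.V1 * alpha))
        if beta > 0:
            val += _auc_mode(t_end, d.start_time_h, T, beta, B / (ip.V1 * beta))
        total += rate * val
    return total


def assess_first_interval(
    doses: Sequence[DoseEvent],
    ip: IndividualParameters,
    tau: float,
) -> PKAssessment:
    """First-interval Cmax, Cmin and AUC0-tau.

    Cmax is the concentration 1 h after the start of the first infusion and
    Cmin the concentration immediately before the second dose (i.e. at tau).
    The AUC is the exact analytic integral over [0, tau].
    """
    if not doses:
        raise ValueError("at least one dose is required")
    first = min(doses, key=lambda d: d.start_time_h)
    if tau < first.infusion_duration_h + 1.0:
        raise ValueError("tau must be at least the infusion duration plus 1 h")
    interval_doses = [d for d in doses if d.start_time_h < first.start_time_h + tau]
    cmax = float(concentration(first.start_time_h + 1.0, interval_doses, ip))
    cmin = float(concentration(first.start_time_h + tau, interval_doses, ip))
    auc = auc_to(first.start_time_h + tau, interval_doses, ip) - auc_to(
        first.start_time_h, interval_doses, ip
    )
    return PKAssessment(cmax_mg_L=cmax, cmin_mg_L=cmin, auc_0_tau_mg_h_L=auc)


# ---------------------------------------------------------------------------
# Residual error / observation model
# ---------------------------------------------------------------------------


def simulate_observation(
    true_conc,
    pop: PopulationParameters,
    rng: np.random.Generator,
):
    """Apply combined residual error and BLQ censoring to true concentration(s).

    y = c * (1 + eps_prop) + eps_add, truncated at 0; records with
    y < 0.8 mg/L are flagged below the limit of quantification but keep
    their value for audit.  Returns ``(y, blq)`` with the input's shape.
    """
    c = np.asarray(true_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("true concentration must be non-negative")
    eps_p = rng.normal(0.0, pop.sigma_prop, size=c.shape) if pop.sigma_prop > 0 else 0.0
    eps_a = rng.normal(0.0, pop.sigma_add, size=c.shape) if pop.sigma_add > 0 else 0.0
    y = np.maximum(c * (1.0 + eps_p) + eps_a, 0.0)
    blq = y < LLOQ_MG_L
    if c.ndim == 0:
        return float(y), bool(blq)
    return y, blq
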