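"""MAP Bayesian individual estimation and desk-scale population re-estimation.

Each subject contributes sparse therapeutic-drug-monitoring concentrations
(typically a trough just before the second dose and a peak 1 h after an
infusion start).  The maximum a posteriori (MAP) estimate of the subject's
random effects eta = (eta_CL, eta_V1) minimizes

    sum_j [ (y_j - f_j(eta))^2 / sigma_j^2 + ln sigma_j^2 ]  +  eta' Omega^-1 eta

with sigma_j^2 = (sigma_prop * f_j)^2 + sigma_add^2 — the standard extended
least-squares objective with a log-normal prior.  Records below the limit of
quantification are excluded from the likelihood.

Population re-estimation uses the iterative two-stage (ITS) algorithm:
alternate MAP estimation of all subjects with updates of the typical values
(geometric mean of individual over typical parameters) and of the IIV
variances (variance of the eta-hats plus the mean posterior variance, which
corrects for shrinkage).  ITS is a desk-scale approximation of full
likelihood estimation in nonlinear mixed-effects software; it is adequate
for parameter-recovery work, not a replacement for FOCE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import (
    DoseEvent,
    NeonateCovariates,
    PKAssessment,
    PopulationParameters,
    assess_first_interval,
    concentration_profile,
    individual_parameters,
    typical_values,
)
from .regimens import RegimenAssignment

__all__ = [
    "ConcentrationObservation",
    "ITSResult",
    "MAPResult",
    "Subject",
    "TDMDataset",
    "assess_subject",
    "map_estimate",
    "population_reestimate",
    "split_dataset",
]


@dataclass(frozen=True)
class ConcentrationObservation:
    """One measured amikacin concentration."""

    time_h: float
    value_mg_L: float
    blq: bool = False
    occasion: int = 1


@dataclass
class Subject:
    """Dosing history, observations and covariates of one neonate."""

    subject_id: str
    covariates: NeonateCovariates
    doses: list[DoseEvent]
    observations: list[ConcentrationObservation]
    assignment: RegimenAssignment | None = None
    truth: dict | None = None  # simulation ground truth, when available

    def __post_init__(self) -> None:
        self.observations = sorted(self.observations, key=lambda o: o.time_h)
        self.doses = sorted(self.doses, key=lambda d: d.start_time_h)
        if self.observations and self.doses:
            if self.observations[0].time_h < self.doses[0].start_time_h:
                raise ValueError(f"subject {self.subject_id}: observation before any dose")

    @property
    def tau_h(self) -> float:
        """First dosing interval: from the assignment or the dose schedule."""
        if self.assignment is not None:
            return self.assignment.interval_h
        if len(self.doses) >= 2:
            return self.doses[1].start_time_h - self.doses[0].start_time_h
        raise ValueError(f"subject {self.subject_id}: dosing interval unknown")


@dataclass
class TDMDataset:
    """A collection of subjects forming one TDM dataset."""

    subjects: list[Subject]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)


@dataclass
class MAPResult:
    eta: tuple[float, float]
    ipred: np.ndarray          # individual predictions at the usable obs times
    pred: np.ndarray           # population predictions (eta = 0)
    objective: float
    objective_at_zero: float
    posterior_variance: tuple[float, float]  # diagonal of the eta posterior cov
    n_obs_used: int
    trace: list[float] = field(default_factory=list)


def _usable(subject: Subject) -> tuple[np.ndarray, np.ndarray]:
    obs = [(o.time_h, o.value_mg_L) for o in subject.observations if not o.blq]
    if not obs:
        return np.empty(0), np.empty(0)
    t, y = map(np.asarray, zip(*obs))
    return t.astype(float), y.astype(float)


def _objective_factory(subject: Subject, pop: PopulationParameters):
    """Vectorized MAP objective over eta arrays of shape (..., 2)."""
    t, y = _usable(subject)
    cl_typ, v1_typ, q_typ, v2_typ = typical_values(pop, subject.covariates)
    doses = subject.doses
    free = np.array([pop.omega_CL > 0, pop.omega_V1 > 0])
    prior_prec = np.array(
        [1.0 / pop.omega_CL**2 if free[0] else 0.0, 1.0 / pop.omega_V1**2 if free[1] else 0.0]
    )

    def objective(eta):
        eta = np.asarray(eta, float)
        e_cl = eta[..., 0]
        e_v1 = eta[..., 1]
        cl = cl_typ * np.exp(e_cl)
        v1 = v1_typ * np.exp(e_v1)
        prior = prior_prec[0] * e_cl**2 + prior_prec[1] * e_v1**2
        if t.size == 0:
            return prior
        f = concentration_profile(t, doses, cl, v1, q_typ, v2_typ)
        sig2 = np.maximum((pop.sigma_prop * f) ** 2 + pop.sigma_add**2, 1e-12)
        ll = np.sum((y - f) ** 2 / sig2 + np.log(sig2), axis=-1)
        return ll + prior

    return objective, free, t, y


_STARTS = np.array(
    [[0.0, 0.0], [0.5, 0.5], [-0.5, -0.5], [0.5, -0.5], [-0.5, 0.5]]
)


def map_estimate(
    subject: Subject,
    pop: PopulationParameters,
    multi_start: bool = True,
    x0: tuple[float, float] | None = None,
) -> MAPResult:
    """MAP estimate of (eta_CL, eta_V1) for one subject.

    Quasi-Newton (L-BFGS-B) minimization from eta = 0 plus +/-0.5
    perturbation starts; components whose omega is zero are held at 0.
    With no usable (non-BLQ) observations the prior mode eta = 0 is
    returned, i.e. the individual collapses to the population prediction.
    """
    objective, free, t, y = _objective_factory(subject, pop)
    obj0 = float(objective(np.zeros(2)))
    trace: list[float] = [obj0]

    best = np.zeros(2)
    best_val = obj0
    if t.size > 0 and free.any():
        starts = _STARTS if multi_start else _STARTS[:1]
        if x0 is not None:
            starts = np.vstack([np.asarray(x0, float), starts[:1]])

        idx = np.flatnonzero(free)

        def reduced(x):
            eta = np.zeros(2)
            eta[idx] = x
            return float(objective(eta))

        for s in starts:
            res = optimize.minimize(
                reduced,
                s[idx],
                method="L-BFGS-B",
                options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 200},
            )
            if not np.isfinite(res.fun):
                raise ArithmeticError(
                    f"subject {subject.subject_id}: non-finite MAP objective at eta={res.x}"
                )
            trace.append(float(res.fun))
            if res.fun < best_val:
                best_val = float(res.fun)
                best = np.zeros(2)
                best[idx] = res.x

    # posterior variance from the curvature of the -2 log posterior
    post_var = [0.0, 0.0]
    h = 1e-4
    for k in (0, 1):
        if free[k]:
            e_p, e_m = best.copy(), best.copy()
            e_p[k] += h
            e_m[k] -= h
            curv = (float(objective(e_p)) - 2.0 * best_val + float(objective(e_m))) / h**2
            omega2 = pop.omega_CL**2 if k == 0 else pop.omega_V1**2
            post_var[k] = 2.0 / curv if curv > 0 else omega2

    ip = individual_parameters(pop, subject.covariates, tuple(best))
    ipred = (
        concentration_profile(t, subject.doses, ip.CL, ip.V1, ip.Q, ip.V2)
        if t.size
        else np.empty(0)
    )
    cl0, v10, q0, v20 = typical_values(pop, subject.covariates)
    pred = concentration_profile(t, subject.doses, cl0, v10, q0, v20) if t.size else np.empty(0)
    return MAPResult(
        eta=(float(best[0]), float(best[1])),
        ipred=np.atleast_1d(ipred),
        pred=np.atleast_1d(pred),
        objective=best_val,
        objective_at_zero=obj0,
        posterior_variance=(post_var[0], post_var[1]),
        n_obs_used=int(t.size),
        trace=trace,
    )


def assess_subject(
    subject: Subject,
    pop: PopulationParameters,
    map_result: MAPResult | None = None,
) -> PKAssessment:
    """First-interval Cmax/Cmin/AUC at the subject's MAP parameters."""
    if map_result is None:
        map_result = map_estimate(subject, pop)
    ip = individual_parameters(pop, subject.covariates, map_result.eta)
    return assess_first_interval(subject.doses, ip, subject.tau_h)


def split_dataset(
    dataset: TDMDataset,
    fraction: float = 0.75,
    seed: int | None = None,
) -> tuple[TDMDataset, TDMDataset]:
    """Random subject-level partition into model-building / validation sets."""
    n = len(dataset)
    if n < 4:
        raise ValueError("at least 4 subjects are required for a split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_build = int(round(fraction * n))
    build_idx = set(order[:n_build].tolist())
    build = [s for i, s in enumerate(dataset.subjects) if i in build_idx]
    valid = [s for i, s in enumerate(dataset.subjects) if i not in build_idx]
    return TDMDataset(build), TDMDataset(valid)


@dataclass
class ITSResult:
    pop: PopulationParameters
    n_iterations: int
    converged: bool
    history: list[dict]
    map_results: list[MAPResult]


def population_reestimate(
    dataset: TDMDataset,
    init: PopulationParameters,
    fixed: frozenset[str] | set[str] | None = None,
    max_iterations: int = 50,
    rel_tol: float = 0.005,
) -> ITSResult:
    """Iterative two-stage re-estimation of theta_CL, theta_V1, omega_CL, omega_V1.

    Components named in ``fixed`` (on top of those already fixed in ``init``)
    are never updated.  Structural parameters without IIV (Q, V2), the
    covariate coefficients and the residual-error SDs are taken as given.
    Stops when every updated parameter changes by less than ``rel_tol``
    (relative) or after ``max_iterations``, in which case a warning is issued
    and the last iterate is returned flagged as non-converged.
    """
    fixed_names = set(init.fixed) | set(fixed or ())
    pop = init
    history: list[dict] = []
    warm: list[tuple[float, float] | None] = [None] * len(dataset)
    map_results: list[MAPResult] = []
    converged = False
    iteration = 0

    for iteration in range(1, max_iterations + 1):
        map_results = [
            map_estimate(s, pop, multi_start=False, x0=warm[i])
            for i, s in enumerate(dataset.subjects)
        ]
        warm = [r.eta for r in map_results]
        eta = np.array([r.eta for r in map_results])
        pvar = np.array([r.posterior_variance for r in map_results])

        updates: dict[str, float] = {}
        if "theta_CL" not in fixed_names:
            updates["theta_CL"] = pop.theta_CL * math.exp(float(eta[:, 0].mean()))
        if "theta_V1" not in fixed_names:
            updates["theta_V1"] = pop.theta_V1 * math.exp(float(eta[:, 1].mean()))
        if "omega_CL" not in fixed_names and pop.omega_CL > 0:
            var = float(eta[:, 0].var()) + float(pvar[:, 0].mean())
            updates["omega_CL"] = math.sqrt(max(var, 1e-8))
        if "omega_V1" not in fixed_names and pop.omega_V1 > 0:
            var = float(eta[:, 1].var()) + float(pvar[:, 1].mean())
            updates["omega_V1"] = math.sqrt(max(var, 1e-8))

        rel_changes = {
            k: abs(v - getattr(pop, k)) / max(abs(getattr(pop, k)), 1e-12)
            for k, v in updates.items()
        }
        pop = pop.with_updates(**updates) if updates else pop
        history.append({"iteration": iteration, **updates, **{f"d_{k}": v for k, v in rel_changes.items()}})
        if not updates or max(rel_changes.values()) < rel_tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"iterative two-stage did not converge in {max_iterations} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return ITSResult(
        pop=pop,
        n_iterations=iteration,
        converged=converged,
        history=history,
        map_results=map_results,
    )
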