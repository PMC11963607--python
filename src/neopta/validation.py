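"""External-validation diagnostics for the population PK model.

Implements the standard pharmacometric validation battery:

* bias (mean prediction error, MPE) and imprecision (root mean squared
  error, RMSE) with confidence intervals, using the sign convention
  PE = prediction - observation so a negative MPE reads as under-prediction;
* normalized prediction distribution errors (NPDE): simulation-based,
  decorrelated residuals that are standard normal when the model describes
  the data, with tests of mean 0 and variance 1;
* visual predictive check (VPC) bin summaries: observed percentiles against
  simulated percentile bands, binned by time after the last dose;
* inter-individual-variability-versus-covariate diagnostics (rank
  correlations of the eta-hats with postnatal age and weights);
* the sensitivity sweep over the fixed IIV on the central volume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .attainment import TargetSet, summarize_cohort
from .estimation import MAPResult, Subject, TDMDataset, assess_subject, map_estimate
from .model import (
    NeonateCovariates,
    PopulationParameters,
    concentration_profile,
    typical_values,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BiasImprecision",
    "NpdeResult",
    "bias_imprecision",
    "iiv_covariate_diagnostics",
    "npde",
    "sensitivity_iiv_v1",
    "simulated_cmax_quartiles",
    "vpc",
]


# ---------------------------------------------------------------------------
# Bias and imprecision
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasImprecision:
    mpe: float
    mpe_ci: tuple[float, float]
    rmse: float
    rmse_ci: tuple[float, float]
    n: int


def bias_imprecision(
    pred,
    obs,
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
) -> BiasImprecision:
    """MPE (t-interval CI) and RMSE (bootstrap percentile CI) in mg/L.

    PE_j = pred_j - obs_j; RMSE >= |MPE| by construction.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have the same length")
    if pred.size < 2:
        raise ValueError("at least two prediction/observation pairs are required")
    pe = pred - obs
    n = pe.size
    mpe = float(pe.mean())
    se = float(pe.std(ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    rmse = float(np.sqrt(np.mean(pe**2)))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.sqrt(np.mean(pe[idx] ** 2, axis=1))
    lo, hi = np.quantile(boot, [0.5 - ci_level / 2.0, 0.5 + ci_level / 2.0])
    return BiasImprecision(
        mpe=mpe,
        mpe_ci=(mpe - tcrit * se, mpe + tcrit * se),
        rmse=rmse,
        rmse_ci=(float(lo), float(hi)),
        n=n,
    )


# ---------------------------------------------------------------------------
# Simulation machinery shared by NPDE and VPC
# ---------------------------------------------------------------------------


def _simulate_subject(
    subject: Subject,
    pop: PopulationParameters,
    times: np.ndarray,
    K: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """K replicate observation vectors (with residual error), shape (K, n)."""
    cl0, v10, q0, v20 = typical_values(pop, subject.covariates)
    eta_cl = rng.normal(0.0, pop.omega_CL, size=K) if pop.omega_CL > 0 else np.zeros(K)
    eta_v1 = rng.normal(0.0, pop.omega_V1, size=K) if pop.omega_V1 > 0 else np.zeros(K)
    f = concentration_profile(times, subject.doses, cl0 * np.exp(eta_cl), v10 * np.exp(eta_v1), q0, v20)
    eps_p = rng.normal(0.0, pop.sigma_prop, size=f.shape) if pop.sigma_prop > 0 else 0.0
    eps_a = rng.normal(0.0, pop.sigma_add, size=f.shape) if pop.sigma_add > 0 else 0.0
    return np.maximum(f * (1.0 + eps_p) + eps_a, 0.0)


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------


@dataclass
class NpdeResult:
    values: np.ndarray          # one npde per usable observation
    mean: float
    variance: float
    t_statistic: float
    t_pvalue: float             # H0: mean = 0
    var_statistic: float
    var_pvalue: float           # H0: variance = 1 (chi-square)
    n_fallback_subjects: int    # subjects decorrelated marginally


def npde(
    dataset: TDMDataset,
    pop: PopulationParameters,
    K: int = 1000,
    seed: int | None = None,
) -> NpdeResult:
    """Normalized prediction distribution errors over all non-BLQ observations.

    Per subject, K full design replicates are simulated under the population
    model; observed and simulated vectors are decorrelated with the inverse
    Cholesky factor of the simulated covariance; the prediction-discrepancy
    is the rank of the decorrelated observation among the decorrelated
    simulations (uniform jitter breaks ties), clipped to
    [1/(2K), 1 - 1/(2K)] and mapped through the standard-normal quantile.
    """
    if K < 500:
        raise ValueError("K must be at least 500")
    rng = np.random.default_rng(seed)
    all_npde: list[np.ndarray] = []
    n_fallback = 0
    for subject in dataset:
        obs = [(o.time_h, o.value_mg_L) for o in subject.observations if not o.blq]
        if not obs:
            continue
        times = np.array([t for t, _ in obs])
        y = np.array([v for _, v in obs])
        sims = _simulate_subject(subject, pop, times, K, rng)
        mu = sims.mean(axis=0)
        cov = np.cov(sims, rowvar=False).reshape(times.size, times.size)
        try:
            L = np.linalg.cholesky(cov)
            y_dec = np.linalg.solve(L, y - mu)
            sims_dec = np.linalg.solve(L, (sims - mu).T).T
        except np.linalg.LinAlgError:
            warnings.warn(
                f"subject {subject.subject_id}: singular simulated covariance; "
                "falling back to marginal (uncorrelated) decorrelation",
                RuntimeWarning,
                stacklevel=2,
            )
            n_fallback += 1
            sd = np.sqrt(np.maximum(np.diag(cov), 1e-12))
            y_dec = (y - mu) / sd
            sims_dec = (sims - mu) / sd
        ranks = (sims_dec < y_dec).sum(axis=0).astype(float)
        pde = (ranks + rng.uniform(0.0, 1.0, size=ranks.shape)) / K
        pde = np.clip(pde, 1.0 / (2 * K), 1.0 - 1.0 / (2 * K))
        all_npde.append(stats.norm.ppf(pde))
    values = np.concatenate(all_npde) if all_npde else np.empty(0)
    n = values.size
    if n < 2:
        raise ValueError("not enough usable observations for NPDE tests")
    t_stat, t_p = stats.ttest_1samp(values, 0.0)
    var = float(values.var(ddof=1))
    chi2 = (n - 1) * var  # H0 variance 1
    var_p = 2.0 * min(stats.chi2.cdf(chi2, df=n - 1), stats.chi2.sf(chi2, df=n - 1))
    return NpdeResult(
        values=values,
        mean=float(values.mean()),
        variance=var,
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        var_statistic=float(chi2),
        var_pvalue=float(var_p),
        n_fallback_subjects=n_fallback,
    )


# ---------------------------------------------------------------------------
# VPC
# ---------------------------------------------------------------------------


def _time_after_last_dose(subject: Subject, t: float) -> float:
    starts = [d.start_time_h for d in subject.doses if d.start_time_h <= t]
    return t - max(starts) if starts else t


def vpc(
    dataset: TDMDataset,
    pop: PopulationParameters,
    n_sim: int = 200,
    bins: int = 8,
    seed: int | None = None,
    band_level: float = 0.95,
) -> pd.DataFrame:
    """Visual-predictive-check bin summaries (plot-ready table).

    Observations are binned by quantiles of time after the last dose;
    observed 5/50/95th percentiles are compared with the ``band_level``
    simulated band of the same percentile in each bin.  Bins with fewer than
    5 observations are merged with their neighbor.
    """
    if n_sim < 200:
        raise ValueError("n_sim must be at least 200")
    rng = np.random.default_rng(seed)
    recs = []
    for si, subject in enumerate(dataset):
        for oi, o in enumerate(subject.observations):
            if not o.blq:
                recs.append((si, o.time_h, o.value_mg_L, _time_after_last_dose(subject, o.time_h)))
    if not recs:
        raise ValueError("no usable observations for a VPC")
    df = pd.DataFrame(recs, columns=["subject", "time", "dv", "tald"])
    edges = np.unique(np.quantile(df["tald"], np.linspace(0, 1, bins + 1)))
    edges[0] -= 1e-9
    which = np.searchsorted(edges, df["tald"].to_numpy(), side="right") - 1
    which = np.clip(which, 0, len(edges) - 2)
    # merge small bins with their left neighbor (leftmost merges right)
    counts = np.bincount(which, minlength=len(edges) - 1)
    keep = [0]
    for b in range(1, len(counts)):
        if counts[keep[-1]] < 5:
            counts[keep[-1]] += counts[b]
            logger.info("vpc: merged under-filled bin %d into its neighbor", b)
        else:
            keep.append(b)
            counts[b] = counts[b]
    # rebuild bin labels after merging
    bin_of = np.zeros(len(counts), dtype=int)
    ki = 0
    for b in range(len(counts)):
        if ki + 1 < len(keep) and b >= keep[ki + 1]:
            ki += 1
        bin_of[b] = ki
    df["bin"] = bin_of[which]

    pcts = (5.0, 50.0, 95.0)
    n_bins = df["bin"].max() + 1

    def binned_percentiles(values: np.ndarray) -> np.ndarray:
        out = np.empty((n_bins, len(pcts)))
        for b in range(n_bins):
            out[b] = np.percentile(values[df["bin"].to_numpy() == b], pcts)
        return out

    obs_p = binned_percentiles(df["dv"].to_numpy())

    sim_p = np.empty((n_sim, n_bins, len(pcts)))
    # simulate replicate datasets on the same design
    by_subject: dict[int, list[int]] = {}
    for row, (si, *_rest) in enumerate(recs):
        by_subject.setdefault(si, []).append(row)
    sim_values = np.empty((n_sim, len(recs)))
    for si, rows in by_subject.items():
        subject = dataset.subjects[si]
        times = df["time"].to_numpy()[rows]
        sims = _simulate_subject(subject, pop, times, n_sim, rng)
        sim_values[:, rows] = sims
    for k in range(n_sim):
        sim_p[k] = binned_percentiles(sim_values[k])

    alpha = (1.0 - band_level) / 2.0
    lo = np.quantile(sim_p, alpha, axis=0)
    hi = np.quantile(sim_p, 1.0 - alpha, axis=0)
    med = np.quantile(sim_p, 0.5, axis=0)

    rows = []
    for b in range(n_bins):
        sel = df[df["bin"] == b]
        row = {
            "bin": b,
            "tald_min": float(sel["tald"].min()),
            "tald_max": float(sel["tald"].max()),
            "tald_mid": float(sel["tald"].median()),
            "n": int(len(sel)),
        }
        for j, p in enumerate(pcts):
            tag = f"p{p:g}"
            row[f"obs_{tag}"] = float(obs_p[b, j])
            row[f"sim_{tag}_lo"] = float(lo[b, j])
            row[f"sim_{tag}_med"] = float(med[b, j])
            row[f"sim_{tag}_hi"] = float(hi[b, j])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IIV vs covariates
# ---------------------------------------------------------------------------


def iiv_covariate_diagnostics(
    map_results: list[MAPResult],
    covariates: list[NeonateCovariates],
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Per-subject eta-hat joined to covariates plus Spearman correlations.

    A constant eta (undefined correlation) is reported as rho = 0 with a
    ``degenerate`` flag.
    """
    if len(map_results) != len(covariates):
        raise ValueError("map_results and covariates must align")
    df = pd.DataFrame(
        {
            "eta_CL": [r.eta[0] for r in map_results],
            "eta_V1": [r.eta[1] for r in map_results],
            "pna_days": [c.pna_days for c in covariates],
            "bw_birth_g": [c.bw_birth_g for c in covariates],
            "bw_current_g": [c.bw_current_g for c in covariates],
        }
    )
    stats_out: dict[str, dict] = {}
    for cov_name in ("pna_days", "bw_birth_g", "bw_current_g"):
        if df["eta_CL"].nunique() < 2 or df[cov_name].nunique() < 2:
            stats_out[cov_name] = {"rho": 0.0, "pvalue": 1.0, "degenerate": True}
            continue
        rho, p = stats.spearmanr(df["eta_CL"], df[cov_name])
        stats_out[cov_name] = {"rho": float(rho), "pvalue": float(p), "degenerate": False}
    return df, stats_out


# ---------------------------------------------------------------------------
# Sensitivity of the fixed IIV on V1
# ---------------------------------------------------------------------------


def simulated_cmax_quartiles(
    pop: PopulationParameters,
    cov: NeonateCovariates,
    doses,
    n: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """(Q1, median, Q3) of the simulated 1 h concentration under full IIV."""
    rng = np.random.default_rng(seed)
    cl0, v10, q0, v20 = typical_values(pop, cov)
    eta_cl = rng.normal(0.0, pop.omega_CL, size=n) if pop.omega_CL > 0 else np.zeros(n)
    eta_v1 = rng.normal(0.0, pop.omega_V1, size=n) if pop.omega_V1 > 0 else np.zeros(n)
    t_peak = min(d.start_time_h for d in doses) + 1.0
    c = concentration_profile(
        np.array([t_peak]), doses, cl0 * np.exp(eta_cl), v10 * np.exp(eta_v1), q0, v20
    )[:, 0]
    q1, med, q3 = np.percentile(c, [25, 50, 75])
    return float(q1), float(med), float(q3)


def sensitivity_iiv_v1(
    dataset: TDMDataset,
    pop: PopulationParameters,
    grid=(0.0, 0.15, 0.30, 0.45, 0.60),
    targets: TargetSet = TargetSet(),
) -> pd.DataFrame:
    """Re-run MAP assessment and target attainment at each fixed omega_V1.

    Returns one row per grid point with overall attainment percentages for
    the clinically used targets and the interquartile range of the
    MAP-estimated Cmax across the dataset.
    """
    if any(w < 0 or w > 0.6 for w in grid):
        raise ValueError("omega_V1 grid must lie within [0, 0.6]")
    rows = []
    for w in grid:
        pop_w = pop.with_updates(omega_V1=w)
        assessments, categories = [], []
        for s in dataset:
            res = map_estimate(s, pop_w)
            assessments.append(assess_subject(s, pop_w, res))
            categories.append(str(s.assignment.category_id) if s.assignment else "all")
        summary = summarize_cohort(assessments, categories, targets)
        cmax = np.array([a.cmax_mg_L for a in assessments])
        q1, q3 = np.percentile(cmax, [25, 75])
        rows.append(
            {
                "omega_V1": w,
                "pct_cmax_ge_15": summary.percent("cmax_ge_15"),
                "pct_cmax_ge_24": summary.percent("cmax_ge_24"),
                "pct_cmin_le_3": summary.percent("cmin_le_3"),
                "pct_cmin_le_5": summary.percent("cmin_le_5"),
                "cmax_iqr_mg_L": float(q3 - q1),
            }
        )
    return pd.DataFrame(rows)
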