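import numpy as np
import pytest

from neopta import (
    ConcentrationObservation,
    NeonateCovariates,
    Subject,
    TDMDataset,
    assign_complex,
    assign_simplified,
    build_dose_events,
    default_parameters,
    individual_parameters,
    simulate_observation,
)
from neopta.model import concentration


@pytest.fixture(scope="session")
def pop():
    """Packaged default population model."""
    return default_parameters()


@pytest.fixture
def preterm_cov():
    return NeonateCovariates(ga_weeks=28.7, pna_days=9, bw_birth_g=1100, bw_current_g=1100)


@pytest.fixture
def term_cov():
    return NeonateCovariates(ga_weeks=39.0, pna_days=2, bw_birth_g=3400, bw_current_g=3300)


def make_subject(
    pop,
    cov,
    eta,
    times,
    seed=0,
    regimen="simplified",
    sigma_prop=None,
    sigma_add=None,
    subject_id="s1",
):
    """Simulate one subject with known random effects at given sampling times."""
    noise = pop
    if sigma_prop is not None or sigma_add is not None:
        noise = pop.with_updates(
            sigma_prop=pop.sigma_prop if sigma_prop is None else sigma_prop,
            sigma_add=pop.sigma_add if sigma_add is None else sigma_add,
        )
    assignment = assign_simplified(cov) if regimen == "simplified" else assign_complex(cov)
    doses = build_dose_events(assignment, cov.bw_current_g, n_doses=2)
    ip = individual_parameters(noise, cov, eta)
    rng = np.random.default_rng(seed)
    obs = []
    for t in times:
        c = float(concentration(t, doses, ip))
        y, blq = simulate_observation(c, noise, rng)
        obs.append(ConcentrationObservation(time_h=t, value_mg_L=y, blq=blq))
    return Subject(subject_id, cov, doses, obs, assignment=assignment), noise


@pytest.fixture
def dense_subject(pop, preterm_cov):
    """High-information, low-noise subject with known eta = (0.3, -0.2)."""
    subject, noise_pop = make_subject(
        pop,
        preterm_cov,
        eta=(0.3, -0.2),
        times=(0.6, 1.0, 2.0, 6.0, 12.0, 24.0),
        seed=42,
        sigma_prop=0.02,
        sigma_add=0.05,
    )
    return subject, noise_pop, (0.3, -0.2)
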