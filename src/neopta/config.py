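"""Population-model configuration files (YAML/JSON, schema version 1).

The engine never hard-codes population parameter values: they are read from
a configuration file.  The packaged default (``data/population_model.yaml``)
carries the covariate structure of the neonatal amikacin model this package
evaluates — birth weight, postnatal age and ibuprofen on clearance, current
weight on central volume — with constants calibrated to published neonatal
amikacin kinetics (see docs/methods.md).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .model import ConfigurationError, CovariateTerm, PopulationParameters

SCHEMA_VERSION = 1

__all__ = ["default_parameters", "load_population_parameters", "save_population_parameters"]


def _parse(doc: dict) -> PopulationParameters:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported schema_version {doc.get('schema_version')!r} (expected {SCHEMA_VERSION})"
        )
    try:
        model = doc["model"]
        theta = model["theta"]
        terms = tuple(
            CovariateTerm(
                target=t["target"],
                kind=t["kind"],
                covariate=t["covariate"],
                coefficient=float(t["coefficient"]),
                reference=float(t.get("reference", 0.0)),
            )
            for t in model.get("covariates", [])
        )
        iiv = model.get("iiv", {})
        residual = model["residual"]
    except KeyError as exc:
        raise ConfigurationError(f"missing configuration key: {exc}") from None

    fixed = set()
    omegas = {}
    for name, entry in iiv.items():
        if name not in ("omega_CL", "omega_V1"):
            raise ConfigurationError(f"unknown IIV component {name!r}")
        if isinstance(entry, dict):
            omegas[name] = float(entry.get("value", 0.30 if name == "omega_V1" else 0.0))
            if entry.get("fixed", False):
                fixed.add(name)
        else:
            omegas[name] = float(entry)
    # a "fixed" marker without a value keeps the 0.30 default on omega_V1
    omegas.setdefault("omega_V1", 0.30)

    scaling = model.get("scaling", {})
    return PopulationParameters(
        theta_CL=float(theta["CL"]),
        theta_V1=float(theta["V1"]),
        theta_Q=float(theta.get("Q", 0.0)),
        theta_V2=float(theta.get("V2", 0.0)),
        covariate_terms=terms,
        omega_CL=float(omegas.get("omega_CL", 0.0)),
        omega_V1=float(omegas["omega_V1"]),
        sigma_prop=float(residual.get("sigma_prop", 0.0)),
        sigma_add=float(residual.get("sigma_add", 0.0)),
        scale_q_with_v1=bool(scaling.get("q_with_v1", False)),
        scale_v2_with_v1=bool(scaling.get("v2_with_v1", False)),
        fixed=frozenset(fixed) if fixed else frozenset(),
    )


def load_population_parameters(path: str | Path) -> PopulationParameters:
    """Load a population-model configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path} does not contain a configuration mapping")
    return _parse(doc)


def save_population_parameters(pop: PopulationParameters, path: str | Path) -> None:
    """Write a configuration file that round-trips through the loader."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "model": {
            "theta": {
                "CL": pop.theta_CL,
                "V1": pop.theta_V1,
                "Q": pop.theta_Q,
                "V2": pop.theta_V2,
            },
            "covariates": [
                {
                    "target": t.target,
                    "kind": t.kind,
                    "covariate": t.covariate,
                    "reference": t.reference,
                    "coefficient": t.coefficient,
                }
                for t in pop.covariate_terms
            ],
            "iiv": {
                "omega_CL": {"value": pop.omega_CL, "fixed": "omega_CL" in pop.fixed},
                "omega_V1": {"value": pop.omega_V1, "fixed": "omega_V1" in pop.fixed},
            },
            "residual": {"sigma_prop": pop.sigma_prop, "sigma_add": pop.sigma_add},
            "scaling": {"q_with_v1": pop.scale_q_with_v1, "v2_with_v1": pop.scale_v2_with_v1},
        },
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def default_parameters() -> PopulationParameters:
    """The packaged default neonatal amikacin population model."""
    text = resources.files("neopta").joinpath("data/population_model.yaml").read_text()
    return _parse(yaml.safe_load(text))
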