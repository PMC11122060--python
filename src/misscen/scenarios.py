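"""Machine-readable catalog of the ten healthcare missingness scenarios.

Each scenario describes one real-world route by which health data end up
missing (patients not visiting, physicians skipping diagnostically
irrelevant tests, unrecorded observations, preprocessing drops, ...),
together with coarse flags answering the theoretical inquiries that drive
identification, estimation and sensitivity analysis.

``mechanism_template`` translates a scenario selection into mechanism
skeletons that :func:`misscen.mgraph.build_graph` accepts once
coefficients are supplied.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, asdict

import yaml

from .mgraph import SELECTION_NODE, indicator_name

__all__ = ["ScenarioSpec", "get_scenario", "all_scenarios", "mechanism_template", "catalog_to_yaml"]


@dataclass(frozen=True)
class ScenarioSpec:
    id: int
    title: str
    agent: str
    mechanism_class: str  # exogenous | observed_history | outcome_dependent | self_masking_possible
    shift_prone: bool
    nde_risk: bool
    interference_risk: bool
    selection_bias: bool
    monotone_inducing: bool
    sensitivity_hint: str


def _load_catalog() -> dict[int, ScenarioSpec]:
    ref = importlib.resources.files("misscen").joinpath("data/scenario_catalog.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    catalog = {}
    for entry in raw["scenarios"]:
        spec = ScenarioSpec(**{k: entry[k] for k in ScenarioSpec.__dataclass_fields__})
        catalog[spec.id] = spec
    ids = sorted(catalog)
    if ids != list(range(1, 11)):
        raise RuntimeError(f"scenario catalog must contain exactly ids 1..10, got {ids}")
    return catalog


_CATALOG = _load_catalog()


def get_scenario(scenario_id: int) -> ScenarioSpec:
    """Return the catalogued scenario; ids run 1..10."""
    try:
        return _CATALOG[int(scenario_id)]
    except (KeyError, ValueError, TypeError):
        raise LookupError(f"no scenario with id {scenario_id!r}; valid ids are 1..10") from None


def all_scenarios() -> tuple[ScenarioSpec, ...]:
    return tuple(_CATALOG[i] for i in range(1, 11))


def catalog_to_yaml() -> str:
    """Serialize the catalog back to YAML (round-trip with the shipped file)."""
    return yaml.safe_dump(
        {"scenarios": [asdict(s) for s in all_scenarios()]}, sort_keys=False, allow_unicode=True
    )


def mechanism_template(
    s: ScenarioSpec, variables, outcome: str | None = None
) -> list[dict]:
    """Mechanism skeletons implied by a scenario's mechanism class.

    Coefficients are left symbolic (``None``); the skeletons become
    buildable by ``build_graph`` once intercepts/weights or probabilities
    are filled in.

    - ``exogenous``: parentless indicators (e.g. invalid-entry drops).
    - ``observed_history``: the indicator of the k-th variable is parented
      by every earlier variable in the given order, mirroring a diagnostic
      flowchart where primary results drive later measurements.
    - ``outcome_dependent``: a single selection node parented by the
      designated outcome drives every indicator (whole-row omission).
    - ``self_masking_possible``: each indicator parented by its own
      variable — flagged so identification can refuse it.
    """
    variables = list(variables)
    if not variables:
        raise ValueError("mechanism_template needs at least one variable")

    if s.mechanism_class == "exogenous":
        return [
            {"target": indicator_name(v), "parents": [], "link": "constant", "probability": None}
            for v in variables
        ]
    if s.mechanism_class == "observed_history":
        return [
            {
                "target": indicator_name(v),
                "parents": variables[:k],
                "link": "constant" if k == 0 else "logistic",
                "probability": None if k else None,
                "intercept": None,
                "weights": None,
            }
            for k, v in enumerate(variables)
        ]
    if s.mechanism_class == "outcome_dependent":
        if outcome is None:
            raise ValueError(
                f"scenario {s.id} ({s.title!r}) drives availability through the outcome; "
                "a designated outcome variable is required"
            )
        skeletons = [
            {
                "target": SELECTION_NODE,
                "parents": [outcome],
                "link": "logistic",
                "intercept": None,
                "weights": None,
            }
        ]
        skeletons += [
            {"target": indicator_name(v), "parents": [], "link": "constant", "probability": None}
            for v in variables
        ]
        return skeletons
    if s.mechanism_class == "self_masking_possible":
        return [
            {
                "target": indicator_name(v),
                "parents": [v],
                "link": "logistic",
                "intercept": None,
                "weights": None,
            }
            for v in variables
        ]
    raise ValueError(f"unknown mechanism class {s.mechanism_class!r}")
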