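"""Synthetic cohorts: structural causal models plus scenario-driven missingness.

The generator serves two purposes. First, it produces the cardiovascular
study population used throughout the simulation study: a four-variable
cohort (age, BMI, systolic BP, binary CVD outcome) drawn from a shared
counterfactual DAG, with missingness induced by three scenario
combinations — invalid-entry drops, patient non-visit selection, and
diagnostically driven BP measurement with unrecorded covariates. Second,
it provides the small worked-example fixtures (the four-patient vector
(2,3,4,7), the no-direct-effect violation, and the monotone/non-monotone
staircases).

Counterfactual tables are plain pandas DataFrames; an
:class:`IncompleteDataset` couples the masked proxy table with the
indicator matrix and, when simulated, the generating ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .mgraph import (
    MGraph,
    MechanismSpec,
    Policy,
    SELECTION_NODE,
    build_graph,
    indicator_name,
)

__all__ = [
    "NodeSpec",
    "StructuralModel",
    "IncompleteDataset",
    "ParamSet",
    "SearchSpace",
    "DEFAULT_SEARCH_SPACE",
    "sample_population",
    "apply_missingness",
    "make_cvd_case",
    "draw_case_params",
    "fixture_example1",
    "fixture_nde",
    "staircase_dataset",
    "write_csv",
    "read_csv",
]

CVD_VARIABLES = ("age", "BMI", "BP", "CVD")


# ---------------------------------------------------------------------------
# Structural causal models


@dataclass(frozen=True)
class NodeSpec:
    """One structural equation: linear-Gaussian or logistic-Bernoulli."""

    parents: tuple[str, ...]
    kind: str  # linear_gaussian | logistic_bernoulli
    intercept: float
    weights: tuple[float, ...] = ()
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.kind not in ("linear_gaussian", "logistic_bernoulli"):
            raise ValueError(f"unknown equation kind {self.kind!r}")
        if len(self.weights) != len(self.parents):
            raise ValueError("one weight per parent required")
        if self.kind == "linear_gaussian" and self.noise_sd <= 0:
            raise ValueError("noise scale must be positive")


@dataclass(frozen=True)
class StructuralModel:
    """Acyclic set of structural equations over counterfactual variables."""

    nodes: dict[str, NodeSpec]
    outcome: str | None = None

    def topological_order(self) -> list[str]:
        order: list[str] = []
        seen: set[str] = set()

        def visit(v: str, stack: tuple[str, ...]):
            if v in seen:
                return
            if v in stack:
                raise ValueError(f"cycle in structural model at {v!r}")
            for p in self.nodes[v].parents:
                if p not in self.nodes:
                    raise ValueError(f"node {v!r} has undeclared parent {p!r}")
                visit(p, stack + (v,))
            seen.add(v)
            order.append(v)

        for v in self.nodes:
            visit(v, ())
        return order

    def to_json(self) -> dict:
        return {
            "outcome": self.outcome,
            "nodes": {v: asdict(s) for v, s in self.nodes.items()},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "StructuralModel":
        nodes = {
            v: NodeSpec(
                parents=tuple(s["parents"]),
                kind=s["kind"],
                intercept=s["intercept"],
                weights=tuple(s.get("weights", ())),
                noise_sd=s.get("noise_sd", 1.0),
            )
            for v, s in obj["nodes"].items()
        }
        return cls(nodes=nodes, outcome=obj.get("outcome"))


def sample_population(m: StructuralModel, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` i.i.d. rows from the structural model in topological order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for v in m.topological_order():
        spec = m.nodes[v]
        eta = np.full(n, spec.intercept, dtype=float)
        for w, p in zip(spec.weights, spec.parents):
            eta += w * cols[p]
        if spec.kind == "linear_gaussian":
            cols[v] = eta + rng.normal(0.0, spec.noise_sd, size=n)
        else:
            prob = 1.0 / (1.0 + np.exp(-eta))
            cols[v] = (rng.random(n) < prob).astype(float)
    return pd.DataFrame({v: cols[v] for v in m.nodes})


# ---------------------------------------------------------------------------
# Incomplete datasets


@dataclass
class IncompleteDataset:
    """Masked proxy table + indicator matrix, with simulation ground truth.

    ``proxies`` holds NaN where the matching indicator is 0. When the
    dataset was simulated, ``counterfactual`` stores the full pre-selection
    table and ``selection_mask`` (aligned to it) marks the rows that
    survived whole-row selection; ``proxies``/``indicators`` cover only the
    surviving rows.
    """

    proxies: pd.DataFrame
    indicators: pd.DataFrame
    counterfactual: pd.DataFrame | None = None
    graph: MGraph | None = None
    selection_mask: pd.Series | None = None

    def __post_init__(self):
        if list(self.proxies.columns) != list(self.indicators.columns):
            raise ValueError("proxy and indicator columns must align")
        masked_ok = (
            self.proxies.isna().to_numpy() == (self.indicators.to_numpy() == 0)
        ).all()
        if not masked_ok:
            raise ValueError("masking violated: NaN entries must match indicator zeros")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.proxies.columns)

    @property
    def n_rows(self) -> int:
        return len(self.proxies)

    def kept_counterfactual(self) -> pd.DataFrame | None:
        """Counterfactual rows that survived selection (None on real data)."""
        if self.counterfactual is None:
            return None
        if self.selection_mask is None:
            return self.counterfactual
        return self.counterfactual.loc[self.selection_mask.astype(bool)].reset_index(drop=True)

    def complete_rows(self) -> pd.Series:
        return (self.indicators == 1).all(axis=1)

    def pattern_set(self):
        from .mgraph import PatternSet

        pats = self.indicators.astype(int).apply(tuple, axis=1)
        counts = pats.value_counts()
        return PatternSet(
            variables=self.variables,
            patterns=list(counts.index),
            counts=[int(c) for c in counts.to_numpy()],
        )


def _mechanism_order(g: MGraph) -> list[str]:
    """Indicators sorted so that indicator-parents are sampled first."""
    targets = list(g.mechanisms)
    order: list[str] = []
    seen: set[str] = set()

    def visit(t: str, stack):
        if t in seen:
            return
        if t in stack:
            raise ValueError(f"indicator dependency cycle at {t}")
        for p in g.mechanisms[t].parents:
            if p in g.mechanisms:
                visit(p, stack + (t,))
        seen.add(t)
        order.append(t)

    if SELECTION_NODE in g.mechanisms:
        visit(SELECTION_NODE, ())
    for t in targets:
        visit(t, ())
    return order


def _mechanism_probs(m: MechanismSpec, values: dict[str, np.ndarray], n: int) -> np.ndarray:
    if m.link == "constant":
        return np.full(n, float(m.probability))
    eta = np.full(n, float(m.intercept))
    for w, p in zip(m.weights, m.parents):
        if p not in values:
            raise ValueError(
                f"mechanism for {m.target} references parent {p!r} not yet resolved"
            )
        eta += w * values[p]
    return 1.0 / (1.0 + np.exp(-eta))


def apply_missingness(table: pd.DataFrame, g: MGraph, seed: int) -> IncompleteDataset:
    """Sample indicators from the graph's mechanisms and mask the table.

    Indicator parents are sampled before their children; if the graph has a
    selection node, rows with selection 0 are dropped entirely and reported
    only through the selection mask.
    """
    missing_vars = [v for v in g.variables if v not in table.columns]
    if missing_vars:
        raise ValueError(f"table lacks counterfactual columns {missing_vars}")
    n = len(table)
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {v: table[v].to_numpy(dtype=float) for v in g.variables}

    sampled: dict[str, np.ndarray] = {}
    for target in _mechanism_order(g):
        prob = _mechanism_probs(g.mechanisms[target], values, n)
        draw = (rng.random(n) < prob).astype(int)
        sampled[target] = draw
        values[target] = draw.astype(float)

    if SELECTION_NODE in sampled:
        sel = sampled[SELECTION_NODE].astype(bool)
        for v in g.variables:
            sampled[indicator_name(v)] = sampled[indicator_name(v)] * sel.astype(int)
        mask = pd.Series(sel, index=table.index, name=SELECTION_NODE)
    else:
        sel = np.ones(n, dtype=bool)
        mask = None

    indicators = pd.DataFrame(
        {v: sampled[indicator_name(v)][sel] for v in g.variables}
    ).reset_index(drop=True)
    kept = table.loc[sel, list(g.variables)].reset_index(drop=True)
    proxies = kept.astype(float).where(indicators == 1, other=np.nan)
    return IncompleteDataset(
        proxies=proxies,
        indicators=indicators,
        counterfactual=table.loc[:, list(g.variables)].reset_index(drop=True),
        graph=g,
        selection_mask=mask.reset_index(drop=True) if mask is not None else None,
    )


# ---------------------------------------------------------------------------
# CVD study population


@dataclass(frozen=True)
class SearchSpace:
    """Uniform search-space bounds for one simulation iteration.

    Scales follow routine clinical magnitudes: age in years around 60,
    BMI in kg/m^2 around 27, systolic BP in mmHg around 130, CVD
    prevalence of an at-risk cohort between 20% and 40%. Per-variable
    target missingness rates sit between 20% and 50%, and the selection
    scenario visits sick patients more often than healthy ones.
    """

    age_mean: float = 60.0
    age_sd: float = 10.0
    bmi_mean: float = 27.0
    bmi_slope: tuple[float, float] = (0.02, 0.12)
    bmi_sd: tuple[float, float] = (2.0, 4.0)
    bp_mean: float = 130.0
    bp_coef: tuple[float, float] = (0.2, 1.0)
    bp_sd: tuple[float, float] = (5.0, 15.0)
    cvd_coef_std: tuple[float, float] = (0.3, 1.2)
    cvd_prevalence: tuple[float, float] = (0.2, 0.4)
    missing_rate: tuple[float, float] = (0.2, 0.5)
    rate_bounds: tuple[float, float] = (0.1, 0.6)
    mech_slope_std: tuple[float, float] = (0.5, 1.5)
    visit_prob_sick: tuple[float, float] = (0.7, 0.95)
    visit_prob_healthy: tuple[float, float] = (0.3, 0.6)
    n_reference: int = 4000


DEFAULT_SEARCH_SPACE = SearchSpace()


@dataclass(frozen=True)
class ParamSet:
    """All structural and mechanism coefficients for one iteration."""

    case_id: int
    seed: int
    structural: dict = field(default_factory=dict)
    mechanisms: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "ParamSet":
        return cls(**obj)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _build_cvd_model(structural: dict) -> StructuralModel:
    s = structural
    return StructuralModel(
        nodes={
            "age": NodeSpec((), "linear_gaussian", s["age_mean"], (), s["age_sd"]),
            "BMI": NodeSpec(
                ("age",), "linear_gaussian", s["bmi_intercept"], (s["bmi_slope"],), s["bmi_sd"]
            ),
            "BP": NodeSpec(
                ("age", "BMI"),
                "linear_gaussian",
                s["bp_intercept"],
                (s["bp_age"], s["bp_bmi"]),
                s["bp_sd"],
            ),
            "CVD": NodeSpec(
                ("age", "BMI", "BP"),
                "logistic_bernoulli",
                s["cvd_intercept"],
                (s["cvd_age"], s["cvd_bmi"], s["cvd_bp"]),
            ),
        },
        outcome="CVD",
    )


def _solve_intercept(eta_no_intercept: np.ndarray, target: float) -> float:
    """Intercept c such that mean(sigmoid(c + eta)) == target, by bisection."""
    lo, hi = -30.0, 30.0

    def rate(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + eta_no_intercept)))))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def draw_case_params(
    case_id: int, seed: int, space: SearchSpace = DEFAULT_SEARCH_SPACE
) -> ParamSet:
    """Draw one iteration's coefficients uniformly from the search space.

    Mechanism intercepts are solved numerically (against a seeded reference
    sample) to hit the drawn target missingness rates; the draw is
    rejection-resampled until every induced marginal missingness rate lies
    within the documented bounds.
    """
    if case_id not in (1, 2, 3):
        raise ValueError(f"case_id must be 1, 2 or 3, got {case_id}")
    rng = np.random.default_rng(seed)
    sp = space

    for attempt in range(1000):
        u = lambda lohi: float(rng.uniform(*lohi))  # noqa: E731
        structural = {
            "age_mean": sp.age_mean,
            "age_sd": sp.age_sd,
            "bmi_slope": u(sp.bmi_slope),
            "bmi_sd": u(sp.bmi_sd),
            "bp_age": u(sp.bp_coef),
            "bp_bmi": u(sp.bp_coef),
            "bp_sd": u(sp.bp_sd),
            "cvd_prevalence": u(sp.cvd_prevalence),
        }
        structural["bmi_intercept"] = sp.bmi_mean - structural["bmi_slope"] * sp.age_mean
        structural["bp_intercept"] = (
            sp.bp_mean - structural["bp_age"] * sp.age_mean - structural["bp_bmi"] * sp.bmi_mean
        )

        # reference sample of the covariates for standardization + intercepts
        ref_seed = int(rng.integers(0, 2**31 - 1))
        partial = StructuralModel(
            nodes={
                "age": NodeSpec((), "linear_gaussian", sp.age_mean, (), sp.age_sd),
                "BMI": NodeSpec(
                    ("age",),
                    "linear_gaussian",
                    structural["bmi_intercept"],
                    (structural["bmi_slope"],),
                    structural["bmi_sd"],
                ),
                "BP": NodeSpec(
                    ("age", "BMI"),
                    "linear_gaussian",
                    structural["bp_intercept"],
                    (structural["bp_age"], structural["bp_bmi"]),
                    structural["bp_sd"],
                ),
            }
        )
        ref = sample_population(partial, sp.n_reference, ref_seed)
        sds = {v: float(ref[v].std()) for v in ("age", "BMI", "BP")}

        # CVD: standardized coefficient magnitudes, risk factors positive
        for var, key in (("age", "cvd_age"), ("BMI", "cvd_bmi"), ("BP", "cvd_bp")):
            structural[key] = u(sp.cvd_coef_std) / sds[var]
        eta = sum(
            structural[k] * ref[v].to_numpy()
            for v, k in (("age", "cvd_age"), ("BMI", "cvd_bmi"), ("BP", "cvd_bp"))
        )
        structural["cvd_intercept"] = _solve_intercept(eta, structural["cvd_prevalence"])

        mechanisms: dict = {"target_missing": {}}
        for v in ("age", "BMI", "BP"):
            mechanisms["target_missing"][v] = u(sp.missing_rate)
        mechanisms["p_obs"] = {
            v: 1.0 - mechanisms["target_missing"][v] for v in ("age", "BMI", "BP")
        }

        if case_id == 2:
            mechanisms["visit_prob_sick"] = u(sp.visit_prob_sick)
            mechanisms["visit_prob_healthy"] = u(sp.visit_prob_healthy)
        if case_id == 3:
            w_age = u(sp.mech_slope_std) / sds["age"]
            w_bmi = u(sp.mech_slope_std) / sds["BMI"]
            eta_bp = w_age * ref["age"].to_numpy() + w_bmi * ref["BMI"].to_numpy()
            target_obs = mechanisms["p_obs"]["BP"]
            mechanisms["bp_mech"] = {
                "w_age": w_age,
                "w_bmi": w_bmi,
                "intercept": _solve_intercept(eta_bp, target_obs),
            }

        params = ParamSet(case_id=case_id, seed=seed, structural=structural, mechanisms=mechanisms)
        if _rates_in_bounds(params, ref, sp):
            return params
    raise RuntimeError("1000 consecutive rejections: search-space configuration error")


def _rates_in_bounds(params: ParamSet, ref: pd.DataFrame, sp: SearchSpace) -> bool:
    """Check induced marginal missingness rates on the reference sample."""
    lo, hi = sp.rate_bounds
    mech = params.mechanisms
    for v in ("age", "BMI"):
        if not (lo <= 1.0 - mech["p_obs"][v] <= hi):
            return False
    if params.case_id == 3:
        bm = mech["bp_mech"]
        eta = bm["intercept"] + bm["w_age"] * ref["age"].to_numpy() + bm["w_bmi"] * ref[
            "BMI"
        ].to_numpy()
        rate = 1.0 - float(np.mean(1.0 / (1.0 + np.exp(-eta))))
    else:
        rate = 1.0 - mech["p_obs"]["BP"]
    return lo <= rate <= hi


def make_cvd_case(case_id: int, params: ParamSet) -> tuple[StructuralModel, MGraph]:
    """Assemble the structural model and m-graph for one scenario case.

    All cases share the counterfactual DAG age→BMI, age→BP, BMI→BP,
    age→CVD, BMI→CVD, BP→CVD and drop invalid entries at random
    (exogenous constant indicators). Case 2 adds whole-row selection
    driven by the CVD outcome (healthy patients visit less). Case 3
    replaces the BP indicator by a diagnostically driven logistic
    mechanism with parents age and BMI, the covariates keeping exogenous
    recording indicators.
    """
    if case_id not in (1, 2, 3):
        raise ValueError(f"case_id must be 1, 2 or 3, got {case_id}")
    model = _build_cvd_model(params.structural)
    mech = params.mechanisms
    p_obs = mech["p_obs"]

    mechanisms: dict[str, dict] = {
        indicator_name("age"): {"parents": [], "link": "constant", "probability": p_obs["age"]},
        indicator_name("BMI"): {"parents": [], "link": "constant", "probability": p_obs["BMI"]},
        indicator_name("BP"): {"parents": [], "link": "constant", "probability": p_obs["BP"]},
        indicator_name("CVD"): {"parents": [], "link": "constant", "probability": 1.0},
    }
    selection = False
    if case_id == 2:
        s1, s0 = mech["visit_prob_sick"], mech["visit_prob_healthy"]
        mechanisms[SELECTION_NODE] = {
            "parents": ["CVD"],
            "link": "logistic",
            "intercept": _logit(s0),
            "weights": [_logit(s1) - _logit(s0)],
        }
        selection = True
    if case_id == 3:
        bm = mech["bp_mech"]
        mechanisms[indicator_name("BP")] = {
            "parents": ["age", "BMI"],
            "link": "logistic",
            "intercept": bm["intercept"],
            "weights": [bm["w_age"], bm["w_bmi"]],
        }

    graph = build_graph(
        {
            "variables": list(CVD_VARIABLES),
            "edges": [
                ["age", "BMI"],
                ["age", "BP"],
                ["BMI", "BP"],
                ["age", "CVD"],
                ["BMI", "CVD"],
                ["BP", "CVD"],
            ],
            "mechanisms": mechanisms,
            "selection_node": selection,
        }
    )
    return model, graph


# ---------------------------------------------------------------------------
# Worked-example fixtures


def fixture_example1() -> tuple[pd.DataFrame, dict[str, Policy]]:
    """Four-patient single-variable cohort with three availability policies.

    The counterfactual column is (2, 3, 4, 7). The ``init`` policy masks
    the fourth patient, ``new`` keeps only values >= 4, and ``full``
    masks nothing. Thresholds are encoded as saturated logistic
    mechanisms, so masking is deterministic to float precision.
    """
    table = pd.DataFrame({"X1": [2.0, 3.0, 4.0, 7.0]})
    r = indicator_name("X1")
    policies = {
        "init": Policy(
            "init",
            {r: MechanismSpec(r, ("X1",), "logistic", intercept=550.0, weights=(-100.0,))},
        ),
        "new": Policy(
            "new",
            {r: MechanismSpec(r, ("X1",), "logistic", intercept=-350.0, weights=(100.0,))},
        ),
        "full": Policy("full", {r: MechanismSpec(r, link="constant", probability=1.0)}),
    }
    return table, policies


def example1_dataset(policy: str = "init", seed: int = 0) -> IncompleteDataset:
    """The four-patient fixture masked under one of its three policies."""
    table, policies = fixture_example1()
    base = build_graph(
        {
            "variables": ["X1"],
            "edges": [],
            "mechanisms": {
                indicator_name("X1"): {"parents": [], "link": "constant", "probability": 1.0}
            },
        }
    )
    from .mgraph import apply_policy

    g = apply_policy(base, policies[policy])
    return apply_missingness(table, g, seed)


def fixture_nde(
    w: float, w0: float, n: int, seed: int, p_obs: float = 0.5
) -> IncompleteDataset:
    """Cohort violating the no-direct-effect assumption: measuring X shifts Y.

    Y follows w*X + eps when X is unmeasured and w*X + w0 + eps when it is
    measured, so the mean of Y depends on the availability policy itself.
    The returned dataset's graph carries the nde_violating flag and the
    identification step refuses standard factorization on it.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=n)
    r_x = (rng.random(n) < p_obs).astype(int)
    y = w * x + w0 * r_x + rng.normal(0.0, 1.0, size=n)
    table = pd.DataFrame({"X": x, "Y": y})
    graph = build_graph(
        {
            "variables": ["X", "Y"],
            "edges": [["X", "Y"], [indicator_name("X"), "Y"]],
            "mechanisms": {
                indicator_name("X"): {"parents": [], "link": "constant", "probability": p_obs},
                indicator_name("Y"): {"parents": [], "link": "constant", "probability": 1.0},
            },
            "nde_violating": True,
        }
    )
    indicators = pd.DataFrame({"X": r_x, "Y": np.ones(n, dtype=int)})
    proxies = table.where(indicators == 1, other=np.nan)
    return IncompleteDataset(
        proxies=proxies, indicators=indicators, counterfactual=table, graph=graph
    )


def staircase_dataset(
    n: int,
    seed: int,
    pattern_probs: tuple[float, ...] = (0.7, 0.1, 0.1, 0.1),
    dropout_slope: float = 0.0,
) -> IncompleteDataset:
    """Monotone staircase over four standard-normal variables.

    Pattern j (j=0 complete) observes only the first ``4-j`` variables.
    With ``dropout_slope`` nonzero, the chance of dropping after X1 grows
    logistically with X1 (a sequential, covariate-driven mechanism);
    otherwise pattern membership is covariate-free multinomial.
    """
    if not math.isclose(sum(pattern_probs), 1.0, abs_tol=1e-9):
        raise ValueError("pattern probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    d = len(pattern_probs)
    x = rng.normal(0.0, 1.0, size=(n, d))
    table = pd.DataFrame(x, columns=[f"X{j + 1}" for j in range(d)])

    if dropout_slope == 0.0:
        pattern = rng.choice(d, size=n, p=pattern_probs)
    else:
        # sequential hazards tilted by X1; base hazards from pattern_probs
        pattern = np.zeros(n, dtype=int)
        alive = np.ones(n, dtype=bool)
        surv = 1.0
        for j in range(d - 1, 0, -1):
            base = pattern_probs[j] / surv
            base = min(max(base, 1e-6), 1 - 1e-6)
            eta = math.log(base / (1 - base)) + dropout_slope * table["X1"].to_numpy()
            h = 1.0 / (1.0 + np.exp(-eta))
            drop = alive & (rng.random(n) < h)
            pattern[drop] = j
            alive &= ~drop
            surv -= pattern_probs[j]
    indicators = pd.DataFrame(
        {f"X{k + 1}": (pattern <= d - 1 - k).astype(int) for k in range(d)}
    )
    proxies = table.where(indicators == 1, other=np.nan)
    return IncompleteDataset(proxies=proxies, indicators=indicators, counterfactual=table)


# ---------------------------------------------------------------------------
# CSV round trip (empty cell = missing)


def write_csv(ds: IncompleteDataset, path, with_indicators: bool = False) -> None:
    out = ds.proxies.copy()
    if with_indicators:
        for v in ds.variables:
            out[f"{v}_R"] = ds.indicators[v].astype(int)
    out.to_csv(path, index=False, na_rep="")


def read_csv(path) -> IncompleteDataset:
    raw = pd.read_csv(path)
    r_cols = [c for c in raw.columns if c.endswith("_R")]
    proxies = raw[[c for c in raw.columns if not c.endswith("_R")]].astype(float)
    if r_cols:
        indicators = raw[r_cols].rename(columns={c: c[:-2] for c in r_cols}).astype(int)
        indicators = indicators[list(proxies.columns)]
    else:
        indicators = (~proxies.isna()).astype(int)
    return IncompleteDataset(proxies=proxies, indicators=indicators)


def write_paramset(params: ParamSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_json(), fh, indent=1)


def read_paramset(path) -> ParamSet:
    with open(path) as fh:
        return ParamSet.from_json(json.load(fh))
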