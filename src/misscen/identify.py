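"""Identification of propensity scores and importance ratios from m-graphs.

Whether the complete-case probability ``p(R = 1 | x)`` (the IPW
denominator) can be estimated from the observed ``(X*, R)`` distribution
is a property of the m-graph alone. The engine factorizes the joint
observation probability along an ordering of the indicators,

    PS(x) = prod_k  p(R_k = 1 | preceding R's = 1, Z_k),

uses d-separation to shrink each factor's conditioning set ``Z_k`` to a
minimal subset of counterfactual variables, and accepts the ordering only
when every retained variable's indicator precedes the factor — in that
event the variable can be syntactically replaced by its proxy and the
factor is estimable from observed data. Self-masking (a variable driving
its own indicator) and outcome-driven whole-row selection both defeat the
search and are reported as such.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .mgraph import (
    AssumptionError,
    MGraph,
    SELECTION_NODE,
    d_separated,
    indicator_name,
    proxy_name,
)

__all__ = [
    "Factor",
    "PropensityExpression",
    "RatioExpression",
    "factorize_propensity",
    "importance_ratio",
    "check_assumptions",
    "without_selection",
]

_MAX_EXACT_ORDERINGS = 6


@dataclass(frozen=True)
class Factor:
    """One term p(R_k=1 | given indicators = 1, given proxies)."""

    indicator: str
    given_indicators: tuple[str, ...]
    given_variables: tuple[str, ...]  # counterfactual names; rendered as proxies

    def formula(self) -> str:
        given = [f"{r}=1" for r in self.given_indicators]
        given += [proxy_name(v) for v in self.given_variables]
        inner = f"{self.indicator}=1"
        if given:
            inner += "|" + ",".join(given)
        return f"p({inner})"


@dataclass
class PropensityExpression:
    """Factorized complete-case probability, or an unidentifiability verdict."""

    factors: list[Factor] = field(default_factory=list)
    identifiable: bool = True
    failure_reason: str | None = None

    def formula(self) -> str:
        if not self.identifiable:
            return f"<unidentifiable: {self.failure_reason}>"
        return "·".join(f.formula() for f in self.factors)

    def to_json(self) -> dict:
        return {
            "identifiable": self.identifiable,
            "failure_reason": self.failure_reason,
            "factors": [
                {
                    "indicator": f.indicator,
                    "given_indicators": list(f.given_indicators),
                    "given_variables": list(f.given_variables),
                }
                for f in self.factors
            ],
            "formula": self.formula(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PropensityExpression":
        return cls(
            factors=[
                Factor(
                    f["indicator"],
                    tuple(f["given_indicators"]),
                    tuple(f["given_variables"]),
                )
                for f in obj.get("factors", ())
            ],
            identifiable=obj["identifiable"],
            failure_reason=obj.get("failure_reason"),
        )

    def evaluate_true(self, g: MGraph, table) -> np.ndarray:
        """PS per row from the graph's true mechanism parameters.

        Valid because each factor's conditional, restricted per the
        d-separations that produced it, equals the mechanism's own
        conditional; used as the oracle in simulation.
        """
        n = len(table)
        ps = np.ones(n)
        for f in self.factors:
            m = g.mechanisms[f.indicator]
            if m.link == "constant":
                ps *= float(m.probability)
            else:
                eta = np.full(n, float(m.intercept))
                for w, p in zip(m.weights, m.parents):
                    if p in table.columns:
                        eta += w * table[p].to_numpy(dtype=float)
                    else:
                        # indicator parent conditioned to 1 inside the factor
                        eta += w
                ps *= 1.0 / (1.0 + np.exp(-eta))
        return ps


def _minimal_conditioning(
    g: MGraph, target: str, preceding: tuple[str, ...]
) -> tuple[str, ...] | None:
    """Greedy-minimal counterfactual set Z with R_target indep (X \\ Z) | preceding+Z.

    Backward elimination in variable order from the full counterfactual
    set; deterministic. Returns None when even the full set fails (cannot
    happen for disjoint node sets, kept defensively).
    """
    z = list(g.variables)
    for v in list(g.variables):
        trial = [w for w in z if w != v]
        rest = [w for w in g.variables if w not in trial]
        if not rest:
            sep = True
        else:
            sep = d_separated(g, {target}, set(rest), set(preceding) | set(trial))
        if sep:
            z = trial
    rest = [w for w in g.variables if w not in z]
    if rest and not d_separated(g, {target}, set(rest), set(preceding) | set(z)):
        return None
    return tuple(z)


def factorize_propensity(g: MGraph) -> PropensityExpression:
    """Search indicator orderings for an estimable factorization of PS(x).

    Exhaustive over indicator permutations for up to 6 study variables
    (topological-priority heuristic beyond, with a warning). Refuses
    graphs flagged nde_violating; graphs whose selection node is driven by
    counterfactual variables are unidentifiable as selection bias.
    """
    if g.nde_violating:
        raise AssumptionError(
            "graph violates the no-direct-effect assumption (Inquiry 3): "
            "measurement alters study variables, so the counterfactual estimand "
            "is ill-posed under standard factorization"
        )
    if g.has_selection:
        sel_parents = tuple(g.mechanisms[SELECTION_NODE].parents)
        if sel_parents:
            return PropensityExpression(
                identifiable=False,
                failure_reason=(
                    "selection bias (Inquiry 5): whole-row omission driven by "
                    f"{', '.join(sel_parents)} is invisible in the dataset; supply an "
                    "external selection model to proceed"
                ),
            )

    indicators = list(g.indicators)
    d = len(indicators)
    if d > _MAX_EXACT_ORDERINGS:
        import warnings

        warnings.warn(
            "more than 6 indicators: ordering search restricted to a "
            "topological-priority ordering and may be incomplete",
            stacklevel=2,
        )
        nondet = [
            n
            for n in _topo_indicator_order(g)
            if n in indicators
        ]
        orderings = iter([tuple(nondet)])
    else:
        orderings = itertools.permutations(indicators)

    blocking: str | None = None
    for ordering in orderings:
        factors: list[Factor] = []
        ok = True
        for k, target in enumerate(ordering):
            preceding = ordering[:k]
            z = _minimal_conditioning(g, target, preceding)
            if z is None:
                ok = False
                break
            bad = [v for v in z if indicator_name(v) not in preceding]
            if bad:
                ok = False
                blocking = bad[0]
                break
            factors.append(Factor(target, preceding, z))
        if ok:
            return PropensityExpression(factors=factors, identifiable=True)

    self_masking = [
        v for v in g.variables if g.digraph.has_edge(v, indicator_name(v))
    ]
    if self_masking:
        reason = (
            f"self-masking: {self_masking[0]} drives its own availability; "
            "its distribution is unidentifiable without extra assumptions"
        )
    else:
        reason = (
            "no indicator ordering admits an estimable factorization"
            + (f" (blocking variable: {blocking})" if blocking else "")
        )
    return PropensityExpression(identifiable=False, failure_reason=reason)


def _topo_indicator_order(g: MGraph) -> list[str]:
    import networkx as nx

    sub = g.digraph.subgraph(
        [n for n, d_ in g.digraph.nodes(data=True) if d_["role"] in ("indicator", "selection")]
    )
    return [n for n in nx.topological_sort(sub)]


def without_selection(g: MGraph) -> MGraph:
    """Copy of ``g`` with the whole-row selection node removed.

    Used when an external (domain-informed) selection model is supplied:
    the remaining per-variable mechanisms can then be factorized on their
    own, and the selection probability enters the estimator separately.
    """
    from .mgraph import graph_to_json, graph_from_json

    obj = graph_to_json(g)
    obj["selection_node"] = False
    obj["mechanisms"] = {t: m for t, m in obj["mechanisms"].items() if t != SELECTION_NODE}
    return graph_from_json(obj)


# ---------------------------------------------------------------------------
# Importance ratios between availability policies


@dataclass
class RatioExpression:
    """Per-row weight lambda relating deployment to collection availability.

    kinds: ``unchanged`` (identical policies, weight 1), ``full_deployment``
    (deployment observes everything: weight 1/PS on complete rows, 0 on
    incomplete ones), ``general_shift`` (ratio of the two mechanism
    products, row by row).
    """

    kind: str
    propensity: PropensityExpression | None = None
    g_init: MGraph | None = None
    g_new: MGraph | None = None

    def evaluate(self, table, indicators) -> np.ndarray:
        """Weights for rows with counterfactual values ``table`` and masks ``indicators``."""
        n = len(table)
        complete = (np.asarray(indicators) == 1).all(axis=1)
        if self.kind == "unchanged":
            return np.ones(n)
        if self.kind == "full_deployment":
            if self.propensity is None or not self.propensity.identifiable:
                raise ValueError(
                    "full-deployment ratio is not evaluable: the collection-side "
                    "propensity score is unidentifiable"
                )
            ps = self.propensity.evaluate_true(self.g_init, table)
            out = np.zeros(n)
            out[complete] = 1.0 / ps[complete]
            return out
        num = _joint_mechanism_prob(self.g_new, table, indicators)
        den = _joint_mechanism_prob(self.g_init, table, indicators)
        return num / den


def _joint_mechanism_prob(g: MGraph, table, indicators) -> np.ndarray:
    """prod_i p(R_i = r_i | parents) per row under g's mechanisms."""
    import pandas as pd

    n = len(table)
    table = pd.DataFrame(table)
    indicators = pd.DataFrame(indicators)
    values = {v: table[v].to_numpy(dtype=float) for v in g.variables}
    for v in g.variables:
        values[indicator_name(v)] = indicators[v].to_numpy(dtype=float)
    out = np.ones(n)
    for v in g.variables:
        m = g.mechanisms[indicator_name(v)]
        if m.link == "constant":
            p1 = np.full(n, float(m.probability))
        else:
            eta = np.full(n, float(m.intercept))
            for w, par in zip(m.weights, m.parents):
                eta += w * values[par]
            p1 = 1.0 / (1.0 + np.exp(-eta))
        r = values[indicator_name(v)]
        out *= np.where(r == 1, p1, 1.0 - p1)
    return out


def importance_ratio(g_init: MGraph, g_new: MGraph) -> RatioExpression:
    """Importance ratio between two policies over the same counterfactuals.

    Requires identical counterfactual sub-graphs (no shift in p(X));
    detects the unchanged and full-deployment regimes, falling back to the
    general per-row mechanism-product ratio.
    """
    import networkx as nx

    if not nx.utils.graphs_equal(
        g_init.counterfactual_subgraph(), g_new.counterfactual_subgraph()
    ):
        raise ValueError(
            "counterfactual sub-graphs differ: the no-counterfactual-shift "
            "assumption p(X)=q(X) does not hold"
        )
    if g_init.mechanisms == g_new.mechanisms:
        return RatioExpression(kind="unchanged")
    is_full = all(
        g_new.mechanisms[r].link == "constant" and g_new.mechanisms[r].probability == 1.0
        for r in g_new.indicators
    )
    if is_full:
        expr = factorize_propensity(g_init)
        if not expr.identifiable:
            return RatioExpression(
                kind="full_deployment", propensity=expr, g_init=g_init, g_new=g_new
            )
        return RatioExpression(kind="full_deployment", propensity=expr, g_init=g_init)
    return RatioExpression(kind="general_shift", g_init=g_init, g_new=g_new)


# ---------------------------------------------------------------------------
# Assumption report


@dataclass
class AssumptionReport:
    nde_ok: bool
    interference_ok: bool
    selection_bias: bool
    shift_prone: bool
    monotone_inducing: bool
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "nde_ok": self.nde_ok,
            "interference_ok": self.interference_ok,
            "selection_bias": self.selection_bias,
            "shift_prone": self.shift_prone,
            "monotone_inducing": self.monotone_inducing,
            "notes": list(self.notes),
        }


def check_assumptions(g: MGraph, scenarios=()) -> AssumptionReport:
    """Merge graph-derived facts with scenario-catalog flags.

    Graph evidence (an R→X edge, a selection node) is authoritative where
    it exists; catalog flags add what the graph cannot show, each verdict
    annotated with its provenance.
    """
    notes: list[str] = []

    nde_ok = not g.nde_violating
    r_to_x = [
        (a, b)
        for a, b, in g.digraph.edges()
        if g.role(a) == "indicator" and g.role(b) == "counterfactual"
    ]
    if r_to_x:
        nde_ok = False
        notes.append(f"graph: indicator-to-variable edge {r_to_x[0][0]}->{r_to_x[0][1]}")
    for s in scenarios:
        if s.nde_risk:
            nde_ok = False
            notes.append(f"catalog: scenario {s.id} ({s.title}) risks direct effects")

    selection = g.has_selection and bool(g.mechanisms[SELECTION_NODE].parents)
    if selection:
        notes.append("graph: selection node with counterfactual drivers")
    for s in scenarios:
        if s.selection_bias:
            selection = True
            notes.append(f"catalog: scenario {s.id} ({s.title}) induces selection bias")

    interference_ok = True
    for s in scenarios:
        if s.interference_risk:
            interference_ok = False
            notes.append(f"catalog: scenario {s.id} ({s.title}) risks interference")

    shift_prone = any(s.shift_prone for s in scenarios)
    monotone = any(s.monotone_inducing for s in scenarios)
    return AssumptionReport(
        nde_ok=nde_ok,
        interference_ok=interference_ok,
        selection_bias=selection,
        shift_prone=shift_prone,
        monotone_inducing=monotone,
        notes=notes,
    )
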