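"""Missingness graphs (m-graphs) for observational health data.

An m-graph is a causal DAG over three kinds of nodes: *counterfactual*
study variables ``X`` (the values a variable would take were it always
available), binary *missingness indicators* ``R_X`` marking availability,
and *proxy* variables ``X_star`` — the observed, possibly-masked version
of ``X``.  The proxy is a deterministic function of its pair::

    X_star = X        if R_X = 1
    X_star = NaN      if R_X = 0

An optional *selection node* ``R_dagger`` models whole-row omission
(selection bias): it parents every indicator, and rows with
``R_dagger = 0`` never reach the dataset at all.

This module houses the graph data model, validation, d-separation,
availability policies, and monotone missingness-pattern analysis.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "MechanismSpec",
    "MGraph",
    "Policy",
    "PatternSet",
    "MonotonicityReport",
    "StructuralError",
    "AssumptionError",
    "SELECTION_NODE",
    "indicator_name",
    "proxy_name",
    "build_graph",
    "d_separated",
    "apply_policy",
    "analyze_patterns",
    "graph_to_json",
    "graph_from_json",
]

SELECTION_NODE = "R_dagger"


class StructuralError(ValueError):
    """The graph description violates an m-graph structural invariant."""


class AssumptionError(ValueError):
    """The graph requires an assumption flag that was not granted."""


def indicator_name(variable: str) -> str:
    return f"R_{variable}"


def proxy_name(variable: str) -> str:
    return f"{variable}_star"


@dataclass(frozen=True)
class MechanismSpec:
    """Parameterization of one missingness indicator (or the selection node).

    ``link="constant"`` fixes ``p(R=1)`` to ``probability``;
    ``link="logistic"`` sets ``p(R=1 | parents) = sigmoid(intercept +
    sum(w_j * parent_j))`` with one weight per parent, in order.
    """

    target: str
    parents: tuple[str, ...] = ()
    link: str = "constant"
    probability: float | None = None
    intercept: float | None = None
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.link == "constant":
            if self.probability is None or not (0.0 <= self.probability <= 1.0):
                raise ValueError(
                    f"constant mechanism for {self.target} needs probability in [0,1]"
                )
            if self.parents:
                raise ValueError(f"constant mechanism for {self.target} takes no parents")
        elif self.link == "logistic":
            if self.intercept is None or self.weights is None:
                raise ValueError(f"logistic mechanism for {self.target} needs intercept+weights")
            if len(self.weights) != len(self.parents):
                raise ValueError(f"mechanism for {self.target}: one weight per parent required")
        else:
            raise ValueError(f"unknown link {self.link!r}")
        object.__setattr__(self, "parents", tuple(self.parents))
        if self.weights is not None:
            object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))

    def prob_observed(self, parent_values) -> float:
        """p(R=1 | parents) for one row; ``parent_values`` ordered as ``parents``."""
        if self.link == "constant":
            return float(self.probability)
        eta = float(self.intercept) + sum(
            w * float(v) for w, v in zip(self.weights, parent_values)
        )
        return 1.0 / (1.0 + math.exp(-eta))

    def to_json(self) -> dict:
        out = {"parents": list(self.parents), "link": self.link}
        if self.link == "constant":
            out["probability"] = self.probability
        else:
            out["intercept"] = self.intercept
            out["weights"] = list(self.weights)
        return out

    @classmethod
    def from_json(cls, target: str, obj: dict) -> "MechanismSpec":
        return cls(
            target=target,
            parents=tuple(obj.get("parents", ())),
            link=obj["link"],
            probability=obj.get("probability"),
            intercept=obj.get("intercept"),
            weights=tuple(obj["weights"]) if obj.get("weights") is not None else None,
        )


@dataclass
class MGraph:
    """Validated m-graph: roles, edges, pairing and missingness mechanisms.

    ``digraph`` carries every node (including the synthesized proxies) with
    a ``role`` attribute in {counterfactual, indicator, proxy, selection}
    and a ``deterministic`` flag on the proxy-defining edges.
    """

    variables: tuple[str, ...]
    digraph: nx.DiGraph
    mechanisms: dict[str, MechanismSpec]
    nde_violating: bool = False
    has_selection: bool = False

    def role(self, node: str) -> str:
        return self.digraph.nodes[node]["role"]

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(indicator_name(v) for v in self.variables)

    def counterfactual_subgraph(self) -> nx.DiGraph:
        keep = [n for n, d in self.digraph.nodes(data=True) if d["role"] == "counterfactual"]
        return self.digraph.subgraph(keep).copy()

    def copy(self) -> "MGraph":
        return MGraph(
            variables=self.variables,
            digraph=self.digraph.copy(),
            mechanisms=dict(self.mechanisms),
            nde_violating=self.nde_violating,
            has_selection=self.has_selection,
        )


def build_graph(spec: dict) -> MGraph:
    """Build and validate an m-graph from a plain description.

    ``spec`` keys:

    - ``variables``: ordered counterfactual variable names; an indicator
      ``R_v`` and proxy ``v_star`` are synthesized for each, along with
      the deterministic edges ``v -> v_star <- R_v``.
    - ``edges``: directed pairs among counterfactual variables, plus any
      explicit indicator-to-counterfactual edges (these require the
      ``nde_violating`` flag).
    - ``mechanisms``: mapping ``R_v`` (or ``R_dagger``) to a mechanism
      description; mechanism parents induce the remaining edges.
    - ``selection_node``: whether a whole-row selection node exists.
    - ``nde_violating``: grants indicator-to-counterfactual edges.
    """
    variables = tuple(spec["variables"])
    if len(set(variables)) != len(variables):
        raise StructuralError("variable names must be unique")
    nde_violating = bool(spec.get("nde_violating", False))
    has_selection = bool(spec.get("selection_node", False))

    g = nx.DiGraph()
    for v in variables:
        g.add_node(v, role="counterfactual")
        g.add_node(indicator_name(v), role="indicator")
        g.add_node(proxy_name(v), role="proxy")
        g.add_edge(v, proxy_name(v), deterministic=True)
        g.add_edge(indicator_name(v), proxy_name(v), deterministic=True)
    if has_selection:
        g.add_node(SELECTION_NODE, role="selection")
        for v in variables:
            g.add_edge(SELECTION_NODE, indicator_name(v), deterministic=False)

    mechanisms: dict[str, MechanismSpec] = {}
    raw_mech = spec.get("mechanisms", {})
    for v in variables:
        r = indicator_name(v)
        if r not in raw_mech:
            raise StructuralError(f"no mechanism declared for indicator {r}")
    expected = set(raw_mech) - {indicator_name(v) for v in variables}
    if expected - ({SELECTION_NODE} if has_selection else set()):
        raise StructuralError(f"mechanisms for unknown indicators: {sorted(expected)}")
    if has_selection and SELECTION_NODE not in raw_mech:
        raise StructuralError("selection node declared but has no mechanism")

    for target, obj in raw_mech.items():
        m = obj if isinstance(obj, MechanismSpec) else MechanismSpec.from_json(target, obj)
        m = replace(m, target=target)
        mechanisms[target] = m
        for p in m.parents:
            if p not in g:
                raise StructuralError(f"mechanism for {target} names unknown parent {p!r}")
            role = g.nodes[p]["role"]
            if role == "proxy":
                raise StructuralError(
                    f"indicator {target} has proxy parent {p!r}: proxies never cause anything"
                )
            if target == SELECTION_NODE and role not in ("counterfactual",):
                raise StructuralError("selection node parents must be counterfactual variables")
            g.add_edge(p, target, deterministic=False)

    for a, b in spec.get("edges", ()):
        for n in (a, b):
            if n not in g:
                raise StructuralError(f"edge references unknown node {n!r}")
        role_a, role_b = g.nodes[a]["role"], g.nodes[b]["role"]
        if role_a == "proxy":
            raise StructuralError(f"proxy {a!r} cannot have outgoing edges")
        if role_b == "proxy":
            raise StructuralError("proxy parent sets are synthesized, not declared")
        if role_a == "indicator" and role_b == "counterfactual":
            if not nde_violating:
                raise AssumptionError(
                    f"edge {a}->{b} makes measurement affect a study variable; "
                    "permitted only on graphs flagged nde_violating "
                    "(no-direct-effect assumption, Inquiry 3)"
                )
            g.add_edge(a, b, deterministic=False)
        elif role_a == "counterfactual" and role_b == "counterfactual":
            g.add_edge(a, b, deterministic=False)
        elif role_b == "indicator" or role_b == "selection":
            # structural edge without coefficients is allowed only if the
            # mechanism also lists it; mechanisms are the authority
            m = mechanisms.get(b)
            if m is None or a not in m.parents:
                raise StructuralError(
                    f"edge {a}->{b} must be declared through {b}'s mechanism parents"
                )
        else:
            raise StructuralError(f"edge {a}->{b} not permitted between roles {role_a}->{role_b}")

    # indicator parents: counterfactual, indicator or selection only
    for v in variables:
        r = indicator_name(v)
        for p in g.predecessors(r):
            if g.nodes[p]["role"] not in ("counterfactual", "indicator", "selection"):
                raise StructuralError(f"indicator {r} has illegal parent {p}")
    if has_selection:
        for s in g.successors(SELECTION_NODE):
            if g.nodes[s]["role"] == "counterfactual":
                raise StructuralError("selection node must not parent counterfactual variables")

    nondet = nx.DiGraph(
        (a, b) for a, b, d in g.edges(data=True) if not d.get("deterministic", False)
    )
    if not nx.is_directed_acyclic_graph(nondet):
        raise StructuralError("cycle among non-deterministic edges")

    return MGraph(
        variables=variables,
        digraph=g,
        mechanisms=mechanisms,
        nde_violating=nde_violating,
        has_selection=has_selection,
    )


def d_separated(g: MGraph, A, B, Z) -> bool:
    """Standard d-separation of ``A`` and ``B`` given ``Z`` in the full graph.

    Deterministic proxy edges participate as ordinary edges; identification
    logic never conditions on proxies directly — it only substitutes them
    syntactically after the independence is established.
    """
    A, B, Z = set(A), set(B), set(Z)
    for n in A | B | Z:
        if n not in g.digraph:
            raise KeyError(f"unknown node {n!r}")
    if (A & B) or (A & Z) or (B & Z):
        raise ValueError("A, B, Z must be disjoint")
    return nx.is_d_separator(g.digraph, A, B, Z)


@dataclass(frozen=True)
class Policy:
    """A data-availability policy: one mechanism per indicator.

    Special names: ``init`` (data-collection regime), ``full`` (every
    indicator constant 1) and ``new`` (a shifted deployment regime).
    """

    name: str
    mechanisms: dict[str, MechanismSpec] = field(default_factory=dict)

    @classmethod
    def full(cls, variables) -> "Policy":
        return cls(
            name="full",
            mechanisms={
                indicator_name(v): MechanismSpec(
                    target=indicator_name(v), link="constant", probability=1.0
                )
                for v in variables
            },
        )


def apply_policy(g: MGraph, p: Policy) -> MGraph:
    """Return a copy of ``g`` with its mechanisms replaced by ``p``'s.

    The counterfactual sub-graph is never touched: a policy changes only
    how availability is decided, not the health variables themselves.
    """
    missing = [r for r in g.indicators if r not in p.mechanisms]
    if missing:
        raise ValueError(f"policy {p.name!r} does not cover indicators: {missing}")
    out = g.copy()
    for r in g.indicators:
        old = out.mechanisms[r]
        for parent in old.parents:
            out.digraph.remove_edge(parent, r)
        new = replace(p.mechanisms[r], target=r)
        for parent in new.parents:
            if parent not in out.digraph:
                raise StructuralError(f"policy mechanism for {r} names unknown parent {parent!r}")
            out.digraph.add_edge(parent, r, deterministic=False)
        out.mechanisms[r] = new
    return out


@dataclass
class PatternSet:
    """Observed missingness patterns: binary availability vectors with counts."""

    variables: tuple[str, ...]
    patterns: list[tuple[int, ...]]
    counts: list[int]

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("PatternSet needs at least one pattern")
        d = len(self.variables)
        for pat, c in zip(self.patterns, self.counts):
            if len(pat) != d:
                raise ValueError("pattern length must match variable order")
            if c <= 0:
                raise ValueError("pattern counts must be positive")


@dataclass
class MonotonicityReport:
    is_monotone: bool
    ordering: tuple[str, ...] | None = None
    violating_pair: tuple[tuple[int, ...], tuple[int, ...]] | None = None


_MAX_EXACT_VARS = 8


def analyze_patterns(ps: PatternSet) -> MonotonicityReport:
    """Decide whether the patterns are monotone and exhibit a witness.

    Monotone means: some ordering of the variables exists under which every
    pattern observes a prefix of the ordering. The search sorts variables by
    their (count-weighted) observed frequency and tries all permutations of
    tied groups — exact for up to 8 variables; beyond that the tied groups
    are kept in lexicographic order and the verdict may be incomplete.
    """
    d = len(ps.variables)
    weights = [0] * d
    for pat, c in zip(ps.patterns, ps.counts):
        for j, bit in enumerate(pat):
            weights[j] += bit * c

    # group indices by weight, descending
    order_groups: list[list[int]] = []
    for w in sorted(set(weights), reverse=True):
        order_groups.append([j for j in range(d) if weights[j] == w])

    exact = d <= _MAX_EXACT_VARS
    if not exact:
        import warnings

        warnings.warn(
            "more than 8 variables: tie permutations not exhausted, "
            "monotonicity verdict may be incomplete",
            stacklevel=2,
        )

    def prefix_ok(order: tuple[int, ...]) -> bool:
        pos = {j: k for k, j in enumerate(order)}
        for pat in ps.patterns:
            observed = [pos[j] for j in range(d) if pat[j] == 1]
            if observed and (max(observed) != len(observed) - 1):
                return False
        return True

    group_perms = (
        [itertools.permutations(grp) for grp in order_groups]
        if exact
        else [[tuple(grp)] for grp in order_groups]
    )
    for combo in itertools.product(*group_perms):
        order = tuple(itertools.chain.from_iterable(combo))
        if prefix_ok(order):
            return MonotonicityReport(
                is_monotone=True,
                ordering=tuple(ps.variables[j] for j in order),
            )

    # not monotone: report a witnessing non-nested pattern pair
    sets = [frozenset(j for j, bit in enumerate(pat) if bit) for pat in ps.patterns]
    for (i, si), (k, sk) in itertools.combinations(enumerate(sets), 2):
        if not (si <= sk or sk <= si):
            return MonotonicityReport(
                is_monotone=False,
                violating_pair=(ps.patterns[i], ps.patterns[k]),
            )
    # nested but no prefix ordering cannot happen; defensive fallback
    return MonotonicityReport(is_monotone=False, violating_pair=(ps.patterns[0], ps.patterns[-1]))


# ---------------------------------------------------------------------------
# JSON round trip


def graph_to_json(g: MGraph) -> dict:
    cf = g.counterfactual_subgraph()
    edges = [[a, b] for a, b in cf.edges()]
    edges += [
        [a, b]
        for a, b, d in g.digraph.edges(data=True)
        if g.role(a) == "indicator" and g.role(b) == "counterfactual"
    ]
    return {
        "variables": list(g.variables),
        "edges": edges,
        "mechanisms": {t: m.to_json() for t, m in g.mechanisms.items()},
        "selection_node": g.has_selection,
        "nde_violating": g.nde_violating,
    }


def graph_from_json(obj: dict) -> MGraph:
    return build_graph(obj)


def save_graph(g: MGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph_to_json(g), fh, indent=1)


def load_graph(path) -> MGraph:
    with open(path) as fh:
        return graph_from_json(json.load(fh))
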