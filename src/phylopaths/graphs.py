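"""Causal model representation and Shipley d-separation basis sets.

A candidate causal hypothesis is a directed acyclic graph over the trait
variables plus one terminal binary outcome vertex.  Each DAG implies a
basis set of conditional-independence claims — one per non-adjacent vertex
pair, conditioned on the union of both vertices' parents — whose joint
truth is what the d-sep test evaluates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

__all__ = [
    "CausalDAG",
    "IndependenceClaim",
    "ModelSet",
    "enumerate_models",
    "basis_set",
    "topological_order",
]


class CausalDAG:
    """A directed acyclic graph of hypothesised causal links.

    Parameters
    ----------
    vertices : sequence of str
        Variable names; declaration order is the deterministic tie-break
        for topological sorting.
    edges : sequence of (parent, child) pairs
    binary_vertex : str, optional
        The outcome vertex (must have out-degree 0 if given).
    name : str, optional
        Model identifier; defaults to "+"-joined sorted added-link names
        when built by :func:`enumerate_models`.
    """

    def __init__(self, vertices, edges, binary_vertex: str | None = None,
                 name: str | None = None):
        self.vertices = list(dict.fromkeys(vertices))
        self.edges = [tuple(e) for e in edges]
        self.binary_vertex = binary_vertex
        self.name = name
        seen = set()
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self-loop on {p!r}")
            if (p, c) in seen:
                raise ValueError(f"duplicate edge {p!r} -> {c!r}")
            seen.add((p, c))
            for v in (p, c):
                if v not in self.vertices:
                    raise ValueError(f"edge endpoint {v!r} not a declared vertex")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"graph has a cycle: {cycle}")
        if binary_vertex is not None:
            if binary_vertex not in self.vertices:
                raise ValueError(f"binary vertex {binary_vertex!r} not declared")
            if g.out_degree(binary_vertex) > 0:
                raise ValueError(
                    f"binary outcome {binary_vertex!r} must have out-degree 0"
                )

    @property
    def q(self) -> int:
        """Number of directed edges = free path coefficients."""
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def parents(self, v: str) -> set[str]:
        return {p for p, c in self.edges if c == v}

    def adjacent(self, x: str, y: str) -> bool:
        return (x, y) in set(self.edges) or (y, x) in set(self.edges)

    def with_edges(self, extra, name: str | None = None) -> "CausalDAG":
        return CausalDAG(self.vertices, self.edges + [tuple(e) for e in extra],
                         binary_vertex=self.binary_vertex, name=name)

    def to_dot(self) -> str:
        lines = ["digraph causal_model {"]
        for v in self.vertices:
            lines.append(f'  "{v}";')
        for p, c in self.edges:
            lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        label = self.name or "CausalDAG"
        return f"{label}(|V|={len(self.vertices)}, q={self.q})"


@dataclass(frozen=True)
class IndependenceClaim:
    """One conditional-independence claim x ⟂ y | Z with a designated response."""

    x: str
    y: str
    conditioning_set: frozenset
    response: str

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("claim endpoints must differ")
        if self.response not in (self.x, self.y):
            raise ValueError("response must be one of the claim endpoints")

    @property
    def predictor(self) -> str:
        """The tested coefficient's variable (the non-response endpoint)."""
        return self.y if self.response == self.x else self.x

    def __str__(self) -> str:  # pragma: no cover
        z = ", ".join(sorted(self.conditioning_set)) or "∅"
        return f"{self.x} ⟂ {self.y} | {{{z}}} (response {self.response})"


@dataclass
class ModelSet:
    """All causal models obtained from a trait-only DAG plus link subsets."""

    trait_only: CausalDAG
    candidate_links: list[tuple]
    models: list[CausalDAG] = field(default_factory=list)


def topological_order(dag: CausalDAG) -> list[str]:
    """Topological sort with ties broken by vertex declaration order."""
    rank = {v: i for i, v in enumerate(dag.vertices)}
    g = dag.to_networkx()
    try:
        return list(nx.lexicographical_topological_sort(g, key=lambda v: rank[v]))
    except nx.NetworkXUnfeasible as exc:  # pragma: no cover - guarded in __init__
        raise ValueError(f"graph has a cycle: {nx.find_cycle(g)}") from exc


def enumerate_models(trait_only: CausalDAG, candidate_links) -> ModelSet:
    """Enumerate all 2^k causal models: trait-only DAG plus each subset of
    candidate direct links.

    Models are ordered by binary counting over the candidate list, so
    models[0] is the trait-only null.  Model names are "+"-joined sorted
    parent names of the added links (the trait-only model is "Trait-only").
    """
    links = [tuple(e) for e in candidate_links]
    urban = trait_only.binary_vertex
    existing = set(trait_only.edges)
    for p, c in links:
        if urban is not None and c != urban:
            raise ValueError(
                f"candidate link {p!r}->{c!r} must target the outcome {urban!r}"
            )
        if (p, c) in existing:
            raise ValueError(f"candidate link {p!r}->{c!r} duplicates a trait-only edge")
    if len(set(links)) != len(links):
        raise ValueError("duplicate candidate links")
    models = []
    for mask in range(2 ** len(links)):
        subset = [links[i] for i in range(len(links)) if mask >> i & 1]
        name = "+".join(sorted(p for p, _ in subset)) if subset else "Trait-only"
        models.append(trait_only.with_edges(subset, name=name))
    return ModelSet(trait_only=trait_only, candidate_links=links, models=models)


def basis_set(dag: CausalDAG, binary_vertex: str | None = None) -> list[IndependenceClaim]:
    """Shipley's generalized d-separation basis set of a DAG.

    One claim per non-adjacent unordered vertex pair {x, y}, conditioned on
    pa(x) ∪ pa(y) minus the pair itself.  The regression response is the
    binary outcome vertex when it is in the pair (a binary variable can
    only be modelled as a response), otherwise the vertex later in
    topological order.  The claim count is C(|V|, 2) − q.
    """
    if binary_vertex is None:
        binary_vertex = dag.binary_vertex
    order = topological_order(dag)
    pos = {v: i for i, v in enumerate(order)}
    edge_set = set(dag.edges)
    claims = []
    for x, y in combinations(order, 2):  # x before y topologically
        if (x, y) in edge_set or (y, x) in edge_set:
            continue
        z = (dag.parents(x) | dag.parents(y)) - {x, y}
        response = binary_vertex if binary_vertex in (x, y) else (
            x if pos[x] > pos[y] else y
        )
        claims.append(
            IndependenceClaim(x=x, y=y, conditioning_set=frozenset(z),
                              response=response)
        )
    return claims
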