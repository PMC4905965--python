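"""Unified-SEM model representation.

Each ROI appears as two observed variables, the original series and a
lag-1 copy; a directed edge A -> B expands to three free paths
(A -> B contemporaneous among unlagged, A_lag -> B_lag contemporaneous
among lagged, A -> B_lag cross-lag), and every node carries one
autoregressive path A -> A_lag.  Residual variances of all 2n variables
are free; covariances among exogenous residuals are fixed at zero.

The model is parameterized as a reticular action model (RAM): an
asymmetric path matrix A over the 2n variables and a diagonal S of
residual variances, with implied covariance (I-A)^{-1} S (I-A)^{-T}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as _Path

import networkx as nx

__all__ = ["Edge", "PathParam", "UsemModel", "build_usem"]

PATH_KINDS = ("contemporaneous", "lagged", "crosslag", "auto")


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    bidirectional: bool = False

    def reversed(self) -> "Edge":
        return Edge(self.target, self.source, self.bidirectional)

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"

    @property
    def pair(self) -> frozenset:
        return frozenset((self.source, self.target))


@dataclass(frozen=True)
class PathParam:
    """One directed path among the 2n observed variables.

    ``kind`` is one of contemporaneous / lagged / crosslag / auto;
    ``source``/``target`` name ROIs (not variables); the variable-level
    indices are derived by :meth:`UsemModel.path_indices`.
    """

    kind: str
    source: str
    target: str

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}[{self.kind}]"


@dataclass
class UsemModel:
    """Node set + directed edge set + derived path registry."""

    node_names: list[str]
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        nodes = set(self.node_names)
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in nodes or e.target not in nodes:
                raise ValueError(f"edge {e.label}: endpoint not in node set")
            if e.source == e.target:
                raise ValueError(f"self-edge {e.label} not allowed")
            key = (e.source, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge {e.label}")
            seen.add(key)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_variables(self) -> int:
        return 2 * self.n_nodes

    @property
    def variable_names(self) -> list[str]:
        return list(self.node_names) + [f"{n}_lag" for n in self.node_names]

    def _directed_edges(self) -> list[Edge]:
        out = []
        for e in self.edges:
            out.append(e)
            if e.bidirectional:
                out.append(e.reversed())
        return out

    @property
    def paths(self) -> list[PathParam]:
        """Free path parameters: 3 per directed edge + 1 auto per node."""
        out = []
        for e in self._directed_edges():
            out.append(PathParam("contemporaneous", e.source, e.target))
            out.append(PathParam("lagged", e.source, e.target))
            out.append(PathParam("crosslag", e.source, e.target))
        for name in self.node_names:
            out.append(PathParam("auto", name, name))
        return out

    def path_indices(self, p: PathParam) -> tuple[int, int]:
        """(target_variable, source_variable) indices into the RAM A matrix."""
        i = {name: k for k, name in enumerate(self.node_names)}
        n = self.n_nodes
        s, t = i[p.source], i[p.target]
        if p.kind == "contemporaneous":
            return t, s
        if p.kind == "lagged":
            return n + t, n + s
        if p.kind == "crosslag":
            return n + t, s
        if p.kind == "auto":
            return n + s, s
        raise ValueError(f"unknown path kind {p.kind!r}")

    # ------------------------------------------------------------------
    # parameter accounting
    # ------------------------------------------------------------------
    def q_per_group(self) -> int:
        """Free parameters in one group: paths + 2n residual variances."""
        return len(self.paths) + self.n_variables

    def q(self, n_groups: int, grouping: str = "free") -> int:
        if grouping == "free":
            return n_groups * self.q_per_group()
        if grouping == "equal":
            return self.q_per_group()
        raise ValueError(f"unknown grouping {grouping!r}")

    def df(self, n_groups: int, grouping: str = "free") -> int:
        """df = G * p(p+1)/2 - q with p = 2 * n_nodes."""
        p = self.n_variables
        return n_groups * p * (p + 1) // 2 - self.q(n_groups, grouping)

    def is_recursive(self) -> bool:
        """True when the path system contains no feedback loop."""
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_variables))
        for p in self.paths:
            t, s = self.path_indices(p)
            g.add_edge(s, t)
        return nx.is_directed_acyclic_graph(g)

    def with_edge(self, edge: Edge) -> "UsemModel":
        return UsemModel(list(self.node_names), list(self.edges) + [edge])

    def has_pair(self, a: str, b: str) -> bool:
        pair = frozenset((a, b))
        return any(e.pair == pair for e in self.edges)

    # ------------------------------------------------------------------
    # JSON model-spec interchange
    # ------------------------------------------------------------------
    def to_json(self, path: str | _Path | None = None, grouping: str = "free") -> dict:
        spec = {
            "nodes": list(self.node_names),
            "edges": [
                {"source": e.source, "target": e.target, "bidirectional": e.bidirectional}
                for e in self.edges
            ],
            "grouping": grouping,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(spec, fh, indent=1)
        return spec

    @classmethod
    def from_json(cls, spec: dict | str | _Path) -> "UsemModel":
        if not isinstance(spec, dict):
            with open(spec) as fh:
                spec = json.load(fh)
        edges = [
            Edge(e["source"], e["target"], bool(e.get("bidirectional", False)))
            for e in spec["edges"]
        ]
        return cls(list(spec["nodes"]), edges)


def build_usem(nodes: list[str], edges: list[Edge | tuple]) -> UsemModel:
    """Build a unified-SEM model from a node list and directed edge list.

    Edges may be ``Edge`` instances or ``(source, target)`` /
    ``(source, target, bidirectional)`` tuples.  The null model (empty
    edge list) contains only the n autoregressive paths and 2n residual
    variances.
    """
    norm = []
    for e in edges:
        if isinstance(e, Edge):
            norm.append(e)
        else:
            norm.append(Edge(*e))
    return UsemModel(list(nodes), norm)
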