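"""Rooted ductal-tree container for a glandular subunit.

A prostatic glandular subunit is modelled as a rooted tree of duct
segments: a single ``urethral_origin`` node, internal ``duct`` and
``branchpoint`` nodes, and terminal ``acinus`` leaves.  Edges carry
physical segment lengths in micrometres, so root-to-node path lengths
are anatomical distances from the urethral outlet.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

NODE_KINDS = ("urethral_origin", "duct", "branchpoint", "acinus")


class DuctalGraphError(ValueError):
    """Raised when a ductal graph violates its structural invariants."""


class DuctalGraph:
    """A rooted tree of duct segments with 3D coordinates.

    Thin wrapper around a :class:`networkx.DiGraph` whose edges point
    from parent (proximal) to child (distal).  Node attributes:
    ``kind`` (one of ``urethral_origin``/``duct``/``branchpoint``/
    ``acinus``) and ``position`` (length-3 tuple, micrometres).  Edge
    attribute: ``length`` (micrometres, > 0).
    """

    def __init__(self, graph: nx.DiGraph):
        self._g = graph
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        nodes: Iterable[Mapping],
        edges: Iterable[Mapping],
    ) -> "DuctalGraph":
        g = nx.DiGraph()
        for n in nodes:
            g.add_node(
                str(n["id"]),
                kind=n["kind"],
                position=tuple(float(x) for x in n["position"]),
            )
        for e in edges:
            g.add_edge(str(e["parent"]), str(e["child"]), length=float(e["length"]))
        return cls(g)

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        g = self._g
        if g.number_of_nodes() == 0:
            raise DuctalGraphError("empty ductal graph")
        roots = [n for n, d in g.in_degree() if d == 0]
        if len(roots) != 1:
            raise DuctalGraphError(f"expected exactly one root, found {roots}")
        if g.nodes[roots[0]]["kind"] != "urethral_origin":
            raise DuctalGraphError("root node must be the urethral_origin")
        kinds = nx.get_node_attributes(g, "kind")
        bad = {n: k for n, k in kinds.items() if k not in NODE_KINDS}
        if bad:
            raise DuctalGraphError(f"unknown node kinds: {bad}")
        n_origins = sum(1 for k in kinds.values() if k == "urethral_origin")
        if n_origins != 1:
            raise DuctalGraphError("exactly one urethral_origin required")
        if not nx.is_arborescence(g):
            raise DuctalGraphError("ductal graph must be a rooted tree")
        for n in g.nodes:
            if kinds[n] == "acinus" and g.out_degree(n) != 0:
                raise DuctalGraphError(f"acinus {n} is not a leaf")
        for u, v, data in g.edges(data=True):
            if not data.get("length", 0) > 0:
                raise DuctalGraphError(f"edge {u}->{v} has non-positive length")

    # -- queries ------------------------------------------------------

    @property
    def root(self) -> str:
        return next(n for n, d in self._g.in_degree() if d == 0)

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def acini(self) -> list[str]:
        return [n for n in self._g.nodes if self._g.nodes[n]["kind"] == "acinus"]

    def kind(self, node: str) -> str:
        return self._g.nodes[node]["kind"]

    def position(self, node: str) -> np.ndarray:
        return np.asarray(self._g.nodes[node]["position"], dtype=float)

    def parent(self, node: str) -> str | None:
        preds = list(self._g.predecessors(node))
        return preds[0] if preds else None

    def children(self, node: str) -> list[str]:
        return list(self._g.successors(node))

    def edge_length(self, parent: str, child: str) -> float:
        return float(self._g.edges[parent, child]["length"])

    def subtree_nodes(self, node: str) -> set[str]:
        """Node plus all of its ductal descendants."""
        return {node} | nx.descendants(self._g, node)

    def undirected(self) -> nx.Graph:
        return self._g.to_undirected(as_view=False)

    def as_networkx(self) -> nx.DiGraph:
        return self._g

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other) -> bool:
        if not isinstance(other, DuctalGraph):
            return NotImplemented
        return nx.utils.graphs_equal(self._g, other._g)

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        nodes = [
            {
                "id": n,
                "kind": self._g.nodes[n]["kind"],
                "position": list(self._g.nodes[n]["position"]),
            }
            for n in sorted(self._g.nodes)
        ]
        edges = [
            {"parent": u, "child": v, "length": self._g.edges[u, v]["length"]}
            for u, v in sorted(self._g.edges)
        ]
        return {"nodes": nodes, "edges": edges}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DuctalGraph":
        return cls.from_records(d["nodes"], d["edges"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "DuctalGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
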