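"""Annotated signaling DAGs.

A signaling network is a directed acyclic graph whose nodes are proteins and
whose edges denote signal flow (kinase -> substrate).  Nodes carry role flags
describing how the experiment touches them:

* ``ligand``      -- an extracellular signal; its activity is set by the
                     experimental design (stimulated or not), never inferred.
* ``receptor``    -- the membrane protein a ligand binds; the edge
                     ligand -> receptor is structurally protected.
* ``observed``    -- a phosphoprotein whose fluorescence readout is measured.
* ``inhibitable`` -- a kinase that a small-molecule inhibitor can switch off
                     in some conditions.

Any node that is neither observed nor a ligand is *hidden*: its activation
state is a latent variable.  A node may hold several roles at once (an
observed kinase can also be inhibitable; an unobserved receptor is hidden).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "NodeRole",
    "SignalingNetwork",
    "NetworkError",
    "CycleError",
    "UnknownNodeError",
    "load_network",
    "collapse_to_observed",
    "markov_blanket",
]


class NetworkError(ValueError):
    """Structural violation in a signaling network."""


class CycleError(NetworkError):
    """The edge set contains a directed cycle."""


class UnknownNodeError(KeyError):
    """A node identifier that is not part of the network was referenced."""


VALID_ROLE_NAMES = frozenset({"ligand", "receptor", "observed", "inhibitable", "hidden"})


@dataclass(frozen=True)
class NodeRole:
    """Immutable role flags for one node.

    ``hidden`` is derived, never stored: a node is hidden iff it is neither
    observed nor a ligand.  This lets unmeasured receptors and inhibited-but-
    unmeasured kinases participate as latent variables.
    """

    ligand: bool = False
    receptor: bool = False
    observed: bool = False
    inhibitable: bool = False

    @property
    def hidden(self) -> bool:
        return not (self.observed or self.ligand)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "NodeRole":
        got = {n.strip().lower() for n in names if n and n.strip()}
        unknown = got - VALID_ROLE_NAMES
        if unknown:
            raise NetworkError(f"unknown role name(s): {sorted(unknown)}")
        role = cls(
            ligand="ligand" in got,
            receptor="receptor" in got,
            observed="observed" in got,
            inhibitable="inhibitable" in got,
        )
        if "hidden" in got and not role.hidden:
            raise NetworkError(
                "role 'hidden' declared for a node that is observed or a ligand"
            )
        return role

    def names(self) -> tuple[str, ...]:
        out = [
            n
            for n, f in (
                ("ligand", self.ligand),
                ("receptor", self.receptor),
                ("observed", self.observed),
                ("inhibitable", self.inhibitable),
            )
            if f
        ]
        if self.hidden:
            out.append("hidden")
        return tuple(out)


class SignalingNetwork:
    """A validated, annotated DAG over protein identifiers.

    Node identifiers are case-sensitive opaque strings.  The graph is
    guaranteed acyclic, self-loop free and duplicate free at all times;
    mutating operations return new instances.
    """

    def __init__(
        self,
        roles: Mapping[str, NodeRole],
        edges: Iterable[tuple[str, str]] = (),
        name: str = "network",
    ) -> None:
        self._roles: dict[str, NodeRole] = dict(roles)
        self.name = name
        g = nx.DiGraph()
        g.add_nodes_from(self._roles)
        for u, v in edges:
            if u not in self._roles:
                raise UnknownNodeError(f"edge endpoint {u!r} has no role record")
            if v not in self._roles:
                raise UnknownNodeError(f"edge endpoint {v!r} has no role record")
            if u == v:
                raise NetworkError(f"self-loop on node {u!r}")
            g.add_edge(u, v)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise CycleError(f"directed cycle detected: {path}")
        self._g = g

    # -- introspection -----------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._g.nodes)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def role(self, node: str) -> NodeRole:
        try:
            return self._roles[node]
        except KeyError:
            raise UnknownNodeError(f"unknown node {node!r}") from None

    @property
    def roles(self) -> Mapping[str, NodeRole]:
        return dict(self._roles)

    def __contains__(self, node: str) -> bool:
        return node in self._roles

    def parents(self, node: str) -> tuple[str, ...]:
        self.role(node)
        return tuple(sorted(self._g.predecessors(node)))

    def children(self, node: str) -> tuple[str, ...]:
        self.role(node)
        return tuple(sorted(self._g.successors(node)))

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    @property
    def ligands(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self._roles[n].ligand)

    @property
    def receptors(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self._roles[n].receptor)

    @property
    def observed_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self._roles[n].observed)

    @property
    def hidden_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self._roles[n].hidden)

    @property
    def inhibitable_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self._roles[n].inhibitable)

    def ligand_receptor_edges(self) -> frozenset[tuple[str, str]]:
        """Edges from a ligand to a receptor; protected against deletion."""
        return frozenset(
            (u, v)
            for u, v in self._g.edges
            if self._roles[u].ligand and self._roles[v].receptor
        )

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._g))

    def would_create_cycle(self, u: str, v: str) -> bool:
        self.role(u)
        self.role(v)
        if u == v:
            return True
        return nx.has_path(self._g, v, u)

    def descendants(self, node: str) -> set[str]:
        self.role(node)
        return set(nx.descendants(self._g, node))

    # -- copy-on-write edits ----------------------------------------------

    def with_edge_added(self, u: str, v: str) -> "SignalingNetwork":
        self.role(u)
        self.role(v)
        if self.has_edge(u, v):
            raise NetworkError(f"duplicate edge {u!r} -> {v!r}")
        if self.would_create_cycle(u, v):
            raise CycleError(f"adding {u!r} -> {v!r} would create a cycle")
        return SignalingNetwork(self._roles, list(self._g.edges) + [(u, v)], self.name)

    def with_edge_removed(self, u: str, v: str) -> "SignalingNetwork":
        if not self.has_edge(u, v):
            raise NetworkError(f"edge {u!r} -> {v!r} not in network")
        edges = [e for e in self._g.edges if e != (u, v)]
        return SignalingNetwork(self._roles, edges, self.name)

    def copy(self) -> "SignalingNetwork":
        return SignalingNetwork(self._roles, self._g.edges, self.name)

    # -- misc --------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalingNetwork):
            return NotImplemented
        return self._roles == other._roles and set(self._g.edges) == set(other._g.edges)

    def __hash__(self) -> int:  # pragma: no cover - identity use only
        return hash((frozenset(self._roles), frozenset(self._g.edges)))

    def __repr__(self) -> str:
        return (
            f"SignalingNetwork({self.name!r}, {self.n_nodes} nodes, "
            f"{self.n_edges} edges)"
        )

    def to_dot(self) -> str:
        """Minimal GraphViz export (roles as shapes/colors)."""
        lines = [f'digraph "{self.name}" {{']
        for n in self.nodes:
            r = self._roles[n]
            color = (
                "green" if r.ligand else
                "lightblue" if r.observed else
                "red" if r.inhibitable else
                "grey"
            )
            lines.append(f'  "{n}" [style=filled, fillcolor={color}];')
        for u, v in self.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)


def load_network(
    edges: Iterable[tuple[str, str]],
    roles: Mapping[str, Iterable[str] | NodeRole],
    name: str = "network",
) -> SignalingNetwork:
    """Build a validated network from parsed edge and role records.

    ``roles`` maps node -> role-name collection (or a ready ``NodeRole``).
    Every edge endpoint must appear in ``roles``; the edge list must be
    non-empty; acyclicity is enforced.
    """
    edge_list = [(str(u), str(v)) for u, v in edges]
    if not edge_list:
        raise NetworkError("empty edge list")
    parsed: dict[str, NodeRole] = {}
    for node, r in roles.items():
        parsed[str(node)] = r if isinstance(r, NodeRole) else NodeRole.from_names(r)
    return SignalingNetwork(parsed, edge_list, name=name)


def collapse_to_observed(net: SignalingNetwork) -> SignalingNetwork:
    """Project the network onto its non-hidden nodes.

    An edge u -> w exists in the collapsed graph iff the full graph contains
    a directed path u -> ... -> w whose interior nodes are all hidden
    (a direct edge counts, with an empty interior).  Hidden nodes and their
    incident edges disappear; visible-to-visible wiring is preserved.
    Idempotent: collapsing a collapsed graph is the identity.
    """
    visible = [n for n in net.nodes if not net.role(n).hidden]
    edges: set[tuple[str, str]] = set()
    for u in visible:
        stack = list(net.children(u))
        seen: set[str] = set()
        while stack:
            w = stack.pop()
            if w in seen:
                continue
            seen.add(w)
            if net.role(w).hidden:
                stack.extend(net.children(w))
            else:
                edges.add((u, w))
    roles = {n: net.role(n) for n in visible}
    return SignalingNetwork(roles, sorted(edges), name=f"{net.name}-collapsed")


def markov_blanket(net: SignalingNetwork, node: str) -> set[str]:
    """Parents, children and co-parents (other parents of children) of a node.

    Conditioned on its blanket, a node is independent of every other node in
    the DAG.
    """
    net.role(node)
    blanket: set[str] = set(net.parents(node)) | set(net.children(node))
    for child in net.children(node):
        blanket.update(net.parents(child))
    blanket.discard(node)
    return blanket
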