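"""Structural graph layer: loading, collapse projection, Markov blankets."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ofbn import (
    CycleError,
    NetworkError,
    NodeParameters,
    NodeRole,
    SignalingNetwork,
    UnknownNodeError,
    collapse_to_observed,
    load_network,
    markov_blanket,
)

from conftest import random_layered_net
from enumeration import joint_distribution


def brute_force_collapse_edges(net):
    """Oracle: enumerate all visible pairs; connect u->w iff some directed
    path u->...->w has an all-hidden interior."""
    g = nx.DiGraph(net.edges)
    g.add_nodes_from(net.nodes)
    visible = [n for n in net.nodes if not net.role(n).hidden]
    hidden = set(net.nodes) - set(visible)
    sub_nodes = lambda u, w: set(net.nodes) - (set(visible) - {u, w})
    edges = set()
    for u, w in itertools.permutations(visible, 2):
        sub = g.subgraph(sub_nodes(u, w))
        if nx.has_path(sub, u, w):
            edges.add((u, w))
    return edges


def brute_force_blanket(net, node):
    out = set()
    for other in net.nodes:
        if other == node:
            continue
        if net.has_edge(other, node) or net.has_edge(node, other):
            out.add(other)
        for child in net.nodes:
            if net.has_edge(node, child) and net.has_edge(other, child):
                out.add(other)
    return out


def random_dag(rng, n=8, p=0.35, observed_frac=0.5):
    names = [f"N{i}" for i in range(n)]
    roles = {
        nm: NodeRole(observed=bool(rng.random() < observed_frac))
        for nm in names
    }
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return SignalingNetwork(roles, edges, name="rnd")


class TestLoadNetwork:
    def test_minimal_chain(self):
        net = load_network(
            [("A", "B"), ("B", "C")],
            {"A": ["ligand"], "B": ["receptor"], "C": ["observed"]},
        )
        assert net.n_nodes == 3 and net.n_edges == 2
        assert net.role("A").ligand and net.role("B").receptor
        assert net.role("B").hidden  # unobserved receptor is latent

    def test_smallest_cycle_rejected(self):
        with pytest.raises(CycleError):
            load_network(
                [("A", "B"), ("B", "A")], {"A": ["hidden"], "B": ["hidden"]}
            )

    def test_unknown_node_rejected(self):
        with pytest.raises(UnknownNodeError):
            load_network([("A", "B")], {"A": ["ligand"]})

    def test_empty_edge_list_rejected(self):
        with pytest.raises(NetworkError):
            load_network([], {"A": ["ligand"]})

    def test_self_loop_rejected(self):
        with pytest.raises(NetworkError):
            load_network([("A", "A")], {"A": ["hidden"]})

    def test_hidden_flag_inconsistency_rejected(self):
        with pytest.raises(NetworkError):
            NodeRole.from_names(["observed", "hidden"])


class TestEdits:
    def test_edit_legality(self, chain_net):
        with pytest.raises(NetworkError):
            chain_net.with_edge_added("L", "R")  # duplicate
        with pytest.raises(CycleError):
            chain_net.with_edge_added("P", "L")
        assert chain_net.with_edge_removed("H", "P").n_edges == 2
        # edits are copy-on-write
        assert chain_net.n_edges == 3

    def test_ligand_receptor_edges(self, chain_net):
        assert chain_net.ligand_receptor_edges() == {("L", "R")}


class TestCollapse:
    def _net(self, edges, observed):
        nodes = {n for e in edges for n in e}
        roles = {n: NodeRole(observed=n in observed) for n in nodes}
        return SignalingNetwork(roles, edges)

    def test_single_hidden_hop(self):
        net = self._net([("A", "h"), ("h", "B")], observed={"A", "B"})
        assert set(collapse_to_observed(net).edges) == {("A", "B")}

    def test_visible_edge_preserved(self):
        net = self._net([("A", "B")], observed={"A", "B"})
        assert set(collapse_to_observed(net).edges) == {("A", "B")}

    def test_branching_hidden_paths(self):
        net = self._net(
            [("A", "h1"), ("h1", "h2"), ("h2", "B"), ("h1", "C")],
            observed={"A", "B", "C"},
        )
        got = set(collapse_to_observed(net).edges)
        assert got == {("A", "B"), ("A", "C")}
        assert got == brute_force_collapse_edges(net)

    def test_visible_interior_blocks_projection(self):
        # A -> B -> C with all visible: no shortcut A -> C
        net = self._net([("A", "B"), ("B", "C")], observed={"A", "B", "C"})
        assert set(collapse_to_observed(net).edges) == {("A", "B"), ("B", "C")}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        net = random_dag(rng)
        collapsed = collapse_to_observed(net)
        assert set(collapsed.edges) == brute_force_collapse_edges(net)
        again = collapse_to_observed(collapsed)
        assert set(again.edges) == set(collapsed.edges)
        assert set(again.nodes) == set(collapsed.nodes)

    def test_empty_hidden_set_is_identity(self):
        net = self._net([("A", "B"), ("B", "C")], observed={"A", "B", "C"})
        collapsed = collapse_to_observed(net)
        assert set(collapsed.nodes) == set(net.nodes)
        assert set(collapsed.edges) == set(net.edges)


class TestMarkovBlanket:
    def test_chain(self):
        net = load_network(
            [("A", "B"), ("B", "C")],
            {"A": ["hidden"], "B": ["hidden"], "C": ["hidden"]},
        )
        assert markov_blanket(net, "B") == {"A", "C"}

    def test_v_structure_includes_coparent(self):
        net = load_network(
            [("A", "C"), ("B", "C")],
            {"A": ["hidden"], "B": ["hidden"], "C": ["hidden"]},
        )
        assert markov_blanket(net, "A") == {"C", "B"}

    def test_unknown_node(self, chain_net):
        with pytest.raises(UnknownNodeError):
            markov_blanket(chain_net, "nope")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_dags(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_dag(rng)
        for node in net.nodes:
            assert markov_blanket(net, node) == brute_force_blanket(net, node)

    def test_blanket_renders_node_independent(self, rng):
        """Conditioned on its blanket, a node is independent of any other
        node: checked by exhaustive enumeration under random CPDs."""
        net = random_layered_net(rng, n_nodes=5)
        params = {
            n: NodeParameters(
                float(rng.normal(0, 1)),
                {p: float(rng.normal(0, 2)) for p in net.parents(n)},
            )
            for n in net.nodes
            if not net.role(n).ligand
        }
        clamps = {"L": 1}
        free, joint = joint_distribution(net, params, clamps)
        for node in free:
            blanket = markov_blanket(net, node) - set(clamps)
            outside = [
                n for n in free if n != node and n not in blanket
            ]
            if not outside:
                continue
            i = free.index(node)
            # p(node | blanket) must not depend on the outside node's value
            for blanket_state in itertools.product((0, 1), repeat=len(blanket)):
                fixed = dict(zip(sorted(blanket), blanket_state))
                probs = []
                for out_val in (0, 1):
                    num = den = 0.0
                    for state, p in joint.items():
                        if any(
                            state[free.index(k)] != v for k, v in fixed.items()
                        ):
                            continue
                        if state[free.index(outside[0])] != out_val:
                            continue
                        den += p
                        num += p * state[i]
                    if den > 1e-12:
                        probs.append(num / den)
                if len(probs) == 2:
                    assert probs[0] == pytest.approx(probs[1], abs=1e-9)
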