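"""Synthetic signaling scenarios with the statistical structure the method
assumes.

A scenario bundles everything a study needs: a layered ground-truth DAG
(ligands -> receptors -> hidden kinase cascade -> observed phosphoprotein
leaves), logistic propagation parameters, a canonical network that is the
truth plus decoy edges (mirroring a literature union that overstates any one
cell type), a gene-gene similarity matrix statistically enriched for true
edges, an experimental design of stimulus/inhibitor combinations over time
points, and fluorescence readings emitted from the two-component Gaussian
model with an optional detector floor.

Similarity scores are drawn from overlapping but separated Beta components
(true pairs ~ Beta(5, 2), all other pairs ~ Beta(2, 5)): enough signal for
prior-guided search to help without making it trivial.  Injected "noise"
edges are forced to score exactly zero so elimination experiments can target
them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from numpy.random import Generator, default_rng

from .mcem import ExperimentTable, NodeParameters, Record, clamp_assignment
from .network import NodeRole, SignalingNetwork
from .prior import SimilarityPrior, build_prior, is_legal_addition
from .search import SaturationError, _legal_additions

__all__ = [
    "SyntheticScenario",
    "generate_scenario",
    "inject_noise_edges",
    "DREAM4_LIKE",
]

Pair = tuple[str, str]

#: Default study conditions mirroring a cytokine/phosphoprotein screen:
#: 4 ligands, a 20-node hidden cascade, 7 observed phosphoproteins,
#: 25 conditions x 3 time points = 75 records of 7 readings each.
DREAM4_LIKE = dict(
    n_ligands=4,
    n_hidden=20,
    n_observed=7,
    n_decoy_edges=8,
    n_conditions=25,
    n_time_points=3,
    effect_range=(2.0, 6.0),
    emission_gap=1000.0,
    noise_sd=200.0,
)


@dataclass
class SyntheticScenario:
    """Ground truth plus everything the inference pipeline consumes."""

    truth_net: SignalingNetwork
    truth_params: dict[str, NodeParameters]
    canonical_net: SignalingNetwork
    similarity: dict[Pair, float]
    design: ExperimentTable
    readings: ExperimentTable
    seed: int
    truth_states: np.ndarray = field(repr=False, default=None)  # (R, n_nodes)
    state_nodes: tuple[str, ...] = ()

    @property
    def prior(self) -> SimilarityPrior:
        return build_prior(self.similarity, self.canonical_net.nodes)

    @property
    def decoy_edges(self) -> frozenset[Pair]:
        return frozenset(self.canonical_net.edges) - frozenset(self.truth_net.edges)

    def with_noise_edges(self, n: int, seed: int) -> "SyntheticScenario":
        """Scenario whose canonical network carries ``n`` extra random legal
        edges with similarity forced to exactly 0."""
        noisy = inject_noise_edges(self.canonical_net, n, seed)
        added = frozenset(noisy.edges) - frozenset(self.canonical_net.edges)
        similarity = dict(self.similarity)
        for u, v in added:
            similarity[tuple(sorted((u, v)))] = 0.0
        return replace(self, canonical_net=noisy, similarity=similarity)

    def true_state(self, record_index: int, node: str) -> int:
        return int(self.truth_states[record_index, self.state_nodes.index(node)])


def _layer_sizes(n_hidden: int, width: int = 5) -> list[int]:
    n_layers = max(1, math.ceil(n_hidden / width))
    base = n_hidden // n_layers
    sizes = [base] * n_layers
    for i in range(n_hidden - base * n_layers):
        sizes[i] += 1
    return sizes


def _connect_layer(
    rng: Generator, prev: list[str], layer: list[str], max_extra: int = 1
) -> list[Pair]:
    """Each node draws 1 + Binomial parents from the previous layer; every
    previous-layer node is then guaranteed at least one child."""
    edges: list[Pair] = []
    covered: set[str] = set()
    for node in layer:
        k = 1 + int(rng.binomial(max_extra, 0.4))
        k = min(k, len(prev))
        parents = rng.choice(len(prev), size=k, replace=False)
        for p in parents:
            edges.append((prev[int(p)], node))
            covered.add(prev[int(p)])
    for p in prev:
        if p not in covered:
            child = layer[int(rng.integers(len(layer)))]
            edges.append((p, child))
    return sorted(set(edges))


def generate_scenario(
    n_ligands: int = 4,
    n_hidden: int = 20,
    n_observed: int = 7,
    n_decoy_edges: int = 8,
    n_conditions: int = 25,
    n_time_points: int = 3,
    effect_range: tuple[float, float] = (2.0, 6.0),
    emission_gap: float = 1000.0,
    noise_sd: float = 200.0,
    seed: int = 0,
    neg_edge_frac: float = 0.0,
    n_inhibitable_hidden: int = 2,
    n_inhibitable_observed: int = 2,
    skip_edges: bool = False,
    apply_floor: bool = False,
    detector_floor: float = 300.0,
) -> SyntheticScenario:
    """Generate a full synthetic study.

    Builds a layered DAG, draws logistic weights with magnitudes uniform in
    ``effect_range`` (sign fixed per edge, negative with probability
    ``neg_edge_frac``), simulates binary states per record by clamped
    topological forward sampling, and emits readings v ~ N(mu_s, sigma) with
    mu1 - mu0 = ``emission_gap`` and sigma = ``noise_sd``.  ``skip_edges``
    adds a few cross-layer shortcuts for harder tests; ``apply_floor``
    truncates readings below ``detector_floor`` at the floor, emulating the
    detector noise floor of fluorescence readers.
    """
    if min(n_ligands, n_hidden, n_observed, n_conditions, n_time_points) < 1:
        raise ValueError("all scenario counts must be >= 1")
    if emission_gap <= 0:
        raise ValueError("emission_gap must be positive")
    rng = default_rng(seed)

    ligands = [f"L{i + 1:02d}" for i in range(n_ligands)]
    receptors = [f"R{i + 1:02d}" for i in range(n_ligands)]
    hidden = [f"H{i + 1:02d}" for i in range(n_hidden)]
    observed = [f"P{i + 1:02d}" for i in range(n_observed)]

    edges: list[Pair] = [(l, r) for l, r in zip(ligands, receptors)]
    layers: list[list[str]] = []
    start = 0
    for size in _layer_sizes(n_hidden):
        layers.append(hidden[start:start + size])
        start += size
    prev = receptors
    for layer in layers:
        edges += _connect_layer(rng, prev, layer)
        prev = layer
    edges += _connect_layer(rng, prev, observed, max_extra=2)
    if skip_edges and len(layers) > 1:
        for _ in range(max(2, n_hidden // 8)):
            a = layers[0][int(rng.integers(len(layers[0])))]
            b = observed[int(rng.integers(len(observed)))]
            edges.append((a, b))
        edges = sorted(set(edges))

    inh_hidden = [
        hidden[i]
        for i in rng.choice(
            n_hidden, size=min(n_inhibitable_hidden, n_hidden), replace=False
        )
    ]
    inh_observed = [
        observed[i]
        for i in rng.choice(
            n_observed, size=min(n_inhibitable_observed, n_observed), replace=False
        )
    ]
    roles: dict[str, NodeRole] = {}
    for n in ligands:
        roles[n] = NodeRole(ligand=True)
    for n in receptors:
        roles[n] = NodeRole(receptor=True)
    for n in hidden:
        roles[n] = NodeRole(inhibitable=n in inh_hidden)
    for n in observed:
        roles[n] = NodeRole(observed=True, inhibitable=n in inh_observed)

    truth = SignalingNetwork(roles, sorted(set(edges)), name=f"truth-{seed}")

    # --- logistic parameters ------------------------------------------------
    lo, hi = effect_range
    params: dict[str, NodeParameters] = {}
    for node in truth.nodes:
        if roles[node].ligand:
            continue
        betas: dict[str, float] = {}
        for p in truth.parents(node):
            mag = float(rng.uniform(lo, hi))
            sign = -1.0 if rng.random() < neg_edge_frac else 1.0
            if roles[p].ligand:
                sign = 1.0  # a receptor is activated by its ligand
            betas[p] = sign * mag
        # OR-gate intercept: any single active parent activates the child
        # (kinase cascades are redundant-activator systems), the all-off
        # baseline stays firmly inactive
        positives = [b for b in betas.values() if b > 0]
        if positives:
            beta0 = -0.5 * min(positives)
        else:
            beta0 = float(rng.uniform(-2.0, -1.0))
        if roles[node].observed:
            mu0 = float(rng.uniform(300.0, 500.0))
            params[node] = NodeParameters(
                beta0, betas,
                mu0=mu0, mu1=mu0 + emission_gap,
                sigma0=noise_sd, sigma1=noise_sd,
            )
        else:
            params[node] = NodeParameters(beta0, betas)

    # --- canonical = truth + decoys ----------------------------------------
    canonical = truth
    for _ in range(n_decoy_edges):
        legal = _legal_additions(canonical)
        if not legal:
            break
        u, v = legal[int(rng.integers(len(legal)))]
        canonical = canonical.with_edge_added(u, v)
    canonical = SignalingNetwork(roles, canonical.edges, name=f"canonical-{seed}")

    # --- similarity: true pairs bright, everything else dim -----------------
    truth_pairs = {tuple(sorted(e)) for e in truth.edges}
    similarity: dict[Pair, float] = {}
    nodes_sorted = sorted(truth.nodes)
    for i, a in enumerate(nodes_sorted):
        for b in nodes_sorted[i + 1:]:
            if (a, b) in truth_pairs:
                similarity[(a, b)] = float(rng.beta(5.0, 2.0))
            else:
                similarity[(a, b)] = float(rng.beta(2.0, 5.0))

    # --- experimental design ------------------------------------------------
    inhibitable = truth.inhibitable_nodes
    times = [0.0, 30.0, 180.0][:n_time_points]
    if n_time_points > 3:
        times = list(np.linspace(0.0, 180.0, n_time_points))
    # balanced screen design: cycle through an unstimulated control and each
    # single ligand so every receptor's pathway is probed individually, with
    # ligand pairs interleaved; inhibitors rotate over alternate conditions
    design_records: list[Record] = []
    cycle = n_ligands + 2
    for c in range(n_conditions):
        slot = c % cycle
        if slot == 0:
            stimuli: frozenset = frozenset()  # control
        elif slot <= n_ligands:
            stimuli = frozenset({ligands[slot - 1]})
        else:
            k = min(2, n_ligands)
            stimuli = frozenset(
                ligands[int(i)] for i in rng.choice(n_ligands, k, replace=False)
            )
        if inhibitable and c % 2 == 1:
            inhibited = frozenset(
                {inhibitable[(c // 2) % len(inhibitable)]}
            )
        else:
            inhibited = frozenset()
        for t in times:
            design_records.append(
                Record(condition=f"c{c:02d}", time=t, stimuli=stimuli,
                       inhibited=inhibited)
            )
    design = ExperimentTable(design_records)

    # --- forward simulation -------------------------------------------------
    order = truth.topological_order()
    states, readings_tbl = _simulate_readings(
        truth, params, design, rng,
        apply_floor=apply_floor, detector_floor=detector_floor,
    )

    return SyntheticScenario(
        truth_net=truth,
        truth_params=params,
        canonical_net=canonical,
        similarity=similarity,
        design=design,
        readings=readings_tbl,
        seed=seed,
        truth_states=states,
        state_nodes=tuple(order),
    )


def _simulate_readings(
    net: SignalingNetwork,
    params: Mapping[str, NodeParameters],
    design: ExperimentTable,
    rng: Generator,
    apply_floor: bool = False,
    detector_floor: float = 300.0,
) -> tuple[np.ndarray, ExperimentTable]:
    """Clamped topological forward sampling of states, then Gaussian
    emission of readings for observed nodes."""
    from scipy.special import expit

    order = net.topological_order()
    index = {n: i for i, n in enumerate(order)}
    R = len(design)
    S = np.zeros((R, len(order)), dtype=np.int8)
    clamped = np.zeros((R, len(order)), dtype=bool)
    cval = np.zeros((R, len(order)), dtype=np.int8)
    for r, rec in enumerate(design.records):
        for node, v in clamp_assignment(net, rec).items():
            clamped[r, index[node]] = True
            cval[r, index[node]] = v
    for i, node in enumerate(order):
        pr = params.get(node)
        if pr is None:
            eta = np.zeros(R)
        else:
            pa = [index[p] for p in net.parents(node)]
            bw = np.array([pr.betas[p] for p in net.parents(node)])
            eta = pr.beta0 + (S[:, pa] @ bw if pa else 0.0)
        draw = (rng.random(R) < expit(eta)).astype(np.int8)
        S[:, i] = np.where(clamped[:, i], cval[:, i], draw)

    completed: list[Record] = []
    for r, rec in enumerate(design.records):
        readings: dict[str, float] = {}
        for node in net.observed_nodes:
            pr = params[node]
            s = S[r, index[node]]
            mu = pr.mu1 if s == 1 else pr.mu0
            sg = pr.sigma1 if s == 1 else pr.sigma0
            v = float(rng.normal(mu, sg))
            if apply_floor:
                v = max(v, detector_floor)
            readings[node] = max(v, 0.0)
        completed.append(replace(rec, readings=readings))
    return S, ExperimentTable(completed)


def inject_noise_edges(
    canonical: SignalingNetwork, n: int, rng_seed: int = 0
) -> SignalingNetwork:
    """Return the canonical network plus ``n`` random legal edges.

    The injected edges stand for biologically irrelevant connections; pair
    them with zero similarity scores (``SyntheticScenario.with_noise_edges``)
    to reproduce noisy-network elimination experiments.  Acyclicity and all
    role rules are preserved; raises ``SaturationError`` if fewer than ``n``
    legal additions exist.
    """
    rng = default_rng(rng_seed)
    net = canonical
    for step in range(n):
        # never-deletable additions (ligand -> receptor is protected) would
        # make elimination experiments ill-posed, so they are not noise
        # candidates
        legal = [
            (u, v)
            for u, v in _legal_additions(net)
            if not (net.role(u).ligand and net.role(v).receptor)
        ]
        if not legal:
            raise SaturationError(
                f"only {step} of {n} requested noise edges could be added"
            )
        u, v = legal[int(rng.integers(len(legal)))]
        net = net.with_edge_added(u, v)
    return SignalingNetwork(canonical.roles, net.edges,
                            name=f"{canonical.name}+noise{n}")


def truth_to_json(scenario: SyntheticScenario) -> str:
    """Serializable ground-truth summary (edges, roles, parameters)."""
    payload = {
        "seed": scenario.seed,
        "truth_edges": sorted(scenario.truth_net.edges),
        "canonical_edges": sorted(scenario.canonical_net.edges),
        "roles": {
            n: list(scenario.truth_net.role(n).names())
            for n in scenario.truth_net.nodes
        },
        "params": {
            node: {
                "beta0": pr.beta0,
                "betas": dict(pr.betas),
                **(
                    {
                        "mu0": pr.mu0, "mu1": pr.mu1,
                        "sigma0": pr.sigma0, "sigma1": pr.sigma1,
                    }
                    if pr.has_emissions
                    else {}
                ),
            }
            for node, pr in scenario.truth_params.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)
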