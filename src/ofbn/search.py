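"""Prior-guided stochastic structure search with BIC model selection.

Starting from a canonical (literature union) network, candidate structures
are produced by chains of single-edge moves.  Each move flips a fair coin
between addition and deletion, samples an unordered pair from the similarity
prior (addition probability rises with similarity, deletion probability
falls), rejects illegal draws, and re-draws; when one move type is exhausted
the other is used.  Every candidate is fitted by Monte Carlo EM, L1-pruned in
its final round, scored by BIC = -2*loglik + k*log(n), and the minimum-BIC
candidate is returned.

Each candidate chain branches independently from the canonical network with
its own seeded random stream, so pools are reproducible and parallelizable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .mcem import (
    ExperimentTable,
    MCEMConfig,
    MCEMResult,
    NodeParameters,
    count_parameters,
    fit_mcem,
)
from .network import SignalingNetwork
from .prior import SimilarityPrior, is_legal_addition, is_legal_deletion

__all__ = [
    "Move",
    "SaturationError",
    "ScoredCandidate",
    "SearchResult",
    "propose_update",
    "propose_chain",
    "search",
]

log = logging.getLogger(__name__)


class SaturationError(RuntimeError):
    """No legal edge move of either type exists."""


@dataclass(frozen=True)
class Move:
    kind: str  # "add" | "delete"
    parent: str
    child: str


def _legal_additions(net: SignalingNetwork) -> list[tuple[str, str]]:
    out = []
    for u in net.nodes:
        for v in net.nodes:
            if u != v and is_legal_addition(net, u, v):
                out.append((u, v))
    return out


def _legal_deletions(net: SignalingNetwork) -> list[tuple[str, str]]:
    return [(u, v) for u, v in net.edges if is_legal_deletion(net, u, v)]


def _try_move(
    net: SignalingNetwork,
    prior: SimilarityPrior,
    rng: Generator,
    kind: str,
    max_rejections: int,
) -> tuple[SignalingNetwork, Move] | None:
    for _ in range(max_rejections):
        a, b = prior.sample_pair(rng, kind)
        if a not in net or b not in net:
            continue
        if kind == "add":
            options = [
                (u, v) for u, v in ((a, b), (b, a)) if is_legal_addition(net, u, v)
            ]
            if options:
                u, v = options[int(rng.integers(len(options)))]
                return net.with_edge_added(u, v), Move("add", u, v)
        else:
            options = [
                (u, v) for u, v in ((a, b), (b, a)) if is_legal_deletion(net, u, v)
            ]
            if options:
                u, v = options[0]  # at most one direction can exist in a DAG
                return net.with_edge_removed(u, v), Move("delete", u, v)
    return None


def propose_update(
    net: SignalingNetwork,
    prior: SimilarityPrior,
    rng_seed: int | Generator = 0,
    max_rejections: int = 1000,
    return_move: bool = False,
):
    """Propose a network differing from ``net`` by one legal edge move.

    The move type is a fair coin flip; the pair is sampled proportionally to
    the prior's add (or delete) probability; illegal draws are rejected and
    redrawn.  An added edge between an unordered pair is oriented to preserve
    acyclicity, uniformly at random when both directions are legal.  After
    ``max_rejections`` rejections the move type is flipped; if no legal move
    of either type exists a ``SaturationError`` is raised.
    """
    rng = rng_seed if isinstance(rng_seed, Generator) else default_rng(rng_seed)
    first = "add" if rng.random() < 0.5 else "delete"
    second = "delete" if first == "add" else "add"

    has_add = bool(_legal_additions(net))
    has_del = bool(_legal_deletions(net))
    if not has_add and not has_del:
        raise SaturationError("no legal edge addition or deletion exists")

    for kind in (first, second):
        feasible = has_add if kind == "add" else has_del
        if not feasible:
            continue
        result = _try_move(net, prior, rng, kind, max_rejections)
        if result is not None:
            new_net, move = result
            return (new_net, move) if return_move else new_net
    raise SaturationError(
        "rejection sampling exhausted although legal moves exist "
        f"(max_rejections={max_rejections})"
    )


def propose_chain(
    net: SignalingNetwork,
    prior: SimilarityPrior,
    n_moves: int,
    rng_seed: int | Generator = 0,
    max_rejections: int = 1000,
) -> tuple[SignalingNetwork, tuple[Move, ...]]:
    """Apply ``n_moves`` sequential prior-guided updates; returns the final
    network and the move provenance (replayable from the seed)."""
    rng = rng_seed if isinstance(rng_seed, Generator) else default_rng(rng_seed)
    moves: list[Move] = []
    current = net
    for _ in range(n_moves):
        current, move = propose_update(
            current, prior, rng, max_rejections, return_move=True
        )
        moves.append(move)
    return current, tuple(moves)


@dataclass
class ScoredCandidate:
    """A fitted, pruned candidate structure with its BIC score."""

    network: SignalingNetwork
    params: dict[str, NodeParameters]
    loglik: float
    bic: float
    k: int
    n: int
    moves: tuple[Move, ...]
    seed: int
    converged: bool
    trace: list[float]
    pruned_edges: tuple


@dataclass
class SearchResult:
    best: ScoredCandidate
    candidates: list[ScoredCandidate]

    def table(self) -> list[dict]:
        return [
            {
                "candidate": i,
                "seed": c.seed,
                "loglik": c.loglik,
                "k": c.k,
                "bic": c.bic,
                "n_edges": c.network.n_edges,
                "converged": c.converged,
            }
            for i, c in enumerate(self.candidates)
        ]


def _score(fit: MCEMResult, n_records: int) -> tuple[int, float]:
    k = count_parameters(fit.network, fit.params)
    bic = -2.0 * fit.loglik + k * math.log(max(n_records, 2))
    return k, bic


def search(
    canonical: SignalingNetwork,
    prior: SimilarityPrior,
    data: ExperimentTable,
    n_candidates: int = 50,
    n_moves: int = 10,
    rng_seed: int = 0,
    config: MCEMConfig | None = None,
    max_rejections: int = 1000,
) -> SearchResult:
    """Generate, fit and score a pool of candidate structures; keep the best.

    ``n_candidates`` chains of ``n_moves`` prior-guided moves each branch
    independently from the canonical network (``n_moves=0`` fits the
    canonical network itself).  Candidates whose fit fails are dropped with a
    warning; if all fail an error is raised.  The minimum-BIC candidate is
    returned with L1-zeroed edges already removed from its structure.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    data.validate_against(canonical)
    cfg = config or MCEMConfig()
    children = SeedSequence(rng_seed).spawn(n_candidates)
    scored: list[ScoredCandidate] = []
    for c, child_ss in enumerate(children):
        move_seed, fit_seed = (
            int(s) % (2**31) for s in child_ss.generate_state(2)
        )
        rng = default_rng(move_seed)
        try:
            candidate, moves = propose_chain(
                canonical, prior, n_moves, rng, max_rejections
            )
        except SaturationError as exc:
            warnings.warn(f"candidate {c}: move chain saturated ({exc})")
            candidate, moves = canonical, ()
        try:
            fit = fit_mcem(
                candidate, data,
                MCEMConfig(**{**cfg.__dict__, "seed": fit_seed}),
            )
        except Exception as exc:  # noqa: BLE001 - candidate-level isolation
            warnings.warn(f"candidate {c}: MCEM failed ({exc}); dropped")
            continue
        k, bic = _score(fit, len(data))
        scored.append(
            ScoredCandidate(
                network=fit.network,
                params=fit.params,
                loglik=fit.loglik,
                bic=bic,
                k=k,
                n=len(data),
                moves=moves,
                seed=move_seed,
                converged=fit.converged,
                trace=fit.trace,
                pruned_edges=fit.pruned_edges,
            )
        )
        log.info(
            "candidate %d/%d: %d edges, loglik %.2f, BIC %.2f",
            c + 1, n_candidates, fit.network.n_edges, fit.loglik, bic,
        )
    if not scored:
        raise RuntimeError("every candidate failed to fit")
    best = min(scored, key=lambda s: s.bic)
    return SearchResult(best=best, candidates=scored)
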