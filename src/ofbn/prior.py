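"""Edge move prior from pairwise gene similarity scores.

A nonnegative symmetric similarity matrix (e.g. literature-derived semantic
similarity between genes) is converted into per-pair probabilities for edge
*addition* and *deletion* moves:

* the scores of all unordered candidate pairs are ranked ascending; the
  probability of proposing to add a pair is its ascending rank divided by the
  sum of all ascending ranks, so highly similar pairs are added more often;
* symmetrically, deletion probability uses the descending rank, so dissimilar
  pairs are deleted more often.

Ties take average ranks, which keeps the probabilities invariant under node
relabeling.  Missing pairs are scored 0 (absence of literature co-mention is
weak evidence against a connection).  Self-pairs are excluded.

The module also encodes the biological legality rules for structure moves:
ligands only feed their receptors, nothing feeds a ligand, receptor-receptor
edges are forbidden, ligand->receptor edges may never be deleted, and every
move must keep the graph acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .network import SignalingNetwork, UnknownNodeError

__all__ = [
    "SimilarityPrior",
    "build_prior",
    "is_legal_addition",
    "is_legal_deletion",
]

Pair = tuple[str, str]


def _norm_pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SimilarityPrior:
    """Similarity scores and derived add/delete move probabilities."""

    nodes: tuple[str, ...]
    pairs: tuple[Pair, ...]
    scores: np.ndarray       # (n_pairs,)
    asc_rank: np.ndarray     # ascending average ranks
    desc_rank: np.ndarray    # descending average ranks
    p_add: np.ndarray        # sums to 1
    p_del: np.ndarray        # sums to 1

    def _index(self, a: str, b: str) -> int:
        pair = _norm_pair(a, b)
        try:
            return self.pairs.index(pair)
        except ValueError:
            raise UnknownNodeError(f"pair {pair!r} not covered by the prior") from None

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self._index(a, b)])

    def p_add_of(self, a: str, b: str) -> float:
        return float(self.p_add[self._index(a, b)])

    def p_del_of(self, a: str, b: str) -> float:
        return float(self.p_del[self._index(a, b)])

    def sample_pair(self, rng: np.random.Generator, kind: str = "add") -> Pair:
        """Draw one unordered pair according to its move probability."""
        if kind == "add":
            p = self.p_add
        elif kind in ("del", "delete"):
            p = self.p_del
        else:
            raise ValueError(f"kind must be 'add' or 'delete', got {kind!r}")
        i = int(rng.choice(len(self.pairs), p=p))
        return self.pairs[i]

    @classmethod
    def uniform(cls, nodes) -> "SimilarityPrior":
        """Flat prior over all pairs; used for unguided (random) search."""
        return build_prior({}, nodes)


def build_prior(
    scores: Mapping[Pair, float] | Mapping[frozenset, float],
    nodes,
) -> SimilarityPrior:
    """Convert pairwise similarity scores into move probabilities.

    ``scores`` maps unordered node pairs to nonnegative values; pairs absent
    from the mapping are imputed as 0.  Raises on negative scores or fewer
    than two nodes.
    """
    node_tuple = tuple(sorted(set(map(str, nodes))))
    if len(node_tuple) < 2:
        raise ValueError("need at least 2 nodes to build an edge prior")
    table: dict[Pair, float] = {}
    for key, val in scores.items():
        a, b = tuple(key)
        if a == b:
            continue  # self-pairs are not edge candidates
        val = float(val)
        if val < 0:
            raise ValueError(f"negative similarity score for pair ({a!r}, {b!r})")
        table[_norm_pair(str(a), str(b))] = val
    pairs = tuple(combinations(node_tuple, 2))
    s = np.array([table.get(p, 0.0) for p in pairs], dtype=float)
    asc = rankdata(s, method="average")
    desc = rankdata(-s, method="average")
    return SimilarityPrior(
        nodes=node_tuple,
        pairs=pairs,
        scores=s,
        asc_rank=asc,
        desc_rank=desc,
        p_add=asc / asc.sum(),
        p_del=desc / desc.sum(),
    )


def is_legal_addition(net: SignalingNetwork, parent: str, child: str) -> bool:
    """May ``parent -> child`` be added?

    Forbidden: existing edges, self-loops, any edge into a ligand, any edge
    out of a ligand to a non-receptor (this subsumes ligand-ligand edges),
    receptor-receptor edges, and additions that would create a cycle.
    """
    rp = net.role(parent)
    rc = net.role(child)
    if parent == child or net.has_edge(parent, child):
        return False
    if rc.ligand:
        return False  # nothing may signal into an extracellular ligand
    if rp.ligand and not rc.receptor:
        return False  # ligands only bind receptors
    if rp.receptor and rc.receptor:
        return False
    if net.would_create_cycle(parent, child):
        return False
    return True


def is_legal_deletion(net: SignalingNetwork, parent: str, child: str) -> bool:
    """May ``parent -> child`` be deleted?

    The edge must exist, and ligand -> receptor edges are protected (the
    input signal must stay wired to its receptor).
    """
    rp = net.role(parent)
    rc = net.role(child)
    if not net.has_edge(parent, child):
        return False
    if rp.ligand and rc.receptor:
        return False
    return True
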