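import logging
import warnings

import numpy as np
import pytest

from ofbn import NodeRole, Record, SignalingNetwork
from ofbn.mcem import ExperimentTable

# MCEM emits RuntimeWarnings for degenerate nodes and log-warnings for
# capped iteration counts; both are expected at the reduced test settings.
logging.getLogger("ofbn").setLevel(logging.ERROR)
logging.getLogger("ofbn.mcem").setLevel(logging.ERROR)
logging.getLogger("ofbn.search").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def chain_net():
    """L -> R -> H -> P: one ligand, one receptor, one hidden kinase, one
    observed phosphoprotein."""
    roles = {
        "L": NodeRole(ligand=True),
        "R": NodeRole(receptor=True),
        "H": NodeRole(),
        "P": NodeRole(observed=True),
    }
    return SignalingNetwork(
        roles, [("L", "R"), ("R", "H"), ("H", "P")], name="chain"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_layered_net(rng, n_nodes=6):
    """A random small layered DAG with ligand/receptor/hidden/observed roles
    (used by oracle comparisons)."""
    n_hidden = max(n_nodes - 3, 1)
    roles = {"L": NodeRole(ligand=True), "R": NodeRole(receptor=True)}
    hidden = [f"H{i}" for i in range(n_hidden - 1)]
    for h in hidden:
        roles[h] = NodeRole(inhibitable=True)
    roles["P"] = NodeRole(observed=True)
    edges = [("L", "R")]
    prev = ["R"]
    for h in hidden:
        k = 1 + int(rng.integers(0, min(2, len(prev))))
        for p in rng.choice(prev, size=k, replace=False):
            edges.append((str(p), h))
        prev.append(h)
    for p in rng.choice(prev, size=min(2, len(prev)), replace=False):
        edges.append((str(p), "P"))
    return SignalingNetwork(roles, sorted(set(edges)), name="rand")


def single_record_table(n_chains, stimuli=("L",), inhibited=(), readings=None):
    """The same experimental record replicated n_chains times: each copy is
    an independent, identically-clamped Gibbs chain."""
    return ExperimentTable(
        [
            Record(
                condition=f"r{i}",
                time=0.0,
                stimuli=frozenset(stimuli),
                inhibited=frozenset(inhibited),
                readings=dict(readings or {}),
            )
            for i in range(n_chains)
        ]
    )
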