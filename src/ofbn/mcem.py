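"""Monte Carlo EM fitting of the latent-state signaling network.

Model
-----
Each protein node ``i`` carries a binary activation (phosphorylation) state
``s_i``.  Given the states of its parents, a node activates through a
logistic conditional:

    p(s_i = 1 | pa(s_i)) = 1 / (1 + exp(-(beta_i0 + sum_j beta_ij * s_j)))

Observed nodes additionally emit a fluorescence reading from a two-component
Gaussian mixture over the latent state:

    v_i | s_i = 0  ~  N(mu_i0, sigma_i0)        (unphosphorylated, dim)
    v_i | s_i = 1  ~  N(mu_i1, sigma_i1)        (phosphorylated, bright)

Experimental design enters through *clamping*: a stimulated ligand is fixed
active, a non-stimulated ligand fixed inactive, and an inhibited kinase is
fixed inactive for that record.  Clamping is treated as an intervention: the
clamped node's own conditional drops out of the joint, so knowledge of an
inhibited child never flows back to its parents.

Fitting alternates a Gibbs E-step (systematic-scan sampling of all unclamped
states from their Markov-blanket full conditionals) with an M-step that
refits the logistic coefficients by (optionally L1-penalized) logistic
regression on the sampled states and the emission parameters by state-
weighted moments of the readings.  The observed-data log-likelihood is
estimated by Monte Carlo forward sampling and drives the convergence check;
the final round applies the L1 penalty, and exactly-zeroed coefficients
delete their edges from the returned structure.
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.special import expit
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression


def _l1_logistic(C: float) -> LogisticRegression:
    try:  # scikit-learn >= 1.8 spells the penalty through l1_ratio
        return LogisticRegression(
            C=C, l1_ratio=1.0, solver="liblinear",
            intercept_scaling=10.0, max_iter=500,
        )
    except TypeError:  # pragma: no cover - older scikit-learn
        return LogisticRegression(
            penalty="l1", C=C, solver="liblinear",
            intercept_scaling=10.0, max_iter=500,
        )


def _plain_logistic() -> LogisticRegression:
    return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)

from .network import SignalingNetwork, UnknownNodeError

__all__ = [
    "NodeParameters",
    "Record",
    "ExperimentTable",
    "StateSamples",
    "MCEMConfig",
    "MCEMResult",
    "logistic_activation",
    "full_conditional",
    "hidden_full_conditional",
    "observed_full_conditional",
    "gibbs_e_step",
    "m_step",
    "mc_loglik",
    "fit_mcem",
    "count_parameters",
    "clamp_assignment",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeParameters:
    """Per-node logistic coefficients and (for observed nodes) emissions."""

    beta0: float
    betas: Mapping[str, float] = field(default_factory=dict)
    mu0: float | None = None
    mu1: float | None = None
    sigma0: float | None = None
    sigma1: float | None = None

    @property
    def has_emissions(self) -> bool:
        return self.mu0 is not None

    def validate(self) -> None:
        if self.has_emissions:
            if self.sigma0 is None or self.sigma1 is None:
                raise ValueError("emission sigmas missing")
            if self.sigma0 <= 0 or self.sigma1 <= 0:
                raise ValueError("emission sigmas must be positive")
            if self.mu1 < self.mu0:  # type: ignore[operator]
                raise ValueError("labels not anchored: mu1 < mu0")


@dataclass(frozen=True)
class Record:
    """One experimental record: clamps plus readings at one (condition, time)."""

    condition: str
    time: float
    stimuli: frozenset = frozenset()
    inhibited: frozenset = frozenset()
    readings: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prot, v in self.readings.items():
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(
                    f"negative reading {v} for {prot!r} in condition {self.condition!r}"
                )


@dataclass
class ExperimentTable:
    """A list of i.i.d. experimental records (condition x time points)."""

    records: list[Record]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterable[Record]:
        return iter(self.records)

    @property
    def proteins(self) -> tuple[str, ...]:
        seen: set[str] = set()
        for rec in self.records:
            seen.update(rec.readings)
        return tuple(sorted(seen))

    def validate_against(self, net: SignalingNetwork) -> None:
        ligands = set(net.ligands)
        inhibitable = set(net.inhibitable_nodes)
        observed = set(net.observed_nodes)
        for rec in self.records:
            bad = rec.stimuli - ligands
            if bad:
                raise UnknownNodeError(
                    f"stimulus on non-ligand node(s) {sorted(bad)} "
                    f"in condition {rec.condition!r}"
                )
            bad = rec.inhibited - inhibitable
            if bad:
                raise UnknownNodeError(
                    f"inhibition of non-inhibitable node(s) {sorted(bad)} "
                    f"in condition {rec.condition!r}"
                )
            bad = set(rec.readings) - observed
            if bad:
                raise UnknownNodeError(
                    f"reading for non-observed node(s) {sorted(bad)} "
                    f"in condition {rec.condition!r}"
                )

    def without_readings(self) -> "ExperimentTable":
        return ExperimentTable(
            [replace(rec, readings={}) for rec in self.records]
        )

    def subset(self, indices: Sequence[int]) -> "ExperimentTable":
        return ExperimentTable([self.records[i] for i in indices])


def clamp_assignment(net: SignalingNetwork, record: Record) -> dict[str, int]:
    """Clamped states for one record.

    Stimulated ligands are active (1), non-stimulated ligands inactive (0),
    and inhibited nodes inactive (0) regardless of their parents.
    """
    clamps = {lig: (1 if lig in record.stimuli else 0) for lig in net.ligands}
    for node in record.inhibited:
        clamps[node] = 0
    return clamps


# ---------------------------------------------------------------------------
# elementary conditionals (reference, per-record implementations)
# ---------------------------------------------------------------------------


def logistic_activation(
    params: NodeParameters, parent_states: Mapping[str, int] | Sequence[int]
) -> float:
    """Activation probability of a node given its parents' binary states."""
    betas = params.betas
    if isinstance(parent_states, Mapping):
        missing = set(betas) - set(parent_states)
        if missing:
            raise ValueError(f"missing parent state(s): {sorted(missing)}")
        eta = params.beta0 + sum(betas[j] * parent_states[j] for j in betas)
    else:
        if len(parent_states) != len(betas):
            raise ValueError(
                f"expected {len(betas)} parent states, got {len(parent_states)}"
            )
        eta = params.beta0 + sum(
            b * s for b, s in zip(betas.values(), parent_states)
        )
    return float(expit(eta))


def _emission_logpdf(
    v: float, mu: float, sigma: float, censor_floor: float | None = None
) -> float:
    if censor_floor is not None and v <= censor_floor:
        # left-censored: only "below the detector floor" is known
        return float(norm.logcdf(censor_floor, loc=mu, scale=sigma))
    return float(norm.logpdf(v, loc=mu, scale=sigma))


def full_conditional(
    net: SignalingNetwork,
    params: Mapping[str, NodeParameters],
    states: Mapping[str, int],
    node: str,
    reading: float | None = None,
    clamped: Iterable[str] = (),
    censor_floor: float | None = None,
) -> tuple[float, float]:
    """Markov-blanket full conditional ``(p(s=0|MB), p(s=1|MB))`` of a node.

    The numerator for state ``x`` is the node's own logistic prior times the
    likelihood of each (unclamped) child's current state under ``s_node=x``,
    times -- when a ``reading`` is supplied -- the Gaussian emission density
    of the reading under state ``x``; the pair is normalized to sum to one.
    """
    clamped = set(clamped)
    if node in clamped:
        raise ValueError(f"full conditional requested for clamped node {node!r}")
    pa = net.parents(node)
    p1 = logistic_activation(params[node], {j: states[j] for j in pa})
    w = [1.0 - p1, p1]
    for x in (0, 1):
        st = dict(states)
        st[node] = x
        for child in net.children(node):
            if child in clamped:
                continue  # intervention: clamped child's conditional is cut
            pc1 = logistic_activation(
                params[child], {j: st[j] for j in net.parents(child)}
            )
            w[x] *= pc1 if states[child] == 1 else 1.0 - pc1
    if reading is not None:
        pr = params[node]
        if not pr.has_emissions:
            raise ValueError(f"node {node!r} has no emission parameters")
        w[0] *= math.exp(_emission_logpdf(reading, pr.mu0, pr.sigma0, censor_floor))
        w[1] *= math.exp(_emission_logpdf(reading, pr.mu1, pr.sigma1, censor_floor))
    total = w[0] + w[1]
    if total == 0.0:  # numerically extinct: fall back to the prior term
        return 1.0 - p1, p1
    return w[0] / total, w[1] / total


def hidden_full_conditional(
    net: SignalingNetwork,
    params: Mapping[str, NodeParameters],
    states: Mapping[str, int],
    node: str,
    clamped: Iterable[str] = (),
) -> float:
    """``p(s_node = 1 | Markov blanket)`` for a node without a reading."""
    return full_conditional(net, params, states, node, None, clamped)[1]


def observed_full_conditional(
    net: SignalingNetwork,
    params: Mapping[str, NodeParameters],
    states: Mapping[str, int],
    node: str,
    reading: float | None,
    clamped: Iterable[str] = (),
    censor_floor: float | None = None,
) -> float:
    """``p(s_node = 1 | Markov blanket, reading)`` for an observed node.

    A missing reading (None/NaN) degrades gracefully to the hidden-node
    conditional.
    """
    if reading is None or (isinstance(reading, float) and math.isnan(reading)):
        reading = None
    return full_conditional(
        net, params, states, node, reading, clamped, censor_floor
    )[1]


# ---------------------------------------------------------------------------
# vectorized Gibbs engine (records in parallel)
# ---------------------------------------------------------------------------


class _GibbsEngine:
    """Systematic-scan Gibbs sampler vectorized across records.

    All records share the structure and parameters; clamps and readings vary
    per record, so one sweep updates each unclamped node across every record
    with a single vector operation.
    """

    def __init__(
        self,
        net: SignalingNetwork,
        params: Mapping[str, NodeParameters],
        table: ExperimentTable,
        use_readings: bool = True,
        censor_floor: float | None = None,
    ) -> None:
        self.net = net
        self.order = net.topological_order()
        self.index = {n: i for i, n in enumerate(self.order)}
        n_nodes = len(self.order)
        n_rec = len(table)
        self.n_rec = n_rec

        self.pa_idx: list[np.ndarray] = []
        self.bw: list[np.ndarray] = []
        self.b0 = np.zeros(n_nodes)
        for i, node in enumerate(self.order):
            pa = net.parents(node)
            self.pa_idx.append(np.array([self.index[p] for p in pa], dtype=np.intp))
            pr = params.get(node)
            if pr is None:
                self.bw.append(np.zeros(len(pa)))
            else:
                self.b0[i] = pr.beta0
                self.bw.append(np.array([pr.betas.get(p, 0.0) for p in pa]))

        # children[i]: (child_index, coefficient of node i in the child's CPD)
        self.children: list[list[tuple[int, float]]] = [[] for _ in range(n_nodes)]
        for i, node in enumerate(self.order):
            for child in net.children(node):
                j = self.index[child]
                pr = params.get(child)
                coef = pr.betas.get(node, 0.0) if pr is not None else 0.0
                self.children[i].append((j, coef))

        self.clamped = np.zeros((n_rec, n_nodes), dtype=bool)
        self.cval = np.zeros((n_rec, n_nodes), dtype=np.int8)
        for r, rec in enumerate(table.records):
            for node, v in clamp_assignment(net, rec).items():
                i = self.index[node]
                self.clamped[r, i] = True
                self.cval[r, i] = v

        # emission log-likelihood difference log N(v|1) - log N(v|0); zero
        # where there is no reading (missing readings behave as hidden)
        self.em_logdiff = np.zeros((n_rec, n_nodes))
        self.readings = np.full((n_rec, n_nodes), np.nan)
        if use_readings:
            for r, rec in enumerate(table.records):
                for node, v in rec.readings.items():
                    if v is None or (isinstance(v, float) and math.isnan(v)):
                        continue
                    i = self.index[node]
                    pr = params.get(node)
                    if pr is None or not pr.has_emissions:
                        continue
                    self.readings[r, i] = v
                    self.em_logdiff[r, i] = _emission_logpdf(
                        v, pr.mu1, pr.sigma1, censor_floor
                    ) - _emission_logpdf(v, pr.mu0, pr.sigma0, censor_floor)

        self.update_order = [
            i for i in range(n_nodes) if not self.clamped[:, i].all()
        ]

    # -- state handling ----------------------------------------------------

    def init_states(self, rng: Generator) -> np.ndarray:
        """Initial joint states: readings thresholded at their per-node
        median; everything else forward-sampled from the current CPDs."""
        S = np.zeros((self.n_rec, len(self.order)), dtype=np.int8)
        medians = {}
        for i in range(len(self.order)):
            col = self.readings[:, i]
            if np.isfinite(col).any():
                medians[i] = np.nanmedian(col)
        for i in range(len(self.order)):
            pa = self.pa_idx[i]
            eta = self.b0[i] + (S[:, pa] @ self.bw[i] if pa.size else 0.0)
            eta = np.broadcast_to(np.asarray(eta, dtype=float), (self.n_rec,))
            draw = (rng.random(self.n_rec) < expit(eta)).astype(np.int8)
            if i in medians:
                col = self.readings[:, i]
                have = np.isfinite(col)
                draw[have] = (col[have] > medians[i]).astype(np.int8)
            S[:, i] = np.where(self.clamped[:, i], self.cval[:, i], draw)
        return S

    def log_odds(self, S: np.ndarray, i: int) -> np.ndarray:
        """log p(s_i=1|rest) - log p(s_i=0|rest) for every record."""
        lo = np.full(self.n_rec, self.b0[i])
        pa = self.pa_idx[i]
        if pa.size:
            lo = lo + S[:, pa] @ self.bw[i]
        for j, coef in self.children[i]:
            pa_j = self.pa_idx[j]
            eta = self.b0[j] + (S[:, pa_j] @ self.bw[j] if pa_j.size else 0.0)
            eta0 = eta - coef * S[:, i]
            eta1 = eta0 + coef
            sc = S[:, j]
            contrib = np.where(
                sc == 1,
                np.logaddexp(0.0, -eta0) - np.logaddexp(0.0, -eta1),
                np.logaddexp(0.0, eta0) - np.logaddexp(0.0, eta1),
            )
            lo = lo + np.where(self.clamped[:, j], 0.0, contrib)
        return lo + self.em_logdiff[:, i]

    def sweep(
        self, S: np.ndarray, rng: Generator, uniforms: np.ndarray | None = None
    ) -> None:
        for k, i in enumerate(self.update_order):
            p1 = expit(self.log_odds(S, i))
            u = rng.random(self.n_rec) if uniforms is None else uniforms[:, k]
            draw = (u < p1).astype(np.int8)
            S[:, i] = np.where(self.clamped[:, i], self.cval[:, i], draw)

    def run(
        self,
        n_sweeps: int,
        burn_in: int,
        rng: Generator,
        uniforms: np.ndarray | None = None,
    ) -> np.ndarray:
        """Run the chain; return retained states (n_kept, n_records, n_nodes).

        ``uniforms`` of shape (n_records, n_sweeps, n_update_nodes) replaces
        the shared stream with per-record streams (used for order-invariant
        prediction).
        """
        if burn_in < 0 or n_sweeps <= burn_in:
            raise ValueError("need n_sweeps > burn_in >= 0")
        S = self.init_states(rng)
        kept = np.empty((n_sweeps - burn_in, self.n_rec, len(self.order)), np.int8)
        for t in range(n_sweeps):
            self.sweep(S, rng, None if uniforms is None else uniforms[:, t, :])
            if t >= burn_in:
                kept[t - burn_in] = S
        return kept


@dataclass
class StateSamples:
    """Retained Gibbs samples: (n_samples, n_records, n_nodes) binary array."""

    states: np.ndarray
    nodes: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_records(self) -> int:
        return self.states.shape[1]

    def node_index(self, node: str) -> int:
        return self.nodes.index(node)

    def marginal(self, node: str) -> np.ndarray:
        """Per-record posterior activation frequency of a node."""
        return self.states[:, :, self.node_index(node)].mean(axis=0)

    def sample(self, k: int, record: int) -> dict[str, int]:
        """One joint assignment (a single completed record)."""
        row = self.states[k, record]
        return {n: int(row[i]) for i, n in enumerate(self.nodes)}


def gibbs_e_step(
    net: SignalingNetwork,
    params: Mapping[str, NodeParameters],
    data: ExperimentTable,
    n_sweeps: int = 700,
    burn_in: int = 200,
    rng_seed: int | Generator = 0,
    censor_floor: float | None = None,
) -> StateSamples:
    """Sample latent states for every record by systematic-scan Gibbs.

    Nodes are updated in topological order from their Markov-blanket full
    conditionals; clamped nodes stay at their clamped value; samples after
    ``burn_in`` sweeps are retained.
    """
    rng = rng_seed if isinstance(rng_seed, Generator) else default_rng(rng_seed)
    engine = _GibbsEngine(net, params, data, censor_floor=censor_floor)
    kept = engine.run(n_sweeps, burn_in, rng)
    return StateSamples(states=kept, nodes=tuple(engine.order))


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def _weighted_logistic_loglik(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, beta0: float, betas: np.ndarray
) -> float:
    eta = beta0 + (X @ betas if X.size else np.zeros(len(y)))
    ll = -np.logaddexp(0.0, -eta) * y - np.logaddexp(0.0, eta) * (1 - y)
    return float(np.sum(w * ll))


def m_step(
    net: SignalingNetwork,
    samples: StateSamples,
    data: ExperimentTable,
    use_lasso: bool = False,
    lasso_grid: Sequence[float] = (100.0, 50.0, 25.0, 12.0, 6.0, 3.0, 1.5, 0.75),
    coef_bound: float = 25.0,
    prev: Mapping[str, NodeParameters] | None = None,
    zero_tol: float = 1e-8,
) -> dict[str, NodeParameters]:
    """Refit all node parameters from sampled states.

    Emission parameters of each observed node are updated first as state-
    weighted means/SDs of its readings, with label anchoring: if the fitted
    "active" mean dips below the "inactive" mean, the two mixture components
    are swapped and the node's sampled states flipped, so that phosphorylated
    always denotes the brighter component.  Logistic coefficients are then
    fitted per node on the (sample x record) stacked design; ``use_lasso``
    switches to L1-penalized fits with the penalty weight chosen per node by
    BIC over ``lasso_grid``, and coefficients shrunk below ``zero_tol`` are
    returned as exact zeros (marking their edges for deletion).
    """
    prev = dict(prev or {})
    S = samples.states.copy()
    K, R, _ = S.shape
    idx = {n: i for i, n in enumerate(samples.nodes)}

    clamped = np.zeros((R, len(samples.nodes)), dtype=bool)
    for r, rec in enumerate(data.records):
        for node in clamp_assignment(net, rec):
            clamped[r, idx[node]] = True

    readings = np.full((R, len(samples.nodes)), np.nan)
    for r, rec in enumerate(data.records):
        for node, v in rec.readings.items():
            if node in idx and v is not None and not (
                isinstance(v, float) and math.isnan(v)
            ):
                readings[r, idx[node]] = v

    finite = readings[np.isfinite(readings)]
    span = float(finite.max() - finite.min()) if finite.size else 1.0
    sigma_floor = max(1e-6 * span, 1e-9)

    out: dict[str, NodeParameters] = {}
    emissions: dict[str, tuple[float, float, float, float]] = {}

    # ---- emissions + label anchoring ------------------------------------
    for node in net.observed_nodes:
        i = idx[node]
        col = readings[:, i]
        have = np.isfinite(col)
        prev_pr = prev.get(node)
        if not have.any():
            if prev_pr is not None and prev_pr.has_emissions:
                emissions[node] = (
                    prev_pr.mu0, prev_pr.mu1, prev_pr.sigma0, prev_pr.sigma1
                )
            continue
        s = S[:, have, i].astype(float)          # (K, n_have)
        v = col[have][None, :]                   # broadcast over samples
        w1 = s.sum()
        w0 = s.size - w1
        if w1 < 1.0 or w0 < 1.0:
            warnings.warn(
                f"emission update degenerate for {node!r}; keeping previous",
                RuntimeWarning,
            )
            if prev_pr is not None and prev_pr.has_emissions:
                emissions[node] = (
                    prev_pr.mu0, prev_pr.mu1, prev_pr.sigma0, prev_pr.sigma1
                )
            else:
                m = float(v.mean())
                sd = max(float(v.std()), sigma_floor)
                emissions[node] = (m - sd, m + sd, sd, sd)
            continue
        mu1 = float((s * v).sum() / w1)
        mu0 = float(((1.0 - s) * v).sum() / w0)
        sg1 = max(math.sqrt(float((s * (v - mu1) ** 2).sum() / w1)), sigma_floor)
        sg0 = max(
            math.sqrt(float(((1.0 - s) * (v - mu0) ** 2).sum() / w0)), sigma_floor
        )
        if mu1 < mu0:
            mu0, mu1, sg0, sg1 = mu1, mu0, sg1, sg0
            free = ~clamped[:, i]
            S[:, free, i] = 1 - S[:, free, i]
        emissions[node] = (mu0, mu1, sg0, sg1)

    # ---- logistic CPDs ---------------------------------------------------
    for node in samples.nodes:
        if net.role(node).ligand:
            continue  # ligands are clamped by design; no conditional to fit
        i = idx[node]
        pa = net.parents(node)
        pidx = [idx[p] for p in pa]
        free = ~clamped[:, i]
        prev_pr = prev.get(node)
        em = emissions.get(node)

        def pack(beta0: float, betas: Mapping[str, float]) -> NodeParameters:
            if em is not None:
                return NodeParameters(
                    beta0, dict(betas), mu0=em[0], mu1=em[1], sigma0=em[2],
                    sigma1=em[3],
                )
            return NodeParameters(beta0, dict(betas))

        if not free.any():
            # node clamped in every record: nothing to learn
            if prev_pr is not None:
                out[node] = pack(prev_pr.beta0, prev_pr.betas)
            else:
                out[node] = pack(0.0, {p: 0.0 for p in pa})
            continue

        y = S[:, free, i].reshape(-1)
        if not pa:
            p_hat = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
            beta0 = float(np.clip(math.log(p_hat / (1 - p_hat)),
                                  -coef_bound, coef_bound))
            out[node] = pack(beta0, {})
            continue

        X = S[:, free, :][:, :, pidx].reshape(-1, len(pa))
        if y.min() == y.max():
            warnings.warn(
                f"degenerate states for {node!r} (all samples identical); "
                "keeping previous parameters",
                RuntimeWarning,
            )
            if prev_pr is not None:
                out[node] = pack(prev_pr.beta0, prev_pr.betas)
            else:
                beta0 = coef_bound if y[0] == 1 else -coef_bound
                out[node] = pack(beta0, {p: 0.0 for p in pa})
            continue

        rows, counts = np.unique(
            np.column_stack([X, y]), axis=0, return_counts=True
        )
        Xu = rows[:, :-1].astype(float)
        yu = rows[:, -1].astype(float)
        w = counts.astype(float) / K  # MC average: total weight = #records

        if use_lasso:
            # relaxed lasso: the L1 path proposes candidate supports, each
            # support is refitted without penalty, and BIC picks the support
            # (shrinkage-biased deviances would otherwise veto sparsity)
            n_eff = max(float(w.sum()), 2.0)
            supports: set[tuple[int, ...]] = {tuple(range(len(pa))), ()}
            for lam in lasso_grid:
                clf = _l1_logistic(C=1.0 / lam)
                clf.fit(Xu, yu, sample_weight=w)
                supports.add(
                    tuple(np.flatnonzero(np.abs(clf.coef_[0]) > zero_tol))
                )
            best = None
            for support in sorted(supports):
                coefs = np.zeros(len(pa))
                if support:
                    ref = _plain_logistic()
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        ref.fit(Xu[:, list(support)], yu, sample_weight=w)
                    coefs[list(support)] = np.clip(
                        ref.coef_[0], -coef_bound, coef_bound
                    )
                    b0_fit = float(
                        np.clip(ref.intercept_[0], -coef_bound, coef_bound)
                    )
                else:
                    p_hat = float(np.clip(np.average(yu, weights=w),
                                          1e-12, 1 - 1e-12))
                    b0_fit = float(np.clip(math.log(p_hat / (1 - p_hat)),
                                           -coef_bound, coef_bound))
                ll = _weighted_logistic_loglik(Xu, yu, w, b0_fit, coefs)
                bic = -2.0 * ll + (1 + len(support)) * math.log(n_eff)
                if best is None or bic < best[0]:
                    best = (bic, b0_fit, coefs)
            _, beta0, coefs = best  # type: ignore[misc]
        else:
            clf = _plain_logistic()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation convergence noise
                clf.fit(Xu, yu, sample_weight=w)
            beta0 = float(np.clip(clf.intercept_[0], -coef_bound, coef_bound))
            coefs = np.clip(clf.coef_[0], -coef_bound, coef_bound)

        out[node] = pack(beta0, dict(zip(pa, map(float, coefs))))

    return out


# ---------------------------------------------------------------------------
# observed-data likelihood (Monte Carlo forward estimate)
# ---------------------------------------------------------------------------


def mc_loglik(
    net: SignalingNetwork,
    params: Mapping[str, NodeParameters],
    data: ExperimentTable,
    n_samples: int = 300,
    rng_seed: int | Generator = 0,
    censor_floor: float | None = None,
) -> float:
    """Monte Carlo estimate of the observed-data log-likelihood.

    Joint states are forward-sampled from the clamped prior (ancestral
    sampling through the DAG), the emission likelihood of the readings is
    averaged over the draws per record, and the per-record log marginals are
    summed.
    """
    rng = rng_seed if isinstance(rng_seed, Generator) else default_rng(rng_seed)
    engine = _GibbsEngine(net, params, data, use_readings=True,
                          censor_floor=censor_floor)
    R = engine.n_rec
    n_nodes = len(engine.order)
    S = np.zeros((R, n_samples, n_nodes), dtype=np.int8)
    for i in range(n_nodes):  # topological order by construction
        pa = engine.pa_idx[i]
        if pa.size:
            eta = engine.b0[i] + S[:, :, pa] @ engine.bw[i]
        else:
            eta = np.full((R, n_samples), engine.b0[i])
        draw = (rng.random((R, n_samples)) < expit(eta)).astype(np.int8)
        cl = engine.clamped[:, i][:, None]
        S[:, :, i] = np.where(cl, engine.cval[:, i][:, None], draw)

    ll = np.zeros((R, n_samples))
    for node in net.observed_nodes:
        i = engine.index[node]
        col = engine.readings[:, i]
        have = np.isfinite(col)
        if not have.any():
            continue
        pr = params[node]
        l0 = np.array([
            _emission_logpdf(v, pr.mu0, pr.sigma0, censor_floor)
            for v in col[have]
        ])
        l1 = np.array([
            _emission_logpdf(v, pr.mu1, pr.sigma1, censor_floor)
            for v in col[have]
        ])
        s = S[have, :, i]
        ll[have] += np.where(s == 1, l1[:, None], l0[:, None])

    from scipy.special import logsumexp

    per_record = logsumexp(ll, axis=1) - math.log(n_samples)
    return float(per_record.sum())


# ---------------------------------------------------------------------------
# the EM driver
# ---------------------------------------------------------------------------


@dataclass
class MCEMConfig:
    """Tunables of the Monte Carlo EM fit."""

    n_sweeps: int = 700
    burn_in: int = 200
    max_iter: int = 30
    tol: float = 1e-3
    use_lasso: bool = True
    lasso_grid: tuple[float, ...] = (
        100.0, 50.0, 25.0, 12.0, 6.0, 3.0, 1.5, 0.75
    )
    coef_bound: float = 25.0
    n_loglik_samples: int = 300
    seed: int = 0
    censor_floor: float | None = None


@dataclass
class MCEMResult:
    params: dict[str, NodeParameters]
    loglik: float
    network: SignalingNetwork
    converged: bool
    n_iter: int
    trace: list[float]
    pruned_edges: tuple[tuple[str, str], ...]


def _initialize(
    net: SignalingNetwork, data: ExperimentTable
) -> dict[str, NodeParameters]:
    values: dict[str, list[float]] = {n: [] for n in net.observed_nodes}
    for rec in data.records:
        for node, v in rec.readings.items():
            if node in values and v is not None and not (
                isinstance(v, float) and math.isnan(v)
            ):
                values[node].append(float(v))
    params: dict[str, NodeParameters] = {}
    for node in net.nodes:
        if net.role(node).ligand:
            continue
        # canonical-pathway edges are believed activating a priori; start
        # from an OR-gate-like CPD so signal propagates from the first sweep
        betas = {p: 4.0 for p in net.parents(node)}
        if net.role(node).observed and values.get(node):
            v = np.array(values[node])
            med = np.median(v)
            lo = v[v <= med]
            hi = v[v > med]
            if hi.size == 0:  # constant readings
                mu0, mu1 = float(med) - 1.0, float(med) + 1.0
                sg0 = sg1 = 1.0
            else:
                mu0, mu1 = float(lo.mean()), float(hi.mean())
                sg0 = max(float(lo.std()), 1e-3)
                sg1 = max(float(hi.std()), 1e-3)
            params[node] = NodeParameters(
                -2.0, betas, mu0=mu0, mu1=mu1, sigma0=sg0, sigma1=sg1
            )
        else:
            params[node] = NodeParameters(-2.0, betas)
    return params


def count_parameters(
    net: SignalingNetwork, params: Mapping[str, NodeParameters]
) -> int:
    """Free parameters: intercept + one coefficient per retained edge per
    non-ligand node, plus (mu, sigma) x 2 states per observed node."""
    k = 0
    for node in net.nodes:
        if net.role(node).ligand:
            continue
        k += 1 + len(net.parents(node))
        pr = params.get(node)
        if pr is not None and pr.has_emissions:
            k += 4
    return k


def _prune_zeroed_edges(
    net: SignalingNetwork, params: Mapping[str, NodeParameters]
) -> tuple[SignalingNetwork, dict[str, NodeParameters], tuple]:
    protected = net.ligand_receptor_edges()
    removed: list[tuple[str, str]] = []
    pruned = net
    for child in net.nodes:
        pr = params.get(child)
        if pr is None:
            continue
        for parent, b in list(pr.betas.items()):
            if b == 0.0 and (parent, child) not in protected:
                if pruned.has_edge(parent, child):
                    pruned = pruned.with_edge_removed(parent, child)
                    removed.append((parent, child))
    new_params: dict[str, NodeParameters] = {}
    for node, pr in params.items():
        keep = {p: b for p, b in pr.betas.items() if pruned.has_edge(p, node)}
        new_params[node] = replace(pr, betas=keep)
    return pruned, new_params, tuple(removed)


def fit_mcem(
    net: SignalingNetwork,
    data: ExperimentTable,
    config: MCEMConfig | None = None,
) -> MCEMResult:
    """Fit the latent-state network by Monte Carlo EM.

    Alternates the Gibbs E-step and the M-step until the relative change of
    the Monte Carlo observed-data log-likelihood drops below ``tol`` (or
    ``max_iter`` is hit); the stopping iteration is refitted with the L1
    penalty when ``use_lasso``, exactly-zeroed coefficients delete their
    edges (ligand->receptor edges are exempt), and the converged likelihood
    is recomputed on the pruned structure.  Non-convergence returns the best
    iterate flagged, never an exception.
    """
    cfg = config or MCEMConfig()
    data.validate_against(net)
    rng = default_rng(SeedSequence(cfg.seed))
    params = _initialize(net, data)
    trace: list[float] = []
    prev_ll: float | None = None
    converged = False
    pruned_net = net
    pruned_edges: tuple = ()
    ll = -math.inf
    n_iter = 0

    for it in range(1, cfg.max_iter + 1):
        n_iter = it
        samples = gibbs_e_step(
            net, params, data, cfg.n_sweeps, cfg.burn_in, rng,
            censor_floor=cfg.censor_floor,
        )
        params = m_step(
            net, samples, data, use_lasso=False, coef_bound=cfg.coef_bound,
            prev=params,
        )
        ll = mc_loglik(
            net, params, data, cfg.n_loglik_samples, rng,
            censor_floor=cfg.censor_floor,
        )
        trace.append(ll)
        log.debug("MCEM iter %d: loglik %.4f", it, ll)
        converged = math.isinf(cfg.tol) or (
            prev_ll is not None
            and abs(ll - prev_ll) <= cfg.tol * max(abs(prev_ll), 1e-12)
        )
        if converged or it == cfg.max_iter:
            if cfg.use_lasso:
                params = m_step(
                    net, samples, data, use_lasso=True,
                    lasso_grid=cfg.lasso_grid, coef_bound=cfg.coef_bound,
                    prev=params,
                )
                pruned_net, params, pruned_edges = _prune_zeroed_edges(net, params)
                ll = mc_loglik(
                    pruned_net, params, data, cfg.n_loglik_samples, rng,
                    censor_floor=cfg.censor_floor,
                )
                trace.append(ll)
            break
        prev_ll = ll

    if not converged:
        log.warning("MCEM did not converge within %d iterations", cfg.max_iter)
    return MCEMResult(
        params=params,
        loglik=ll,
        network=pruned_net,
        converged=converged,
        n_iter=n_iter,
        trace=trace,
        pruned_edges=pruned_edges,
    )


def record_stream_seed(base_seed: int, record: Record, occurrence: int = 0) -> SeedSequence:
    """Content-derived seed for one record's private random stream.

    Hashing the record's clamps (not its position) makes downstream Monte
    Carlo output invariant to the order of condition records; ``occurrence``
    separates byte-identical duplicates.
    """
    payload = "|".join(
        (
            str(record.condition),
            repr(float(record.time)),
            ",".join(sorted(record.stimuli)),
            ",".join(sorted(record.inhibited)),
            str(occurrence),
        )
    ).encode()
    return SeedSequence([int(base_seed) & 0x7FFFFFFF, zlib.crc32(payload)])
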