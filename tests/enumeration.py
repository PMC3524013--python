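"""Independent brute-force oracles for small latent-state networks.

Everything here recomputes probabilities from the model definition with
plain ``math`` over exhaustively enumerated joint states; it never calls the
package's samplers or conditionals, so it can serve as ground truth for
them.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _normal_pdf(v: float, mu: float, sigma: float) -> float:
    z = (v - mu) / sigma
    return math.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))


def joint_distribution(
    net,
    params: Mapping,
    clamps: Mapping[str, int],
    readings: Mapping[str, float] | None = None,
) -> tuple[list[str], dict[tuple[int, ...], float]]:
    """Exact joint over unclamped nodes given clamps (interventions) and
    optional readings.  Returns (free node order, {state tuple: prob})."""
    order = list(net.topological_order())
    free = [n for n in order if n not in clamps]
    readings = readings or {}
    weights: dict[tuple[int, ...], float] = {}
    for assignment in itertools.product((0, 1), repeat=len(free)):
        st = dict(clamps)
        st.update(zip(free, assignment))
        w = 1.0
        for node in order:
            if node in clamps:
                continue  # clamping is an intervention: its factor is cut
            pr = params[node]
            eta = pr.beta0 + sum(
                pr.betas[p] * st[p] for p in net.parents(node)
            )
            p1 = _logistic(eta)
            w *= p1 if st[node] == 1 else 1.0 - p1
        for node, v in readings.items():
            pr = params[node]
            if st[node] == 1:
                w *= _normal_pdf(v, pr.mu1, pr.sigma1)
            else:
                w *= _normal_pdf(v, pr.mu0, pr.sigma0)
        weights[assignment] = w
    total = sum(weights.values())
    return free, {k: v / total for k, v in weights.items()}


def marginals(
    net, params, clamps, readings=None
) -> dict[str, float]:
    """Exact activation marginal p(s=1 | clamps, readings) per free node."""
    free, joint = joint_distribution(net, params, clamps, readings)
    out = {n: 0.0 for n in free}
    for state, p in joint.items():
        for n, s in zip(free, state):
            if s == 1:
                out[n] += p
    return out


def conditional_of_node(
    net, params, clamps, node, others: Mapping[str, int], readings=None
) -> float:
    """Exact p(s_node = 1 | all other free nodes fixed at ``others``)."""
    free, joint = joint_distribution(net, params, clamps, readings)
    i = free.index(node)
    num = den = 0.0
    for state, p in joint.items():
        if all(state[free.index(k)] == v for k, v in others.items()):
            den += p
            if state[i] == 1:
                num += p
    return num / den


def total_variation(
    empirical: Mapping[tuple, float], exact: Mapping[tuple, float]
) -> float:
    keys = set(empirical) | set(exact)
    return 0.5 * sum(
        abs(empirical.get(k, 0.0) - exact.get(k, 0.0)) for k in keys
    )


def empirical_joint(samples, free_indices) -> dict[tuple, float]:
    """Empirical distribution of the given state columns from an array of
    joint samples (n_samples, n_nodes)."""
    counts: dict[tuple, int] = {}
    for row in samples:
        key = tuple(int(row[i]) for i in free_indices)
        counts[key] = counts.get(key, 0) + 1
    n = len(samples)
    return {k: c / n for k, c in counts.items()}
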