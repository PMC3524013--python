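"""Readout prediction under new stimulus/inhibitor conditions.

Given a fitted network, each design record (clamps, no readings) is completed
by sampling joint activation states from the model's posterior, and each
retained joint sample draws a fluorescence value for every observed node from
its fitted emission component; the prediction is the mean of those draws,
with the across-sample SD as a Monte Carlo error bar.

With no readings attached to a record, the posterior over states given the
clamps factorizes along the DAG, so ancestral (topological forward) sampling
draws *exact*, independent posterior samples -- unlike a single Gibbs chain,
which can mix arbitrarily slowly between the near-deterministic modes of a
strongly parameterized cascade.  Prediction therefore uses ancestral
sampling; the Gibbs machinery is reserved for records carrying evidence.

Every record gets a private random stream seeded from its *content*, so
predictions are bit-reproducible and invariant to the order of the records.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.special import expit

from .mcem import (
    ExperimentTable,
    NodeParameters,
    _GibbsEngine,
    record_stream_seed,
)
from .network import SignalingNetwork

__all__ = ["predict", "evaluate_predictions"]


def predict(
    net: SignalingNetwork,
    params: Mapping[str, NodeParameters],
    conditions: ExperimentTable,
    n_samples: int = 50,
    rng_seed: int = 0,
    analytic: bool = False,
) -> pd.DataFrame:
    """Predict observed-node readouts for each design record.

    Returns a DataFrame with columns ``condition, time, protein, predicted,
    sd``.  ``analytic=True`` averages the state-conditional means mu_s
    instead of drawing noisy signals (a lower-variance alternative to the
    default mixture draw).
    """
    design = conditions.without_readings()
    design.validate_against(net)
    for node in net.observed_nodes:
        pr = params.get(node)
        if pr is None or not pr.has_emissions:
            raise ValueError(f"missing emission parameters for observed {node!r}")

    # engine reused only for its per-record clamp matrices and CPD arrays
    engine = _GibbsEngine(net, params, design, use_readings=False)
    obs = list(net.observed_nodes)
    R = len(design.records)
    n_nodes = len(engine.order)

    # per-record private streams, keyed on record content
    uniforms = np.empty((R, n_samples, n_nodes))
    noise = np.empty((R, n_samples, len(obs)))
    seen: Counter = Counter()
    for r, rec in enumerate(design.records):
        key = (rec.condition, rec.time, rec.stimuli, rec.inhibited)
        ss = record_stream_seed(rng_seed, rec, occurrence=seen[key])
        seen[key] += 1
        rng_r = default_rng(ss)
        uniforms[r] = rng_r.random((n_samples, n_nodes))
        noise[r] = rng_r.standard_normal((n_samples, len(obs)))

    # exact posterior draws by ancestral sampling (topological order)
    S = np.zeros((R, n_samples, n_nodes), dtype=np.int8)
    for i in range(n_nodes):
        pa = engine.pa_idx[i]
        if pa.size:
            eta = engine.b0[i] + S[:, :, pa] @ engine.bw[i]
        else:
            eta = np.full((R, n_samples), engine.b0[i])
        draw = (uniforms[:, :, i] < expit(eta)).astype(np.int8)
        cl = engine.clamped[:, i][:, None]
        S[:, :, i] = np.where(cl, engine.cval[:, i][:, None], draw)

    rows = []
    for oi, node in enumerate(obs):
        pr = params[node]
        s = S[:, :, engine.index[node]]             # (R, n_samples)
        mu = np.where(s == 1, pr.mu1, pr.mu0)
        if analytic:
            vals = mu
        else:
            sigma = np.where(s == 1, pr.sigma1, pr.sigma0)
            vals = mu + sigma * noise[:, :, oi]
        pred = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1) if n_samples > 1 else np.zeros(R)
        for r, rec in enumerate(design.records):
            rows.append(
                {
                    "condition": rec.condition,
                    "time": rec.time,
                    "protein": node,
                    "predicted": float(pred[r]),
                    "sd": float(sd[r]),
                }
            )
    df = pd.DataFrame(rows, columns=["condition", "time", "protein", "predicted", "sd"])
    return df.sort_values(["condition", "time", "protein"], kind="stable").reset_index(
        drop=True
    )


def evaluate_predictions(
    predictions: pd.DataFrame, truth: ExperimentTable
) -> dict[str, float]:
    """Sum of squared errors and squared Pearson correlation against a truth
    table, matched on (condition, time, protein)."""
    truth_rows = []
    for rec in truth.records:
        for node, v in rec.readings.items():
            truth_rows.append(
                {
                    "condition": rec.condition,
                    "time": rec.time,
                    "protein": node,
                    "observed": float(v),
                }
            )
    tdf = pd.DataFrame(truth_rows)
    merged = predictions.merge(tdf, on=["condition", "time", "protein"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping (condition, time, protein) entries")
    err = merged["predicted"] - merged["observed"]
    r = np.corrcoef(merged["predicted"], merged["observed"])[0, 1]
    return {
        "sse": float(np.sum(err**2)),
        "r2": float(r**2),
        "n": int(len(merged)),
    }
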