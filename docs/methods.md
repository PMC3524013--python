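# Methods

## The model

`ofbn` fits a Bayesian network to cue–signal–response phosphoproteomics
screens.  Nodes are proteins of a canonical signaling pathway; a directed
edge means the parent kinase influences the child's phosphorylation.  Each
node `i` carries a binary latent activation state `s_i`.  Three mechanisms
connect the graph to data:

1. **Propagation.**  Given its parents' states, a node activates through a
   logistic conditional,
   `p(s_i = 1 | pa(i)) = logistic(beta_i0 + sum_j beta_ij s_j)`.
   Positive `beta_ij` is activation, negative is inhibition; the intercept
   sets the node's baseline.
2. **Emission.**  An observed node additionally emits a fluorescence
   reading from a two-component Gaussian mixture over its state:
   `v_i | s_i = k ~ N(mu_ik, sigma_ik)`, with the convention that the
   phosphorylated state is the brighter one (`mu_i1 >= mu_i0`).
3. **Clamping.**  The experimental design fixes states by intervention: a
   stimulated ligand is active, a non-stimulated ligand inactive, an
   inhibited kinase inactive.  Intervention semantics means a clamped
   node's own conditional is removed from the joint — evidence about an
   inhibited kinase never flows backwards to its parents.

Each (condition, time) row of the measurement table is treated as one
i.i.d. observation of this static network; no temporal dynamics are
modeled.

## Fitting: Monte Carlo EM

The latent states are integrated out by Monte Carlo EM:

* **E-step.**  A systematic-scan Gibbs sampler updates every unclamped node
  in topological order from its Markov-blanket full conditional (the
  node's own logistic prior, times the likelihood of each unclamped
  child's state, times the emission density when a reading is present).
  All records are updated in parallel with vectorized sweeps.  Each
  iteration's chain is initialized by thresholding readings at their
  per-node median and forward-sampling the remaining nodes from the
  *current* conditionals.
* **M-step.**  Per node, a logistic regression of the sampled child states
  on the sampled parent states (records with the child clamped are
  excluded; Monte Carlo samples are weight-normalized so the effective
  sample size equals the number of records).  Per observed node, emission
  means and SDs are state-weighted moments of the readings, with label
  anchoring: if the fitted "active" component is dimmer than the
  "inactive" one, the components are swapped and the node's sampled states
  flipped.  Sigmas are floored at `1e-6` of the reading range.
* **Convergence.**  The observed-data log-likelihood is estimated by
  ancestral (forward) Monte Carlo sampling of states under the clamps,
  averaging the emission likelihood per record.  The EM loop stops when
  its relative change drops below `tol` (default `1e-3`) or after
  `max_iter` iterations; the stopping iteration's M-step is repeated with
  an L1 penalty (below), and coefficients shrunk exactly to zero delete
  their edges from the returned structure.  Ligand→receptor edges are
  exempt from deletion.

Defaults: 700 sweeps with 200 burn-in, `max_iter` 30, coefficient cap ±25
(perfect separation on sampled binary data is routine; the cap records
"saturating" rather than diverging), 300 forward samples for the
likelihood estimate.

### Initialization

Canonical-pathway edges are believed activating a priori, so all
coefficients start at an OR-gate-like `beta = 4`, `beta0 = -2`, and
emission components start from a median split of each node's readings.
A deliberately weak start (`beta ≈ 1`, `beta0 = 0`) leaves the hidden
states near coin flips, the M-step then reproduces the weak coupling, and
EM settles in a non-informative fixed point; the opinionated start lets
evidence propagate from the first sweep.  This is the one place where the
fit encodes a biological prior beyond the graph itself.

### Final-round L1 (relaxed lasso)

The last M-step uses an L1-penalized logistic fit per node to decide which
edges the data cannot support.  Penalized deviances are biased against
sparse solutions (by the time the spurious coefficient reaches zero the
true ones are badly shrunk), so the implementation uses the *relaxed*
form: the L1 path over a geometric grid of penalty weights proposes
candidate supports, each support is refitted without penalty, and BIC over
the refits selects the support.  Zeroed coefficients mark their edges for
deletion.

A caveat found while validating: an irrelevant edge between two *hidden*
nodes is generally not removable this way, because EM co-adapts the weakly
identified hidden states to the extra parent until it is genuinely
predictive in the completed data.  Removing such edges is the job of the
structure search (deletion moves plus cross-candidate BIC), not of the
within-model penalty.

## Structure search

Candidate structures grow from the canonical network by chains of
single-edge moves.  A move flips a fair coin between addition and
deletion; the unordered pair is sampled from the similarity prior —
addition probability is the pair's ascending similarity rank over the sum
of ranks, deletion probability the descending analogue (average ranks for
ties, missing pairs scored 0) — and is rejected and redrawn while illegal.
Biological legality: nothing may point at a ligand, ligands only feed
receptors, receptor–receptor edges are forbidden, ligand→receptor edges
are never deleted, and every move must keep the graph acyclic.  An added
pair is oriented to preserve acyclicity, uniformly at random when both
directions are legal.  When one move type is exhausted the other is used;
when neither is possible the search reports saturation.

Each of `n_candidates` chains (default 50) branches independently from the
canonical network with its own seeded stream and applies `n_moves` moves
(default 10).  Every candidate is fitted by MCEM, pruned in its final
round, and scored by `BIC = -2 loglik + k log n`, where `k` counts one
intercept plus one coefficient per retained edge per non-ligand node plus
four emission parameters per observed node, and `n` is the number of
records.  The minimum-BIC candidate is returned.

Because BIC rewards parsimony, the selected structure is typically
*sparser* than the generating truth when parallel paths are redundant —
the same behavior seen in real screens, where the selected pathway dropped
a fifth of the canonical edges.

## Prediction

For a new stimulus/inhibitor design without readings the posterior over
states given the clamps factorizes along the DAG, so the package draws
exact, independent joint states by ancestral sampling (a single Gibbs
chain, in contrast, mixes arbitrarily slowly between the near-deterministic
modes of a strong cascade; this was measurable as a collapse of predictive
correlation).  Each of `n_samples` (default 50) joint draws then emits a
signal for every observed protein from its fitted Gaussian component; the
prediction is the mean of those draws and the reported `sd` their spread.
The analytic mixture mean `sum_s p(s) mu_s` is available as an option.

Every record's draws come from a private stream seeded by the record's
*content* (condition, time, clamps), so predictions are bit-reproducible
and invariant to row order; byte-identical duplicate rows get separate
streams so replicate predictions remain independent.

The collapsed network reported alongside the fit projects the structure
onto its non-hidden nodes: `u -> w` iff a directed path runs from `u` to
`w` through hidden interior nodes only.  The projection is idempotent.

## The synthetic-data generator

`generate_scenario` builds everything the pipeline consumes, so all
studies run without any external data:

* **Topology.**  A layered DAG: ligands → one receptor each → hidden
  kinase layers (width ≈ 5) → observed leaves; every layer node has 1–2
  parents (leaves 1–3) and every node at least one child.  Optional
  cross-layer shortcuts (`skip_edges`).
* **Parameters.**  Edge magnitudes uniform in `effect_range`, all
  activating by default (`neg_edge_frac` adds inhibitory edges; note that
  the sign of a coefficient incident to a hidden node is only identifiable
  up to that node's label flip, so recovery studies keep cascades
  activation-only).  Intercepts follow an OR-gate rule,
  `beta0 = -0.5 min(positive beta)`: any single active parent activates
  the child, the all-off baseline stays off.  A sum-based intercept makes
  multi-parent nodes noisy majority gates and the cascade decays into coin
  flips within a few layers — the opposite of the near-Boolean regime real
  fits exhibit (coefficients up to ~50).
* **Design.**  A balanced screen: conditions cycle through an
  unstimulated control and each single ligand, with ligand pairs
  interleaved and inhibitors rotating over alternate conditions, each
  condition at 3 time points.  (An unbalanced random design leaves
  OR-hub proteins nearly constant and makes a screen's information content
  a lottery.)  The default preset is 4 ligands, 20 hidden nodes, 7
  observed proteins, 25 conditions × 3 time points = 75 records.
* **Readings.**  States forward-sampled per record under the clamps;
  readings `N(mu_s, noise_sd)` with `mu1 - mu0 = emission_gap` (defaults
  1000 and 200), optionally truncated at a detector floor (300).
* **Similarity.**  True-edge pairs score `Beta(5,2)`, all other pairs
  `Beta(2,5)` — overlapping but separated, so guidance helps without
  trivializing the search.  `inject_noise_edges` adds random legal edges
  whose similarity is forced to exactly 0 (never ligand→receptor, which
  the legality rules would make permanently undeletable).

What the generator does *not* emulate: temporal dynamics, feedback loops,
partial phosphorylation (graded states), batch effects, or heteroscedastic
detector noise.  Passing the studies therefore shows the estimator is
correct and well-behaved under its own assumptions, not that those
assumptions hold for any particular real dataset.

## Reference studies and their conditions

`ofbn.studies` freezes one set of study conditions per claim
(`scripts/acceptance.py` re-runs all of them):

* **Sampler exactness** — all four layered nets with ≤ 6 nodes, 20 random
  parameterizations, half with readings; 500 identically-clamped records
  run as parallel Gibbs chains (60 retained sweeps each after 250
  burn-in), giving ≥ 30k retained samples per check, against exhaustive
  enumeration.  Also the worst `p0 + p1 - 1` defect of the full
  conditionals.
* **Parameter recovery** — 100 replicate screens at the small-screen
  conditions (75 records, `|beta|` in [2, 6], gap/noise = 5), fitting the
  true structure.  Summaries: coefficient sign agreement, and the *median*
  relative error of emission means.  The median is the right summary at
  these conditions: with ~37 records per state the oracle that knows the
  true states has a standard error of `sigma/sqrt(n0) ≈ 33` fluorescence
  units, larger than 5 % of a 400-unit baseline, so no estimator can put
  every mean within 5 %; the fitted medians track the oracle's.
* **L1 pruning** — 100 replicates of the M-step-level simulation: i.i.d.
  parent states, child drawn from a known logistic CPD with three strong
  parents and one null parent, n = 200.
* **Guidance value** — one fixed screen (3 ligands, 6 hidden, 4 observed,
  6 low-similarity decoy edges, 60 records, steep gates); 30 paired
  restarts of 10-move single-chain searches with similarity-guided vs
  uniform move priors; one-sided Wilcoxon signed-rank on converged
  log-likelihoods.  (Shorter chains carry only ~3 deletions each, so the
  two arms barely differ and the comparison is underpowered.)
* **Noise elimination** — 5 zero-similarity edges injected into a clean
  canonical network; 20 runs of a 5-candidate, 70-move search.  The move
  budget matters: covering five specific edges takes ≈ 14 deletions in
  expectation, so short chains fail for combinatorial reasons unrelated to
  guidance.
* **Prediction fidelity** — three replicate 7-protein screens with steep
  gates (`effect_range` (12, 20)) and gap/noise = 10, chosen so the
  *Bayes-optimal* predictor (true parameters) attains r² ≈ 0.9–0.96;
  the study then reports the median fitted r² over 150-record training /
  40-held-out-condition splits, so it measures estimation quality rather
  than a single draw's irreducible ceiling.  Also the slope of log
  prediction-SD vs log sample count (expected −1/2), measured across 40
  duplicated records with independent streams.
* **Structural invariants** — collapse vs a path-enumeration oracle and
  idempotence on 50 random DAGs; DAG-ness and ligand→receptor retention
  along 20-move proposal chains.

## Numerical choices and degenerate inputs

* Conditionals are computed in log-odds form with `log1p(exp(·))`
  softplus; normalization holds to machine precision by construction.
* Logistic fits run on deduplicated design rows with multiplicity
  weights, which bounds the fit cost by `2^(parents+1)` rows per node.
* Degenerate M-step inputs (a node sampled constant, an emission component
  with no assigned mass) keep the previous iteration's parameters and
  warn.
* Missing readings are treated as hidden for that record.  Readings below
  a detector floor can optionally be treated as left-censored
  (`censor_floor`), replacing the emission density by the component CDF at
  the floor during state sampling and likelihood estimation; parameter
  updates still use the recorded values.
* Non-convergence at `max_iter` returns the best iterate with
  `converged=False`, never an exception; a candidate whose fit raises is
  dropped from the search pool with a warning.

## Known limitations

* Hidden-state label symmetry: coefficients incident to hidden nodes are
  recovered up to each hidden node's label flip unless an observed
  descendant anchors it; the activating-edge prior in the initialization
  resolves the gauge in practice but inhibitory edges into deep hidden
  nodes remain non-identifiable.
* The within-model L1 step cannot remove irrelevant hidden–hidden edges
  (state co-adaptation); only the search can.
* Single-site Gibbs mixes slowly in near-deterministic regimes; fitting
  compensates with evidence-anchored initialization, and prediction avoids
  the issue entirely via exact ancestral sampling, but E-step accuracy for
  *strongly* coupled fits with sparse evidence is the weakest link.
* BIC with the forward Monte Carlo likelihood is noisy; candidate
  selection between near-tied structures can flip with the likelihood
  seed.  Increase `n_loglik_samples` when ranking close candidates.
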