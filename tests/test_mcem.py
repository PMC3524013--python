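"""Latent-state model: conditionals, Gibbs E-step, M-step, MCEM driver."""

import math

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm, spearmanr

from ofbn import (
    ExperimentTable,
    MCEMConfig,
    NodeParameters,
    NodeRole,
    Record,
    SignalingNetwork,
    clamp_assignment,
    fit_mcem,
    full_conditional,
    generate_scenario,
    gibbs_e_step,
    hidden_full_conditional,
    logistic_activation,
    m_step,
    mc_loglik,
    observed_full_conditional,
)
from ofbn.mcem import StateSamples

from conftest import single_record_table
from enumeration import conditional_of_node, marginals


class TestLogisticActivation:
    def test_logistic_at_zero(self):
        assert logistic_activation(NodeParameters(0.0), {}) == 0.5

    def test_closed_form_quarter(self):
        p = logistic_activation(NodeParameters(-math.log(3.0), {"a": 2.0}),
                                {"a": 0})
        assert p == pytest.approx(0.25, abs=1e-12)

    def test_saturating_coefficient(self):
        # a very large activating weight drives the child essentially to 1
        p = logistic_activation(NodeParameters(0.0, {"a": 53.12}), {"a": 1})
        assert 1.0 - p < 1e-20

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            logistic_activation(NodeParameters(0.0, {"a": 1.0}), {})
        with pytest.raises(ValueError):
            logistic_activation(NodeParameters(0.0, {"a": 1.0}), [1, 0])


def chain_params():
    return {
        "R": NodeParameters(-1.0, {"L": 3.0}),
        "H": NodeParameters(0.5, {"R": -2.0}),
        "P": NodeParameters(-0.5, {"H": 2.5}, mu0=300.0, mu1=900.0,
                            sigma0=100.0, sigma1=150.0),
    }


class TestFullConditionals:
    def test_leaf_with_inactive_parent_is_prior(self, chain_net):
        params = chain_params()
        params["P"] = NodeParameters(0.0, {"H": 2.0}, mu0=300.0, mu1=900.0,
                                     sigma0=100.0, sigma1=100.0)
        states = {"L": 1, "R": 1, "H": 0, "P": 0}
        assert hidden_full_conditional(chain_net, params, states, "P") == 0.5

    def test_child_with_zero_coupling_reduces_to_prior(self, chain_net):
        params = chain_params()
        params["P"] = NodeParameters(1.2, {"H": 0.0}, mu0=300.0, mu1=900.0,
                                     sigma0=100.0, sigma1=100.0)
        states = {"L": 1, "R": 1, "H": 0, "P": 1}
        got = hidden_full_conditional(chain_net, params, states, "H")
        prior_only = logistic_activation(params["H"], {"R": 1})
        assert got == pytest.approx(prior_only, abs=1e-12)

    def test_identical_emissions_cancel(self, chain_net):
        params = chain_params()
        params["P"] = NodeParameters(-0.5, {"H": 2.5}, mu0=600.0, mu1=600.0,
                                     sigma0=120.0, sigma1=120.0)
        states = {"L": 1, "R": 1, "H": 1, "P": 0}
        with_reading = observed_full_conditional(
            chain_net, params, states, "P", reading=580.0
        )
        without = hidden_full_conditional(chain_net, params, states, "P")
        assert with_reading == pytest.approx(without, abs=1e-12)

    def test_dominant_reading_pins_state(self, chain_net):
        params = chain_params()
        states = {"L": 0, "R": 0, "H": 0, "P": 0}
        p = observed_full_conditional(
            chain_net, params, states, "P", reading=900.0
        )
        assert p > 0.99

    def test_missing_reading_treated_as_hidden(self, chain_net):
        params = chain_params()
        states = {"L": 1, "R": 1, "H": 1, "P": 0}
        assert observed_full_conditional(
            chain_net, params, states, "P", reading=None
        ) == hidden_full_conditional(chain_net, params, states, "P")
        assert observed_full_conditional(
            chain_net, params, states, "P", reading=float("nan")
        ) == hidden_full_conditional(chain_net, params, states, "P")

    def test_clamped_query_rejected(self, chain_net):
        params = chain_params()
        states = {"L": 1, "R": 0, "H": 0, "P": 0}
        with pytest.raises(ValueError):
            full_conditional(chain_net, params, states, "H", clamped={"H"})

    @pytest.mark.parametrize("seed", range(6))
    def test_normalization_and_enumeration_agreement(self, seed, chain_net):
        """p(0|MB) + p(1|MB) = 1 to 1e-12, and the conditional matches the
        exhaustively enumerated joint, with and without a reading."""
        rng = np.random.default_rng(seed)
        params = {
            n: NodeParameters(
                float(rng.normal(0, 1)),
                {p: float(rng.normal(0, 2)) for p in chain_net.parents(n)},
                **(
                    dict(mu0=400.0, mu1=900.0, sigma0=150.0, sigma1=180.0)
                    if n == "P"
                    else {}
                ),
            )
            for n in ("R", "H", "P")
        }
        clamps = {"L": int(rng.random() < 0.5)}
        states = {
            n: int(rng.random() < 0.5) for n in chain_net.nodes
        }
        states.update(clamps)
        reading = float(rng.uniform(200, 1100))
        # latent nodes: conditional given everything else, no emission term
        for node in ("R", "H"):
            p0, p1 = full_conditional(
                chain_net, params, states, node, clamped=clamps
            )
            assert p0 + p1 == pytest.approx(1.0, abs=1e-12)
            others = {
                n: states[n]
                for n in chain_net.nodes
                if n != node and n not in clamps
            }
            exact = conditional_of_node(chain_net, params, clamps, node, others)
            assert p1 == pytest.approx(exact, abs=1e-9)
        # observed leaf: the emission likelihood of its reading enters
        others = {
            n: states[n]
            for n in chain_net.nodes
            if n != "P" and n not in clamps
        }
        p0, p1 = full_conditional(
            chain_net, params, states, "P", reading=reading, clamped=clamps
        )
        assert p0 + p1 == pytest.approx(1.0, abs=1e-12)
        exact = conditional_of_node(
            chain_net, params, clamps, "P", others, readings={"P": reading}
        )
        assert p1 == pytest.approx(exact, abs=1e-9)


class TestGibbs:
    def test_all_clamped_nodes_stay_clamped(self):
        roles = {"L1": NodeRole(ligand=True), "L2": NodeRole(ligand=True),
                 "K": NodeRole(inhibitable=True)}
        net = SignalingNetwork(roles, [("L1", "K"), ("L2", "K")])
        params = {"K": NodeParameters(0.0, {"L1": 2.0, "L2": 2.0})}
        table = ExperimentTable(
            [Record("c0", 0.0, stimuli=frozenset({"L1"}),
                    inhibited=frozenset({"K"}))]
        )
        samples = gibbs_e_step(net, params, table, n_sweeps=50, burn_in=10,
                               rng_seed=0)
        i = {n: k for k, n in enumerate(samples.nodes)}
        assert (samples.states[:, 0, i["L1"]] == 1).all()
        assert (samples.states[:, 0, i["L2"]] == 0).all()
        assert (samples.states[:, 0, i["K"]] == 0).all()

    def test_seed_determinism(self, chain_net):
        params = chain_params()
        table = single_record_table(3, readings={"P": 700.0})
        a = gibbs_e_step(chain_net, params, table, 80, 20, rng_seed=42)
        b = gibbs_e_step(chain_net, params, table, 80, 20, rng_seed=42)
        assert (a.states == b.states).all()
        c = gibbs_e_step(chain_net, params, table, 80, 20, rng_seed=43)
        assert (c.states != a.states).any()

    def test_chain_marginals_match_enumeration(self, chain_net):
        """Long-run Gibbs marginals on the 4-node chain agree with exact
        enumeration within 0.02 (reading attached to the leaf)."""
        params = chain_params()
        reading = 640.0
        table = single_record_table(64, stimuli=("L",),
                                    readings={"P": reading})
        samples = gibbs_e_step(chain_net, params, table, 350, 100,
                               rng_seed=9)
        exact = marginals(chain_net, params, {"L": 1},
                          readings={"P": reading})
        for node, target in exact.items():
            i = samples.nodes.index(node)
            got = samples.states[:, :, i].mean()
            assert got == pytest.approx(target, abs=0.02)

    def test_sweep_validation(self, chain_net):
        with pytest.raises(ValueError):
            gibbs_e_step(chain_net, chain_params(),
                         single_record_table(1), 10, 10)


class TestMStep:
    def _design_table(self, n):
        return ExperimentTable([Record(f"r{i}", 0.0) for i in range(n)])

    def _samples_from(self, net, arrays):
        order = net.topological_order()
        S = np.stack([arrays[n] for n in order], axis=-1)[None, :, :]
        return StateSamples(S.astype(np.int8), tuple(order))

    def test_separation_capped(self):
        roles = {"A": NodeRole(), "B": NodeRole()}
        net = SignalingNetwork(roles, [("A", "B")])
        rng = np.random.default_rng(0)
        a = (rng.random(300) < 0.5).astype(np.int8)
        samples = self._samples_from(net, {"A": a, "B": a})  # perfect copy
        params = m_step(net, samples, self._design_table(300),
                        coef_bound=25.0)
        assert abs(params["B"].betas["A"]) <= 25.0 + 1e-9
        assert params["B"].betas["A"] > 10.0  # ran to the cap, not to zero

    def test_sign_recovery_on_simulated_states(self):
        """Unpenalized M-step recovers coefficient signs from states
        simulated at known beta (20 replicates, |beta| in [2, 6])."""
        roles = {"X0": NodeRole(), "X1": NodeRole(), "Y": NodeRole()}
        net = SignalingNetwork(roles, [("X0", "Y"), ("X1", "Y")])
        rng = np.random.default_rng(5)
        hits = total = 0
        for _ in range(20):
            betas = rng.uniform(2, 6, 2) * rng.choice([-1, 1], 2)
            X = (rng.random((200, 2)) < 0.5).astype(np.int8)
            eta = -0.5 * betas.sum() + X @ betas
            y = (rng.random(200) < expit(eta)).astype(np.int8)
            samples = self._samples_from(
                net, {"X0": X[:, 0], "X1": X[:, 1], "Y": y}
            )
            params = m_step(net, samples, self._design_table(200))
            for j, name in enumerate(("X0", "X1")):
                total += 1
                hits += (params["Y"].betas[name] > 0) == (betas[j] > 0)
        assert hits / total >= 0.95

    def test_lasso_zeroes_spurious_parent(self):
        """L1 M-step zeroes a parent with no true effect in most replicates
        while keeping all strong true parents."""
        roles = {f"X{j}": NodeRole() for j in range(3)}
        roles.update({"Xs": NodeRole(), "Y": NodeRole()})
        net = SignalingNetwork(
            roles, [(f"X{j}", "Y") for j in range(3)] + [("Xs", "Y")]
        )
        rng = np.random.default_rng(17)
        zeroed = kept = 0
        n_rep = 25
        for _ in range(n_rep):
            betas = rng.uniform(2, 6, 3)
            X = (rng.random((200, 4)) < 0.5).astype(np.int8)
            eta = -0.5 * betas.sum() + X[:, :3] @ betas
            y = (rng.random(200) < expit(eta)).astype(np.int8)
            samples = self._samples_from(
                net,
                {"X0": X[:, 0], "X1": X[:, 1], "X2": X[:, 2],
                 "Xs": X[:, 3], "Y": y},
            )
            params = m_step(net, samples, self._design_table(200),
                            use_lasso=True)
            zeroed += params["Y"].betas["Xs"] == 0.0
            kept += all(params["Y"].betas[f"X{j}"] != 0.0 for j in range(3))
        assert zeroed / n_rep >= 0.8
        assert kept / n_rep >= 0.95

    def test_degenerate_states_keep_previous(self):
        roles = {"A": NodeRole(), "B": NodeRole()}
        net = SignalingNetwork(roles, [("A", "B")])
        ones = np.ones(50, dtype=np.int8)
        samples = self._samples_from(net, {"A": ones, "B": ones})
        prev = {"A": NodeParameters(0.3), "B": NodeParameters(0.7, {"A": 1.5})}
        with pytest.warns(RuntimeWarning):
            params = m_step(net, samples, self._design_table(50), prev=prev)
        assert params["B"].betas["A"] == 1.5
        assert params["B"].beta0 == 0.7

    def test_emission_update_and_label_anchoring(self):
        """Emission means are state-weighted averages, and the anchored fit
        always reports mu1 >= mu0 even if the sampler's labels are flipped."""
        roles = {"P": NodeRole(observed=True)}
        net = SignalingNetwork(roles, [], name="lone")
        rng = np.random.default_rng(2)
        true_state = (rng.random(400) < 0.5).astype(np.int8)
        v = np.where(true_state == 1, 900.0, 300.0) + rng.normal(0, 40, 400)
        data = ExperimentTable(
            [Record(f"r{i}", 0.0, readings={"P": float(max(x, 0.0))})
             for i, x in enumerate(v)]
        )
        # deliberately flipped labels in the samples
        samples = self._samples_from(net, {"P": 1 - true_state})
        params = m_step(net, samples, data)
        assert params["P"].mu1 > params["P"].mu0
        assert params["P"].mu0 == pytest.approx(300.0, abs=30.0)
        assert params["P"].mu1 == pytest.approx(900.0, abs=30.0)
        assert params["P"].sigma0 > 0 and params["P"].sigma1 > 0


class TestFitMCEM:
    def _scenario(self, seed=0):
        return generate_scenario(
            n_ligands=2, n_hidden=3, n_observed=2, n_decoy_edges=0,
            n_conditions=15, n_time_points=3, effect_range=(4, 8),
            emission_gap=1000.0, noise_sd=150.0, seed=seed,
        )

    def test_infinite_tol_runs_one_iteration(self):
        scn = self._scenario()
        res = fit_mcem(
            scn.truth_net, scn.readings,
            MCEMConfig(n_sweeps=60, burn_in=20, max_iter=10,
                       tol=float("inf"), seed=1),
        )
        assert res.n_iter == 1
        assert res.converged

    def test_ascent_trend_and_convergence_flag(self):
        scn = self._scenario(seed=3)
        res = fit_mcem(
            scn.truth_net, scn.readings,
            MCEMConfig(n_sweeps=120, burn_in=40, max_iter=6, tol=0.0,
                       use_lasso=False, seed=2),
        )
        assert not res.converged  # tol=0 can never be met exactly
        assert len(res.trace) == 6
        rho = spearmanr(np.arange(len(res.trace)), res.trace).statistic
        assert rho > 0

    def test_beats_intercept_only_on_held_out_records(self):
        scn = generate_scenario(
            n_ligands=2, n_hidden=3, n_observed=2, n_decoy_edges=0,
            n_conditions=30, n_time_points=2, effect_range=(4, 8),
            emission_gap=1000.0, noise_sd=150.0, seed=6,
        )
        train = ExperimentTable(scn.readings.records[:40])
        held = ExperimentTable(scn.readings.records[40:])
        res = fit_mcem(
            scn.truth_net, train,
            MCEMConfig(n_sweeps=150, burn_in=50, max_iter=6,
                       use_lasso=False, seed=4),
        )
        flat = {
            n: NodeParameters(
                0.0, {p: 0.0 for p in pr.betas},
                mu0=pr.mu0, mu1=pr.mu1, sigma0=pr.sigma0, sigma1=pr.sigma1,
            )
            for n, pr in res.params.items()
        }
        ll_fit = mc_loglik(res.network, res.params, held, 400, 11)
        ll_flat = mc_loglik(res.network, flat, held, 400, 11)
        assert ll_fit > ll_flat

    def test_redundant_parallel_path_pruned(self):
        """A duplicated parallel wire carries no extra information; the
        final L1 round deletes at least one redundant edge in most runs."""
        roles = {
            "L": NodeRole(ligand=True), "R": NodeRole(receptor=True),
            "P": NodeRole(observed=True),
        }
        pruned_runs = 0
        n_rep = 5
        for seed in range(n_rep):
            rng = np.random.default_rng(200 + seed)
            net = SignalingNetwork(
                roles, [("L", "R"), ("R", "P")], name="dup"
            )
            # duplicate direct wire R -> P is redundant with itself plus a
            # cloned intermediate path through an extra hidden node
            roles2 = dict(roles)
            roles2["H"] = NodeRole()
            net = SignalingNetwork(
                roles2,
                [("L", "R"), ("R", "P"), ("R", "H"), ("H", "P")],
            )
            s_r = np.zeros(60, dtype=np.int8)
            recs = []
            for i in range(60):
                stim = i % 2 == 0
                s = 1 if stim else 0
                v = 900.0 + rng.normal(0, 80) if s else 300.0 + rng.normal(0, 80)
                recs.append(
                    Record(f"r{i}", 0.0,
                           stimuli=frozenset({"L"} if stim else set()),
                           readings={"P": float(max(v, 0.0))})
                )
            data = ExperimentTable(recs)
            res = fit_mcem(
                net, data,
                MCEMConfig(n_sweeps=120, burn_in=40, max_iter=4,
                           use_lasso=True, seed=seed),
            )
            redundant = {("R", "P"), ("R", "H"), ("H", "P")}
            pruned_runs += any(e in redundant for e in res.pruned_edges)
        assert pruned_runs >= 3

    def test_clamp_assignment_semantics(self, chain_net):
        rec = Record("c", 0.0, stimuli=frozenset({"L"}),
                     inhibited=frozenset())
        assert clamp_assignment(chain_net, rec) == {"L": 1}
        rec2 = Record("c", 0.0)
        assert clamp_assignment(chain_net, rec2) == {"L": 0}

    def test_validation_rejects_unknown_references(self, chain_net):
        bad = ExperimentTable(
            [Record("c", 0.0, stimuli=frozenset({"R"}))]
        )
        with pytest.raises(KeyError):
            bad.validate_against(chain_net)
        with pytest.raises(ValueError):
            Record("c", 0.0, readings={"P": -5.0})
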