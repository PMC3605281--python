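import itertools

import numpy as np
import pytest

from logictrain.formats import MidasDataset, PriorKnowledgeNetwork
from logictrain.ode import (OdeFitConfig, OdeParams, build_rhs,
                            default_params, fit_ode, integrate,
                            simulate_ode_all)
from logictrain.preprocess import expand, mark_status


def _bbar(scaffold, bits, params, x_by_node):
    """Evaluate the continuous update Bbar via the vector field at x_i=0."""
    rhs, clamped, _ = build_rhs(scaffold, bits, params)
    idx = scaffold.node_index()
    x = np.zeros(len(scaffold.nodes))
    for name, v in x_by_node.items():
        x[idx[name]] = v
    return rhs(0.0, x), idx


class TestBuildRhs:
    def test_or_of_two_inputs_is_probabilistic_sum(self):
        net = PriorKnowledgeNetwork.from_edges(
            [("A", 1, "C"), ("B", 1, "C")])
        sc = expand(net, max_and_arity=1)
        params = default_params(sc, np.ones(2, dtype=int), tau=1.0)
        # identity-like literals: evaluate at vertex inputs where the Hill
        # transfer is exact, and at h-transformed interior points
        for xa, xb in itertools.product([0.0, 1.0], repeat=2):
            dx, idx = _bbar(sc, np.ones(2, dtype=int), params,
                            {"A": xa, "B": xb})
            assert dx[idx["C"]] == pytest.approx(xa + xb - xa * xb)

    def test_and_is_product(self):
        net = PriorKnowledgeNetwork.from_edges(
            [("A", 1, "C"), ("B", 1, "C")])
        sc = expand(net, max_and_arity=2)
        labels = sc.gate_labels()
        bits = np.zeros(sc.n_gates, dtype=int)
        bits[labels.index("A^B=>C")] = 1
        params = default_params(sc, bits, tau=1.0)
        for xa, xb in itertools.product([0.0, 1.0], repeat=2):
            dx, idx = _bbar(sc, bits, params, {"A": xa, "B": xb})
            assert dx[idx["C"]] == pytest.approx(xa * xb)

    def test_vertex_consistency_all_sign_patterns_up_to_three_inputs(self):
        """At Boolean vertex inputs the continuous gate equals the Boolean
        OR-of-ANDs output, exhaustively over arities 1-3, sign patterns and
        gate subsets."""
        rng = np.random.default_rng(0)
        for d in (1, 2, 3):
            for signs in itertools.product([1, -1], repeat=d):
                edges = [(f"I{i}", signs[i], "O") for i in range(d)]
                sc = expand(PriorKnowledgeNetwork.from_edges(edges),
                            max_and_arity=d)
                subsets = (range(1, 2 ** sc.n_gates) if sc.n_gates <= 4
                           else rng.integers(1, 2 ** sc.n_gates, 8))
                for code in subsets:
                    bits = np.array([(int(code) >> e) & 1
                                     for e in range(sc.n_gates)])
                    params = default_params(
                        sc, bits, n_h=float(rng.uniform(1, 6)),
                        k=float(rng.uniform(0.1, 1.0)))
                    for vertex in itertools.product([0.0, 1.0], repeat=d):
                        xs = {f"I{i}": vertex[i] for i in range(d)}
                        dx, idx = _bbar(sc, bits, params, xs)
                        expected = 0
                        for e, g in enumerate(sc.gates):
                            if not bits[e]:
                                continue
                            gv = all(
                                (xs[n] if s > 0 else 1 - xs[n]) > 0.5
                                for n, s in g.inputs)
                            expected = expected or gv
                        assert dx[idx["O"]] == pytest.approx(float(expected))

    def test_missing_parameter_errors(self):
        net = PriorKnowledgeNetwork.from_edges([("A", 1, "B")])
        sc = expand(net)
        with pytest.raises(ValueError, match="transfer"):
            build_rhs(sc, np.ones(1, dtype=int),
                      OdeParams(transfers={}, tau={"B": 1.0}))
        with pytest.raises(ValueError, match="tau"):
            build_rhs(sc, np.ones(1, dtype=int),
                      OdeParams(transfers={(0, 0): (2.0, 0.5)}, tau={}))


class TestIntegrate:
    def test_closed_form_single_activating_edge(self):
        """Input clamped at 1 -> dx = (1 - x)/tau; x(1) = 1 - e^-1."""
        net = PriorKnowledgeNetwork.from_edges([("A", 1, "B")])
        sc = expand(net)
        params = OdeParams(transfers={(0, 0): (3.0, 0.5)}, tau={"B": 1.0})
        rhs, clamped, clamp_val = build_rhs(sc, np.ones(1, dtype=int),
                                            params, stimuli={"A": 1.0})
        x0 = np.where(clamped, clamp_val, 0.0)
        traj = integrate(rhs, x0, np.array([0.0, 1.0]), rtol=1e-10,
                         atol=1e-12)
        xb = traj[-1, sc.node_index()["B"]]
        assert xb == pytest.approx(1 - np.exp(-1), abs=1e-6)

    def test_self_activation_fixpoint_at_zero(self):
        net = PriorKnowledgeNetwork.from_edges([("B", 1, "B")])
        sc = expand(net)
        params = default_params(sc, np.ones(1, dtype=int))
        rhs, _, _ = build_rhs(sc, np.ones(1, dtype=int), params)
        traj = integrate(rhs, np.zeros(1), np.array([0.0, 5.0]))
        assert traj[-1, 0] == 0.0

    def test_flow_stays_in_unit_cube(self, toy):
        truth, _ = toy
        traj = simulate_ode_all(truth.scaffold, truth.bits, truth.params,
                                truth.template, truth.status)
        assert np.all(traj >= 0.0) and np.all(traj <= 1.0)

    def test_feedback_free_model_approaches_fuzzy_style_fixpoint(self):
        """As t -> inf a cascade converges to the algebraic fixpoint of its
        transfer functions."""
        net = PriorKnowledgeNetwork.from_edges(
            [("A", 1, "B"), ("B", 1, "C")])
        sc = expand(net)
        params = default_params(sc, np.ones(2, dtype=int), n_h=2.0, k=0.5)
        rhs, clamped, clamp_val = build_rhs(sc, np.ones(2, dtype=int),
                                            params, stimuli={"A": 0.7})
        x0 = np.where(clamped, clamp_val, 0.0)
        traj = integrate(rhs, x0, np.array([0.0, 200.0]))
        idx = sc.node_index()

        def h(x, n=2.0, k=0.5):
            return x**n * (1 + k**n) / (x**n + k**n)

        xb = h(0.7)
        assert traj[-1, idx["B"]] == pytest.approx(xb, abs=1e-5)
        assert traj[-1, idx["C"]] == pytest.approx(h(xb), abs=1e-5)


def _single_edge_problem(tau_star=2.0, n_star=3.0, k_star=0.5):
    net = PriorKnowledgeNetwork.from_edges([("A", 1, "B")])
    times = np.linspace(0.0, 10.0, 21)
    data = MidasDataset(
        stimuli=["A"], inhibitors=[], signals=["B"], times=times,
        treatments=np.array([[1.0], [0.0]]),
        values=np.zeros((2, 1, len(times))),
    )
    sc = expand(net)
    status = mark_status(net, data)
    bits = np.ones(1, dtype=int)
    truth = OdeParams(transfers={(0, 0): (n_star, k_star)},
                      tau={"B": tau_star})
    traj = simulate_ode_all(sc, bits, truth, data, status)
    data.values[:, 0, :] = traj[:, :, sc.node_index()["B"]]
    return sc, status, data, bits, truth


class TestFitOde:
    def test_self_consistency_fit_reaches_planted_optimum(self):
        sc, status, data, bits, truth = _single_edge_problem()
        res = fit_ode(sc, bits, data, status,
                      cfg=OdeFitConfig(seed=0, maxiter=40, popsize=10))
        assert res.mse <= 1e-5

    def test_tau_recovery_within_five_percent(self):
        sc, status, data, bits, truth = _single_edge_problem(tau_star=2.0)
        res = fit_ode(sc, bits, data, status,
                      cfg=OdeFitConfig(seed=1, maxiter=40, popsize=10))
        tau_hat = res.params.tau["B"]
        assert abs(tau_hat - 2.0) / 2.0 < 0.05

    def test_same_seed_identical_report(self):
        sc, status, data, bits, _ = _single_edge_problem()
        cfg = OdeFitConfig(seed=7, maxiter=10, popsize=6)
        a = fit_ode(sc, bits, data, status, cfg=cfg)
        b = fit_ode(sc, bits, data, status, cfg=cfg)
        assert a.mse == b.mse
        assert a.params.transfers == b.params.transfers
        assert a.params.tau == b.params.tau

    def test_pluggable_optimizer(self):
        from scipy.optimize import differential_evolution

        sc, status, data, bits, _ = _single_edge_problem()

        def my_opt(fun, bounds, seed):
            return differential_evolution(fun, bounds, seed=seed, maxiter=5,
                                          popsize=5, polish=False)

        res = fit_ode(sc, bits, data, status, optimizer=my_opt)
        assert np.isfinite(res.mse)

    def test_unidentifiable_setup_warns(self):
        sc, status, data, bits, _ = _single_edge_problem()
        # measure nothing downstream of the selected gate
        data2 = MidasDataset(
            stimuli=["A"], inhibitors=[], signals=["A"], times=data.times,
            treatments=data.treatments,
            values=np.tile(data.treatments[:, :1, None],
                           (1, 1, len(data.times))),
        )
        net = PriorKnowledgeNetwork.from_edges([("A", 1, "B")])
        status2 = mark_status(net, data2)
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit_ode(sc, bits, data2, status2,
                    cfg=OdeFitConfig(seed=0, maxiter=2, popsize=4))

    def test_too_few_times_rejected(self):
        sc, status, data, bits, _ = _single_edge_problem()
        short = MidasDataset(
            stimuli=["A"], inhibitors=[], signals=["B"],
            times=data.times[:2], treatments=data.treatments,
            values=data.values[:, :, :2],
        )
        with pytest.raises(ValueError, match="time"):
            fit_ode(sc, bits, short, status)
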