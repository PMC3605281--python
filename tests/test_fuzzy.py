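import itertools

import numpy as np
import pytest

from logictrain.boolean_engine import simulate_all
from logictrain.formats import MidasDataset, PriorKnowledgeNetwork
from logictrain.fuzzy import (IDENTITY, FuzzyModel, TransferFunction,
                              decode_chromosome, default_menu,
                              encode_boolean_chromosome, eval_transfer,
                              fuzzy_theta, refine_and_reduce, simulate_fuzzy,
                              simulate_fuzzy_all, train_fuzzy)
from logictrain.preprocess import expand, mark_status
from logictrain.scoring import ScoringConfig, theta_f
from logictrain.search import GAConfig, optimize_boolean


class TestTransferFunction:
    @pytest.mark.parametrize("tf", [
        TransferFunction(2, 0.5), TransferFunction(4, 0.2),
        TransferFunction(7, 1.0), IDENTITY])
    def test_normalized_endpoints(self, tf):
        assert eval_transfer(tf, 0.0) == 0.0
        assert eval_transfer(tf, 1.0) == pytest.approx(
            1.0 if tf.identity else tf.gain)

    def test_hand_computed_midpoint(self):
        # n=2, K=0.5 at x=0.5: 0.25*1.25 / 0.5 = 0.625
        assert eval_transfer(TransferFunction(2, 0.5), 0.5) == \
            pytest.approx(0.625)

    def test_identity_passthrough(self):
        assert eval_transfer(IDENTITY, 0.3) == pytest.approx(0.3)

    def test_monotone(self):
        tf = TransferFunction(4, 0.55)
        xs = np.linspace(0, 1, 50)
        ys = eval_transfer(tf, xs)
        assert np.all(np.diff(ys) >= 0)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            assert eval_transfer(IDENTITY, 1.5) == 1.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            TransferFunction(n_h=-1, k=0.5)
        with pytest.raises(ValueError):
            TransferFunction(n_h=2, k=2.0)
        with pytest.raises(ValueError):
            TransferFunction(n_h=2, k=0.5, gain=0.0)


def _model(scaffold, bits, tf):
    transfers = {
        (e, j): tf
        for e, g in enumerate(scaffold.gates) if bits[e]
        for j in range(g.n_inputs)
    }
    return FuzzyModel(bits=np.asarray(bits, dtype=int), transfers=transfers)


class TestSimulateFuzzy:
    def test_boolean_limit_on_binary_cues(self, cascade):
        """Unit-gain transfers on 0/1 states reproduce the Boolean engine."""
        sc, status, data = cascade
        bits = np.ones(sc.n_gates, dtype=int)
        for tf in (TransferFunction(2, 0.5), TransferFunction(4, 0.85),
                   IDENTITY):
            fz = simulate_fuzzy_all(sc, _model(sc, bits, tf), data, status)
            bl = simulate_all(sc, bits, data, status)
            np.testing.assert_allclose(fz.states, bl.states, atol=1e-12)

    def test_or_is_max_of_gate_outputs(self):
        net = PriorKnowledgeNetwork.from_edges(
            [("A", 1, "C"), ("B", 1, "C")])
        sc = expand(net, max_and_arity=1)
        model = _model(sc, np.ones(sc.n_gates, dtype=int), IDENTITY)
        x, conv, _ = simulate_fuzzy(sc, model, {"A": 0.3, "B": 0.7})
        assert conv
        assert x[sc.node_index()["C"]] == pytest.approx(0.7)

    def test_and_is_min_of_transferred_literals(self):
        net = PriorKnowledgeNetwork.from_edges(
            [("A", 1, "C"), ("B", 1, "C")])
        sc = expand(net, max_and_arity=2)
        labels = sc.gate_labels()
        bits = np.zeros(sc.n_gates, dtype=int)
        bits[labels.index("A^B=>C")] = 1
        model = _model(sc, bits, IDENTITY)
        x, _, _ = simulate_fuzzy(sc, model, {"A": 0.3, "B": 0.7})
        assert x[sc.node_index()["C"]] == pytest.approx(0.3)

    def test_gain_scales_output(self):
        net = PriorKnowledgeNetwork.from_edges([("A", 1, "B")])
        sc = expand(net)
        model = _model(sc, np.ones(1, dtype=int),
                       TransferFunction(2, 0.5, gain=0.5))
        x, _, _ = simulate_fuzzy(sc, model, {"A": 1.0})
        assert x[sc.node_index()["B"]] == pytest.approx(0.5)

    def test_nonconvergent_loop_flagged(self):
        net = PriorKnowledgeNetwork.from_edges(
            [("S", 1, "A"), ("A", 1, "B"), ("B", -1, "A")])
        sc = expand(net)
        labels = sc.gate_labels()
        bits = np.zeros(sc.n_gates, dtype=int)
        bits[labels.index("!B^S=>A")] = 1
        bits[labels.index("A=>B")] = 1
        model = _model(sc, bits, TransferFunction(4, 0.5))
        x, conv, _ = simulate_fuzzy(sc, model, {"S": 1.0}, max_iter=60)
        idx = sc.node_index()
        assert not conv
        assert np.isnan(x[idx["A"]]) and np.isnan(x[idx["B"]])


class TestChromosomeCodec:
    def test_round_trip_through_boolean_encoding(self, cascade):
        sc, _, _ = cascade
        menu = default_menu()
        bits = np.array([1, 0] + [0] * (sc.n_gates - 2))[:sc.n_gates]
        chrom = encode_boolean_chromosome(bits, sc, menu)
        model = decode_chromosome(chrom, sc, menu)
        assert np.array_equal(model.bits, bits)
        for tf in model.transfers.values():
            assert tf.identity or tf.gain == 1.0

    def test_transfers_exist_exactly_for_selected_gates(self, cascade):
        sc, _, _ = cascade
        menu = default_menu()
        chrom = encode_boolean_chromosome(np.ones(sc.n_gates, dtype=int),
                                          sc, menu)
        model = decode_chromosome(chrom, sc, menu)
        model.validate(sc)


class TestTrainFuzzy:
    def _partial_problem(self):
        """B's activation is sub-maximal (0.5): only a gain < 1 can fit it."""
        net = PriorKnowledgeNetwork.from_edges([("A", 1, "B")])
        data = MidasDataset(
            stimuli=["A"], inhibitors=[], signals=["B"],
            times=np.array([0.0, 10.0]),
            treatments=np.array([[1.0], [0.0]]),
            values=np.array([[[0.0, 0.5]], [[0.0, 0.0]]]),
        )
        sc = expand(net)
        return sc, mark_status(net, data), data

    def test_fits_partial_activation_below_boolean_floor(self):
        sc, status, data = self._partial_problem()
        scoring = ScoringConfig(alpha=0.0)
        bres = optimize_boolean(sc, data, status, scoring,
                                GAConfig(pop_size=8, generations=10, seed=0),
                                time_index=1)
        bool_tf = theta_f(simulate_all(sc, bres.best_bits, data, status),
                          data, status, 1)
        model, res = train_fuzzy(sc, data, status, scoring,
                                 GAConfig(pop_size=20, generations=30,
                                          seed=1), time_index=1)
        assert res.best_score < bool_tf
        assert res.best_score == pytest.approx(0.0, abs=1e-3)

    def test_single_steep_unit_gain_menu_reduces_to_boolean(self, cascade):
        sc, status, data = cascade
        scoring = ScoringConfig(alpha=1e-3)
        menu = [TransferFunction(4, 0.5)]
        model, res = train_fuzzy(sc, data, status, scoring,
                                 GAConfig(pop_size=15, generations=25,
                                          seed=0), menu=menu, time_index=1)
        bres = optimize_boolean(sc, data, status, scoring,
                                GAConfig(pop_size=15, generations=25,
                                         seed=0), time_index=1)
        assert res.best_score == pytest.approx(bres.best_score, abs=1e-12)


class TestRefineAndReduce:
    def test_refinement_recovers_off_menu_gain(self):
        """Planted gain 0.37 is off the menu; refinement approaches it."""
        sc, status, data = TestTrainFuzzy()._partial_problem()
        data.values[0, 0, 1] = 0.37
        scoring = ScoringConfig(alpha=0.0)
        menu = [TransferFunction(2, 0.5, gain=0.5),
                TransferFunction(2, 0.5, gain=1.0)]
        model, res = train_fuzzy(sc, data, status, scoring,
                                 GAConfig(pop_size=10, generations=15,
                                          seed=0), menu=menu, time_index=1)
        before = fuzzy_theta(sc, model, data, status, scoring, 1)
        refined = refine_and_reduce(sc, model, data, status, scoring,
                                    time_index=1, reduction_threshold=0.0)
        after = fuzzy_theta(sc, refined, data, status, scoring, 1)
        assert after <= before
        assert after == pytest.approx(0.0, abs=1e-4)

    def test_reduction_removes_redundant_gate(self):
        # two parallel activators, one suffices to explain the data
        net = PriorKnowledgeNetwork.from_edges(
            [("A", 1, "C"), ("B", 1, "C")])
        data = MidasDataset(
            stimuli=["A", "B"], inhibitors=[], signals=["C"],
            times=np.array([0.0, 10.0]),
            treatments=np.array([[1.0, 1.0]]),
            values=np.array([[[0.0, 1.0]]]),
        )
        sc = expand(net)
        status = mark_status(net, data)
        labels = sc.gate_labels()
        bits = np.zeros(sc.n_gates, dtype=int)
        bits[labels.index("A=>C")] = 1
        bits[labels.index("B=>C")] = 1
        model = _model(sc, bits, TransferFunction(2, 0.5))
        scoring = ScoringConfig(alpha=0.01)
        reduced = refine_and_reduce(sc, model, data, status, scoring,
                                    time_index=1, reduction_threshold=1e-4)
        assert reduced.bits.sum() < bits.sum()

    def test_zero_threshold_keeps_needed_gates(self):
        sc, status, data = TestTrainFuzzy()._partial_problem()
        model = _model(sc, np.ones(1, dtype=int),
                       TransferFunction(2, 0.5, gain=0.5))
        scoring = ScoringConfig(alpha=0.0)
        reduced = refine_and_reduce(sc, model, data, status, scoring,
                                    time_index=1, reduction_threshold=0.0)
        assert reduced.bits.sum() == 1  # removing the gate would hurt the fit

    def test_reduction_never_increases_gate_count(self, cascade):
        sc, status, data = cascade
        model = _model(sc, np.ones(sc.n_gates, dtype=int),
                       TransferFunction(2, 0.5))
        reduced = refine_and_reduce(sc, model, data, status,
                                    ScoringConfig(alpha=0.01), time_index=1)
        assert reduced.bits.sum() <= model.bits.sum()
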