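"""Forward pass, loss, bespoke weight update and the training loop."""

from __future__ import annotations

import math

import pytest

from coesnet.clustering import TermCluster
from coesnet.fixtures import case_study_network
from coesnet.fnn import (
    FnnNetwork,
    LayerSpec,
    build_layers,
    forward,
    loss,
    sigmoid_derivative,
    train,
    update_weights,
)


def make_layer(x=0.5, w=0.5, b=0.1, level=5):
    return LayerSpec(go_level=level, terms=(("GO:0000001", "direct"),), x=x, w=w, b=b)


class TestForward:
    def test_reference_network_initial_weights(self):
        s, y = forward(case_study_network("initial").layers)
        assert s == pytest.approx(4.6419, abs=1e-4)
        assert y == pytest.approx(0.991, abs=0.001)

    def test_reference_network_updated_weights(self):
        s, y = forward(case_study_network("updated").layers)
        assert s == pytest.approx(5.5468, abs=1e-4)
        assert y == pytest.approx(0.996, abs=0.001)

    def test_all_zero_parameters_give_half(self):
        layers = [make_layer(x=0.0, w=0.0, b=0.0) for _ in range(3)]
        s, y = forward(layers)
        assert (s, y) == (0.0, 0.5)

    def test_prediction_in_open_unit_interval(self):
        for w in (-30.0, -5.0, 0.0, 5.0, 30.0):
            _, y = forward([make_layer(x=1.0, w=w, b=0.0)])
            assert 0.0 < y < 1.0

    def test_saturating_pre_activation_is_overflow_safe(self):
        # |s| > 700 must not raise or produce NaN; the sigmoid saturates.
        for w in (-800.0, 800.0):
            _, y = forward([make_layer(x=1.0, w=w, b=0.0)])
            assert 0.0 <= y <= 1.0

    def test_non_finite_layer_is_an_error(self):
        with pytest.raises(ValueError, match="non-finite"):
            forward([make_layer(w=math.inf)])


class TestLoss:
    def test_perfect_prediction_has_zero_loss(self):
        assert loss(0.7, 0.7).e == 0.0

    def test_reference_outputs_hand_arithmetic(self):
        result = loss(0.991, 0.996)
        assert result.e == pytest.approx(1.25e-5)
        assert result.distance == pytest.approx(0.005)

    def test_extreme_case(self):
        assert loss(1.0, 0.0).e == pytest.approx(0.5)


class TestUpdateWeights:
    def test_zero_input_zero_s_gives_half(self):
        (updated,) = update_weights(
            [make_layer(x=0.0, w=123.0)], s=0.0, y_desired=0.5, y_predicted=0.5
        )
        assert updated.w == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        (updated,) = update_weights(
            [make_layer(x=0.79, w=0.49)], s=4.642, y_desired=0.991, y_predicted=0.996
        )
        expected = 1.0 / (1.0 + math.exp(-0.79 * 0.49)) + 4.642 * 0.005
        assert updated.w == pytest.approx(expected)
        assert updated.w == pytest.approx(0.6188, abs=1e-4)

    def test_zero_error_reduces_to_squashed_product(self):
        layer = make_layer(x=0.3, w=-1.2)
        (updated,) = update_weights([layer], s=2.0, y_desired=0.8, y_predicted=0.8)
        assert updated.w == pytest.approx(1.0 / (1.0 + math.exp(0.3 * 1.2)))

    def test_originals_untouched(self):
        layer = make_layer(w=0.4)
        update_weights([layer], s=1.0, y_desired=0.9, y_predicted=0.1)
        assert layer.w == 0.4


class TestSigmoidDerivative:
    def test_maximum_at_zero(self):
        assert sigmoid_derivative(0.0) == pytest.approx(0.25)

    def test_reference_pre_activation(self):
        assert sigmoid_derivative(4.642) == pytest.approx(0.00946, abs=1e-5)

    @pytest.mark.parametrize("s", [-700.0, -30.0, -1.0, 0.5, 30.0, 700.0])
    def test_bounded_and_symmetric(self, s):
        d = sigmoid_derivative(s)
        assert 0.0 < d <= 0.25
        assert d == pytest.approx(sigmoid_derivative(-s))

    def test_saturation_limit(self):
        assert sigmoid_derivative(1e6) == pytest.approx(0.0, abs=1e-12)


class TestTrain:
    def test_already_converged_stops_at_epoch_zero(self):
        network = FnnNetwork(layers=[make_layer()])
        _, y = forward(network.layers)
        state = train(network, y_desired=y, max_epochs=10, tol=1e-4)
        assert state.stop_reason == "tol_reached"
        assert state.final.epoch == 0

    def test_max_epochs_one_applies_exactly_one_update(self):
        network = FnnNetwork(layers=[make_layer(w=5.0)])
        state = train(network, y_desired=0.01, max_epochs=1, tol=1e-12)
        assert [rec.epoch for rec in state.history] == [0, 1]
        assert state.history[0].weights != state.history[1].weights

    def test_reference_network_training_terminates_with_reason(self):
        network = case_study_network("initial")
        state = train(network, y_desired=0.991, max_epochs=1000, tol=1e-4)
        assert state.stop_reason in ("tol_reached", "loss_stalled", "max_epochs")
        assert [rec.epoch for rec in state.history] == list(
            range(len(state.history))
        )
        if state.stop_reason == "tol_reached":
            assert state.final.e < 1e-4

    def test_training_is_deterministic(self):
        states = [
            train(case_study_network("initial"), 0.991, max_epochs=50, tol=1e-8)
            for _ in range(2)
        ]
        assert [r.e for r in states[0].history] == [r.e for r in states[1].history]


class TestBuildLayers:
    def setup_method(self):
        self.levels = {"GO:0000010": 2, "GO:0000011": 2, "GO:0000012": 3}
        self.annotations = {
            "gene_a": {"GO:0000010"},
            "gene_b": {"GO:0000011", "GO:0000012"},
        }
        self.coes = {"gene_a": 1.0, "gene_b": 0.5}

    def test_single_level_has_unit_bias(self):
        layers = build_layers(
            TermCluster(1, ["GO:0000010"]),
            TermCluster(2, ["GO:0000011"]),
            self.levels,
            self.coes,
            self.annotations,
        )
        assert len(layers) == 1
        assert layers[0].b == 1.0

    def test_equal_level_counts_split_bias_evenly(self):
        layers = build_layers(
            TermCluster(1, ["GO:0000010"]),
            TermCluster(2, ["GO:0000012"]),
            self.levels,
            self.coes,
            self.annotations,
        )
        assert [layer.b for layer in layers] == [0.5, 0.5]
        assert [layer.go_level for layer in layers] == [2, 3]

    def test_bias_vector_sums_to_one(self):
        layers = build_layers(
            TermCluster(1, ["GO:0000010", "GO:0000012"]),
            TermCluster(2, ["GO:0000011"]),
            self.levels,
            self.coes,
            self.annotations,
        )
        assert sum(layer.b for layer in layers) == pytest.approx(1.0, abs=1e-12)

    def test_weights_are_normalized_mean_levels(self):
        layers = build_layers(
            TermCluster(1, ["GO:0000010"]),
            TermCluster(2, ["GO:0000012"]),
            self.levels,
            self.coes,
            self.annotations,
        )
        assert [layer.w for layer in layers] == pytest.approx([2 / 3, 1.0])
        raw = build_layers(
            TermCluster(1, ["GO:0000010"]),
            TermCluster(2, ["GO:0000012"]),
            self.levels,
            self.coes,
            self.annotations,
            weight_mode="raw",
        )
        assert [layer.w for layer in raw] == pytest.approx([2.0, 3.0])

    def test_input_is_mean_coes_of_annotated_genes(self):
        layers = build_layers(
            TermCluster(1, ["GO:0000010", "GO:0000011"]),
            TermCluster(2, ["GO:0000012"]),
            self.levels,
            self.coes,
            self.annotations,
        )
        level2 = next(layer for layer in layers if layer.go_level == 2)
        assert level2.x == pytest.approx((1.0 + 0.5) / 2)

    def test_term_without_level_is_an_error(self):
        with pytest.raises(KeyError, match="GO:0000099"):
            build_layers(
                TermCluster(1, ["GO:0000099"]),
                TermCluster(2, ["GO:0000011"]),
                self.levels,
                self.coes,
                self.annotations,
            )

    def test_empty_union_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_layers(
                TermCluster(1, []), TermCluster(2, []), self.levels, self.coes, {}
            )
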