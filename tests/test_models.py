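"""Receptive-field algebra, branch forward passes, multitask loss, training."""

import numpy as np
import pytest

from sleepstager import _nn
from sleepstager.models import (
    CnnBranchClassifier,
    MultitaskLossConfig,
    TcnBranchClassifier,
    TcnConfig,
    cnn_forward,
    context_targets,
    min_layers,
    multitask_loss,
    receptive_field,
    tcn_forward,
    train_branch,
)


def _weight1_stack_output(x, k, n, b):
    """Independent oracle: final output of a weight-1 dilated causal stack."""
    y = np.asarray(x, dtype=float)
    for i in range(n):
        d = b**i
        out = np.zeros_like(y)
        for t in range(y.size):
            for j in range(k):
                if t - j * d >= 0:
                    out[t] += y[t - j * d]
        y = out
    return y[-1]


def _perturbation_width(k, n, b, length):
    base = np.zeros(length)
    ref = _weight1_stack_output(base, k, n, b)
    count = 0
    for t in range(length):
        x = base.copy()
        x[t] = 1.0
        if _weight1_stack_output(x, k, n, b) != ref:
            count += 1
    return count


class TestReceptiveField:
    def test_pointwise_kernel_sees_one_sample(self):
        assert receptive_field(1, 4, 3) == 1

    def test_default_configuration_covers_an_epoch(self):
        w = receptive_field(7, 5, 5)
        assert w == 1 + 6 * (5**5 - 1) // 4 == 4687
        assert w >= 3000

    @pytest.mark.parametrize("k", [2, 3])
    @pytest.mark.parametrize("b", [1, 2])
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_formula_matches_perturbation_oracle(self, k, n, b):
        w = receptive_field(k, n, b)
        assert w == _perturbation_width(k, n, b, length=w + 3)

    def test_small_case_on_16_sample_input(self):
        # k=2, b=2, n=3: every influential position of a 16-sample input
        assert receptive_field(2, 3, 2) == _perturbation_width(2, 3, 2, length=16)


class TestMinLayers:
    def test_published_depth_for_epoch_coverage(self):
        assert min_layers(3000, 7, 5) == 5

    def test_single_sample_needs_one_layer(self):
        assert min_layers(1, 7, 5) == 1

    @pytest.mark.parametrize("k,b", [(2, 2), (3, 2), (3, 3)])
    def test_minimality_by_exhaustive_search(self, k, b):
        for l in range(2, 65):
            n = min_layers(l, k, b)
            assert receptive_field(k, n, b) >= l
            assert n == 1 or receptive_field(k, n - 1, b) < l

    def test_pointwise_kernel_cannot_cover(self):
        with pytest.raises(ValueError):
            min_layers(8, 1, 2)


class TestTcnForward:
    def test_untrained_heads_emit_uniform_distributions(self, rng):
        net = _nn.TcnNetwork(kernel_size=2, n_layers=2, dilation_base=2, n_filters=3, seed=0)
        probs = tcn_forward(rng.standard_normal((2, 3000)), net)
        np.testing.assert_allclose(probs, 0.2, atol=1e-7)

    def test_outputs_are_distributions(self, rng):
        net = _nn.TcnNetwork(kernel_size=2, n_layers=2, dilation_base=2, n_filters=3, seed=0)
        for h in _nn.HEADS:  # random heads, arbitrary logits
            net.params[f"head_{h}_W"] = rng.standard_normal((3, 5)).astype(np.float32)
        probs = tcn_forward(rng.standard_normal((4, 3000)), net)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("t", [25, 60, 99])
    def test_causality_no_backward_information_flow(self, rng, t):
        """Perturbing sample t leaves all activations at positions < t unchanged."""
        net = _nn.TcnNetwork(
            kernel_size=2, n_layers=3, dilation_base=2, n_filters=3, dropout_rate=0.0, seed=4
        )
        x = rng.standard_normal((1, 100)).astype(np.float32)
        ref = net.forward(x, return_sequence=True)
        x2 = x.copy()
        x2[0, t] += 10.0
        out = net.forward(x2, return_sequence=True)
        np.testing.assert_array_equal(out[:, :, :t], ref[:, :, :t])
        assert np.any(out[:, :, t:] != ref[:, :, t:])

    def test_wrong_input_length_rejected(self, rng):
        est = TcnBranchClassifier()
        with pytest.raises(ValueError, match="3000"):
            est.fit(rng.standard_normal((4, 100)), np.zeros(4, dtype=int))

    def test_kernel_smaller_than_dilation_base_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            TcnConfig(kernel_size=3, n_layers=2, dilation_base=5)
        with pytest.raises(ValueError, match="kernel"):
            _nn.TcnNetwork(kernel_size=3, dilation_base=5)


class TestCnnForward:
    def test_untrained_heads_emit_uniform_distributions(self, rng):
        net = _nn.CnnNetwork(n_filters_total=12, seed=0)
        probs = cnn_forward(rng.standard_normal((3, 29, 20)), net)
        np.testing.assert_allclose(probs, 0.2, atol=1e-7)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_filters_split_across_kernel_widths(self):
        net = _nn.CnnNetwork(kernel_widths=(3, 5, 7), n_filters_total=400)
        assert net.filters_per_width == [133, 133, 134]
        assert sum(net.filters_per_width) == 400

    def test_wrong_spectrogram_dims_rejected(self, rng):
        net = _nn.CnnNetwork(n_filters_total=6, seed=0)
        with pytest.raises(ValueError, match="spectrograms"):
            net.forward(rng.standard_normal((3, 29, 19)))

    def test_one_max_pool_shifts_with_additive_constant(self, rng):
        a = rng.random((4, 10, 6))
        pooled, _ = _nn.one_max_pool(a)
        pooled_c, _ = _nn.one_max_pool(a + 3.7)
        np.testing.assert_allclose(pooled_c, pooled + 3.7, atol=1e-12)

    def test_pooled_features_invariant_to_interior_time_shift(self, rng):
        """Circular frame shift leaves pooled features unchanged when every
        feature map's maximum sits away from the edges."""
        net = _nn.CnnNetwork(kernel_widths=(3,), n_filters_total=8, n_freq=6, seed=1)
        X = np.zeros((1, 20, 6), dtype=np.float32)
        X[0, 9:12] = rng.standard_normal((3, 6)) * 5  # activity strictly interior
        maps = net.feature_maps(X)[0]
        pooled, arg = _nn.one_max_pool(maps)
        assert (arg > 1).all() and (arg < maps.shape[1] - 2).all()
        pooled_shift, _ = _nn.one_max_pool(net.feature_maps(np.roll(X, 1, axis=1))[0])
        np.testing.assert_allclose(pooled_shift, pooled, atol=1e-6)


class TestMultitaskLoss:
    def test_perfect_prediction_gives_zero_loss(self):
        onehot = np.zeros((2, 3, 5))
        onehot[:, :, 2] = 1.0
        assert multitask_loss(onehot, onehot) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_outputs_cost_three_log_five(self):
        outputs = np.full((4, 3, 5), 0.2)
        targets = np.zeros((4, 3, 5))
        targets[:, :, 1] = 1.0
        assert multitask_loss(outputs, targets) == pytest.approx(3 * np.log(5), rel=1e-9)

    def test_missing_neighbor_subtasks_are_dropped(self):
        outputs = np.full((1, 3, 5), 0.2)
        targets = np.zeros((1, 3, 5))
        targets[0, 1, 0] = 1.0  # only the classification subtask present
        assert multitask_loss(outputs, targets) == pytest.approx(np.log(5), rel=1e-9)

    def test_l2_vanishes_with_zero_parameters(self):
        outputs = np.full((1, 3, 5), 0.2)
        targets = np.zeros((1, 3, 5))
        targets[:, :, 0] = 1.0
        params = {"W": np.zeros((3, 3)), "b_b": np.ones(3)}
        cfg = MultitaskLossConfig(l2_lambda=0.5)
        assert multitask_loss(outputs, targets, cfg, params) == pytest.approx(3 * np.log(5))

    def test_non_one_hot_targets_rejected(self):
        outputs = np.full((1, 3, 5), 0.2)
        bad = np.full((1, 3, 5), 0.3)
        with pytest.raises(ValueError, match="one-hot"):
            multitask_loss(outputs, bad)

    def test_context_targets_mask_recording_boundaries(self):
        y = np.array([0, 1, 2, 3, 4])
        groups = np.array(["a", "a", "a", "b", "b"])
        t = context_targets(y, groups)
        np.testing.assert_array_equal(t[:, 1], y)
        np.testing.assert_array_equal(t[:, 0], [-1, 0, 1, -1, 3])
        np.testing.assert_array_equal(t[:, 2], [1, 2, -1, 4, -1])


class TestTraining:
    def _small_cnn_data(self, small_dataset):
        from sleepstager.preprocessing import SpectrogramTransformer, standardize_signals
        from sleepstager.simulate import dataset_arrays

        X, y, groups, _ = dataset_arrays(small_dataset)
        std = standardize_signals(X, groups=groups)
        return SpectrogramTransformer().fit().transform(std), y, groups

    def test_single_epoch_smoke_loss_finite(self, rng):
        X = rng.standard_normal((10, 29, 20))
        y = rng.integers(0, 5, 10)
        est = CnnBranchClassifier(n_filters_total=6, n_epochs=1, seed=0)
        est.fit(X, y)
        assert np.isfinite(est.history_[0]["train_loss"])

    def test_cnn_branch_beats_chance_on_separable_data(self, small_dataset):
        specs, y, groups = self._small_cnn_data(small_dataset)
        est = CnnBranchClassifier(
            n_filters_total=48, n_epochs=8, learning_rate=1e-3, seed=0
        ).fit(specs, y, groups=groups)
        prior = np.bincount(y, minlength=5).max() / y.size
        assert est.validation_accuracy_ > max(0.55, prior)

    def test_training_is_deterministic_under_fixed_seed(self, small_dataset):
        specs, y, groups = self._small_cnn_data(small_dataset)
        accs = []
        for _ in range(2):
            est = CnnBranchClassifier(n_filters_total=24, n_epochs=3, learning_rate=1e-3, seed=9)
            est.fit(specs, y, groups=groups)
            accs.append(est.validation_accuracy_)
        assert accs[0] == accs[1]

    def test_loss_decreases_on_separable_data(self, small_dataset):
        specs, y, groups = self._small_cnn_data(small_dataset)
        est = CnnBranchClassifier(n_filters_total=24, n_epochs=5, learning_rate=1e-3, seed=0)
        est.fit(specs, y, groups=groups)
        losses = [h["train_loss"] for h in est.history_]
        assert losses[-1] < losses[0]
        increases = sum(b > a for a, b in zip(losses, losses[1:]))
        assert increases <= 1  # monotone trend, allowing single-step noise

    def test_tcn_branch_trains_and_records_accuracies(self, small_dataset):
        from sleepstager.preprocessing import standardize_signals
        from sleepstager.simulate import dataset_arrays

        X, y, groups, _ = dataset_arrays(small_dataset[:3])
        std = standardize_signals(X, groups=groups)
        est = train_branch(
            std, y, branch="tcn", groups=groups, seed=0,
            n_filters=4, n_epochs=1, learning_rate=1e-3,
        )
        for acc in (est.acc_current_, est.pre_acc_prev_, est.pre_acc_next_):
            assert 0.0 <= acc <= 1.0
        probs = est.predict_context_proba(std[:5])
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_empty_training_set_rejected(self):
        est = CnnBranchClassifier()
        with pytest.raises(ValueError):
            est.fit(np.empty((0, 29, 20)), np.empty(0, dtype=int))
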