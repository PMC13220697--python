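"""The splittable 1D-CNN engine: shapes, gradients, split-equivalence."""

import numpy as np
import pytest

from fedsplitsim.errors import ConfigurationError, ShapeError
from fedsplitsim.nn import (
    LayerSpec,
    ModelSpec,
    backward,
    build_reference_model,
    cross_entropy,
    forward,
    init_params,
    load_params,
    output_shapes,
    param_count,
    predict,
    save_params,
    sgd_step,
    smashed_feature_count,
    split_backward,
    split_forward_device,
    split_forward_server,
    split_params,
)


class TestReferenceModel:
    def test_device_side_layer_count(self, canonical_spec):
        assert canonical_spec.cut_layer == 4
        kinds = [ls.kind for ls in canonical_spec.layers[:4]]
        assert kinds == ["conv1d", "maxpool1d", "conv1d", "flatten"]

    def test_device_side_output_width(self, canonical_spec):
        # 187 -> same-pad conv -> 187 -> pool 2 (floor) -> 93 -> same-pad conv -> 93
        shapes = output_shapes(canonical_spec)
        assert shapes[0] == ("seq", 187, 16)
        assert shapes[1] == ("seq", 93, 16)
        assert shapes[2] == ("seq", 93, 32)
        assert shapes[3] == ("flat", 2976)
        assert smashed_feature_count(canonical_spec) == 2976

    def test_ends_in_two_class_softmax(self, canonical_spec):
        assert canonical_spec.layers[-1].kind == "softmax"
        assert canonical_spec.layers[-2].units == 2

    def test_yaml_round_trip(self, tmp_path, canonical_spec):
        path = tmp_path / "model.yaml"
        canonical_spec.to_yaml(path)
        assert ModelSpec.from_yaml(path) == canonical_spec


class TestForward:
    def test_zero_params_give_uniform_probabilities(self, canonical_spec):
        params = {k: np.zeros_like(v) for k, v in init_params(canonical_spec, 0).items()}
        X = np.random.default_rng(0).normal(size=(3, 187))
        probs, _ = forward(params, canonical_spec, X)
        np.testing.assert_allclose(probs, 0.5)

    def test_probabilities_normalised(self, tiny_spec, tiny_batch):
        X, _ = tiny_batch
        probs, _ = forward(init_params(tiny_spec, 1), tiny_spec, X)
        assert probs.min() >= 0 and probs.max() <= 1
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_batch_independence(self, tiny_spec):
        """Forward on a batch equals stacking per-segment forwards."""
        params = init_params(tiny_spec, 2)
        X = np.random.default_rng(3).normal(size=(32, tiny_spec.input_length))
        batch_probs, _ = forward(params, tiny_spec, X)
        single = np.vstack([forward(params, tiny_spec, X[i : i + 1])[0] for i in range(32)])
        np.testing.assert_allclose(batch_probs, single, rtol=1e-12, atol=1e-14)

    def test_shape_error_names_layer(self, tiny_spec):
        params = init_params(tiny_spec, 0)
        with pytest.raises(ShapeError):
            forward(params, tiny_spec, np.zeros((2, tiny_spec.input_length + 1)))


class TestBackward:
    def test_gradients_match_finite_differences(self, tiny_spec, tiny_batch):
        """Central finite differences (h=1e-5, float64) agree to <1e-5
        relative error for every parameter of every layer kind."""
        X, y = tiny_batch
        params = init_params(tiny_spec, 3)
        _, tape = forward(params, tiny_spec, X)
        grads = backward(params, tape, y)
        h = 1e-5
        for k in params:
            for idx in np.ndindex(params[k].shape):
                shifted = {a: b.copy() for a, b in params.items()}
                shifted[k][idx] += h
                up = cross_entropy(forward(shifted, tiny_spec, X)[0], y)
                shifted[k][idx] -= 2 * h
                dn = cross_entropy(forward(shifted, tiny_spec, X)[0], y)
                fd = (up - dn) / (2 * h)
                scale = max(abs(fd), abs(grads[k][idx]), 1e-8)
                assert abs(fd - grads[k][idx]) / scale < 1e-5, (k, idx)

    def test_softmax_logit_gradient_closed_form(self, tiny_spec, tiny_batch):
        """d(loss)/d(logits) = (p - onehot)/B, via the dense-bias gradient of
        the classifier layer (its pre-activation is the logits)."""
        X, y = tiny_batch
        params = init_params(tiny_spec, 4)
        probs, tape = forward(params, tiny_spec, X)
        grads = backward(params, tape, y)
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(y)), y] = 1.0
        expected = ((probs - onehot) / len(y)).sum(axis=0)
        np.testing.assert_allclose(grads["L5_b"], expected, rtol=1e-12)

    def test_invalid_label_rejected(self, tiny_spec, tiny_batch):
        X, _ = tiny_batch
        params = init_params(tiny_spec, 0)
        _, tape = forward(params, tiny_spec, X)
        with pytest.raises(ValueError):
            backward(params, tape, np.array([0, 1, 2, 0, 1, 0]))


class TestSgd:
    def test_zero_lr_leaves_params_unchanged(self, tiny_spec, tiny_batch):
        X, y = tiny_batch
        params = init_params(tiny_spec, 5)
        _, tape = forward(params, tiny_spec, X)
        grads = backward(params, tape, y)
        new = sgd_step(params, grads, 0.0)
        for k in params:
            np.testing.assert_array_equal(new[k], params[k])

    def test_step_matches_hand_computation(self):
        params = {"w": np.array([2.0])}
        grads = {"w": np.array([3.0])}
        assert sgd_step(params, grads, 0.1)["w"][0] == pytest.approx(1.7)

    def test_small_step_descends(self, tiny_spec):
        """Loss decreases after one small step in >=95% of random trials."""
        wins = 0
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            params = init_params(tiny_spec, trial)
            X = rng.normal(size=(8, tiny_spec.input_length))
            y = rng.integers(0, 2, 8)
            probs, tape = forward(params, tiny_spec, X)
            before = cross_entropy(probs, y)
            stepped = sgd_step(params, backward(params, tape, y), 1e-3)
            after = cross_entropy(forward(stepped, tiny_spec, X)[0], y)
            wins += after < before
        assert wins >= 95

    def test_prediction_tie_breaks_low_index(self):
        assert predict(np.array([[0.5, 0.5]]))[0] == 0


class TestSplitEquivalence:
    @pytest.mark.parametrize("cut", list(range(8)))
    def test_split_matches_full_engine_bitwise(self, canonical_spec, cut):
        """Core split-learning property: device+server composition reproduces
        the unsplit forward and every parameter gradient bit-for-bit."""
        spec = canonical_spec.with_cut(cut)
        params = init_params(spec, 6)
        rng = np.random.default_rng(cut)
        X = rng.normal(size=(4, 187))
        y = rng.integers(0, 2, 4)
        probs, tape = forward(params, spec, X)
        full_grads = backward(params, tape, y)
        smashed, dev_tape = split_forward_device(params, spec, X)
        split_probs, srv_tape = split_forward_server(params, spec, smashed)
        assert np.array_equal(split_probs, probs)
        srv_g, cut_grad, dev_g = split_backward(params, srv_tape, dev_tape, y)
        merged = {**srv_g, **dev_g}
        assert set(merged) == set(full_grads)
        for k in full_grads:
            assert np.array_equal(merged[k], full_grads[k]), k
        assert cut_grad.shape == smashed.activations.shape

    def test_degenerate_cut_zero_passes_raw_batch(self, canonical_spec):
        spec = canonical_spec.with_cut(0)
        params = init_params(spec, 0)
        X = np.random.default_rng(0).normal(size=(2, 187))
        smashed, _ = split_forward_device(params, spec, X)
        np.testing.assert_array_equal(smashed.activations[:, :, 0], X)

    def test_smashed_payload_size_after_flatten(self, canonical_spec):
        params = init_params(canonical_spec, 0)
        X = np.zeros((1, 187))
        smashed, _ = split_forward_device(params, canonical_spec, X)
        assert smashed.activations.shape == (1, 2976)
        assert smashed.byte_size == 11_904  # 2,976 features x 4 bytes

    def test_cut_out_of_range_rejected(self, canonical_spec):
        with pytest.raises(ConfigurationError):
            canonical_spec.with_cut(99)

    def test_split_params_partition(self, canonical_spec):
        params = init_params(canonical_spec, 1)
        device, server = split_params(params, canonical_spec)
        assert set(device) == {"L0_W", "L0_b", "L2_W", "L2_b"}
        assert set(server) == {"L4_W", "L4_b", "L5_W", "L5_b"}
        assert param_count(device) + param_count(server) == param_count(params)


class TestSerialization:
    def test_save_load_forward_bit_identical(self, tmp_path, tiny_spec, tiny_batch):
        X, _ = tiny_batch
        params = init_params(tiny_spec, 9)
        path = tmp_path / "params.json"
        save_params(params, path)
        loaded = load_params(path)
        for k in params:
            assert np.array_equal(loaded[k], params[k])
        p1, _ = forward(params, tiny_spec, X)
        p2, _ = forward(loaded, tiny_spec, X)
        assert np.array_equal(p1, p2)

    def test_init_deterministic(self, tiny_spec):
        a, b = init_params(tiny_spec, 123), init_params(tiny_spec, 123)
        assert all(np.array_equal(a[k], b[k]) for k in a)
        c = init_params(tiny_spec, 124)
        assert any(not np.array_equal(a[k], c[k]) for k in a)


def test_invalid_layer_specs_rejected():
    with pytest.raises(ConfigurationError):
        LayerSpec("conv1d", filters=0, kernel=3)
    with pytest.raises(ConfigurationError):
        LayerSpec("dense", units=0)
    with pytest.raises(ConfigurationError):
        LayerSpec("warp")
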