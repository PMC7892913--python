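"""Decoder architecture, gradients, training behavior, determinism."""

import numpy as np
import pytest

from megfix.errors import DegenerateTrainingError, InvalidArchitectureError
from megfix.models import (
    ModelConfig,
    _backward,
    _forward,
    build_model,
    load_model,
    predict_proba,
    save_model,
    train,
)
from megfix.preprocessing import EpochSet

from conftest import subset


def toy_epochs(n_trials=40, n_channels=6, n_times=30, separation=0.0, seed=0):
    """Two-class Gaussian data; ``separation`` offsets class 1 in channel 0."""
    rng = np.random.default_rng(seed)
    labels = np.tile([0, 1], n_trials // 2)
    data = rng.normal(size=(n_trials, n_channels, n_times))
    data[labels == 1, 0, :] += separation
    return EpochSet(data, 125.0, (-0.2, 0.04), labels, [f"c{i}" for i in range(n_channels)])


class TestArchitecture:
    def test_paper_scale_shapes(self):
        cfg = ModelConfig()
        m = build_model("LF", 204, 87, cfg)
        assert m.W.shape == (204, 16)
        assert m.temporal_filters.shape == (16, 14)
        assert m.output_weights.shape == (21, 16, 2)  # floor(87/4) pooled samples

    def test_var_temporal_weight_count_is_k_times_lf(self):
        cfg = ModelConfig(k=5, l_filt=7)
        lf = build_model("LF", 10, 40, cfg)
        var = build_model("VAR", 10, 40, cfg)
        assert var.temporal_filters.size == cfg.k * lf.temporal_filters.size

    def test_pool_one_keeps_full_time_axis(self):
        cfg = ModelConfig(k=3, l_filt=5, pool=1)
        m = build_model("LF", 8, 33, cfg)
        assert m.output_weights.shape == (33, 3, 2)

    def test_filter_longer_than_epoch_rejected(self):
        with pytest.raises(InvalidArchitectureError):
            build_model("LF", 8, 10, ModelConfig(l_filt=14))

    def test_unknown_variant_rejected(self):
        with pytest.raises(InvalidArchitectureError):
            build_model("CNN", 8, 87, ModelConfig())


class TestGradients:
    @pytest.mark.parametrize("variant", ["LF", "VAR"])
    def test_backprop_matches_finite_differences(self, variant):
        cfg = ModelConfig(
            k=3, l_filt=4, pool=2, dropout_rate=0.0, l1_penalty=1e-3, seed=1, dtype="float64"
        )
        C, T, B = 5, 11, 7
        m = build_model(variant, C, T, cfg)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((B, C, T))
        y = rng.integers(0, 2, B)

        def loss(params):
            saved = m.params
            m.params = params
            probs, _ = _forward(m, X)
            val = -np.log(probs[np.arange(B), y]).mean()
            val += cfg.l1_penalty * (np.abs(params["W"]).sum() + np.abs(params["H"]).sum())
            m.params = saved
            return val

        _, cache = _forward(m, X)
        grads = _backward(m, cache, y)
        eps = 1e-6
        for key, g in grads.items():
            base = {k: v.copy() for k, v in m.params.items()}
            num = np.zeros_like(g)
            it = np.nditer(num, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                up = {k: v.copy() for k, v in base.items()}
                up[key][i] += eps
                dn = {k: v.copy() for k, v in base.items()}
                dn[key][i] -= eps
                num[i] = (loss(up) - loss(dn)) / (2 * eps)
            np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-7)


class TestPredict:
    def test_probabilities_sum_to_one(self, trained_small_lf):
        model, prep = trained_small_lf
        probs = predict_proba(model, prep)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_zero_weight_model_is_maximally_uncertain(self):
        cfg = ModelConfig(k=2, l_filt=3, seed=0)
        m = build_model("LF", 4, 20, cfg)
        for key in m.params:
            m.params[key] = np.zeros_like(m.params[key])
        probs = predict_proba(m, toy_epochs(10, 4, 20))
        np.testing.assert_allclose(probs, 0.5, atol=1e-7)

    def test_softmax_shift_invariance(self):
        cfg = ModelConfig(k=2, l_filt=3, seed=3)
        m = build_model("LF", 4, 20, cfg)
        ep = toy_epochs(10, 4, 20)
        before = predict_proba(m, ep)
        m.params["b_out"] = m.params["b_out"] + 7.3  # same constant on both logits
        np.testing.assert_allclose(predict_proba(m, ep), before, atol=1e-5)

    def test_shape_mismatch_rejected(self, trained_small_lf):
        model, _ = trained_small_lf
        with pytest.raises(InvalidArchitectureError):
            predict_proba(model, toy_epochs(4, 3, 10))


class TestTraining:
    def test_separable_data_reaches_perfect_training_auc(self):
        from megfix.evaluation import roc_auc

        ep = toy_epochs(200, 6, 30, separation=4.0, seed=1)
        cfg = ModelConfig(k=4, l_filt=5, max_iterations=800, batch_size=50, seed=2)
        m = build_model("LF", 6, 30, cfg)
        train(m, ep, ep, cfg)
        assert m.trace.max() == 1.0

    def test_same_seed_identical_weights(self):
        ep = toy_epochs(60, 5, 24, separation=1.0, seed=4)
        va = toy_epochs(20, 5, 24, separation=1.0, seed=5)
        cfg = ModelConfig(k=3, l_filt=5, max_iterations=40, batch_size=30, seed=9)
        runs = []
        for _ in range(2):
            m = build_model("VAR", 5, 24, cfg)
            train(m, ep, va, cfg)
            runs.append(m.params)
        for key in runs[0]:
            np.testing.assert_array_equal(runs[0][key], runs[1][key])

    def test_single_class_training_rejected(self):
        ep = toy_epochs(20, 4, 20)
        ep.labels[:] = 1
        cfg = ModelConfig(k=2, l_filt=3, max_iterations=5, seed=0)
        with pytest.raises(DegenerateTrainingError):
            train(build_model("LF", 4, 20, cfg), ep, None, cfg)

    def test_trace_recorded_every_iteration(self, trained_small_lf):
        model, _ = trained_small_lf
        assert len(model.trace) == model.config.max_iterations
        assert np.all((model.trace >= 0) & (model.trace <= 1))

    def test_stronger_l1_gives_smaller_conv_weight_norm(self):
        ep = toy_epochs(120, 6, 30, separation=0.8, seed=6)
        norms = []
        for l1 in (0.0, 3e-3):
            cfg = ModelConfig(k=3, l_filt=5, max_iterations=200, batch_size=60, l1_penalty=l1, seed=7)
            m = build_model("LF", 6, 30, cfg)
            train(m, ep, None, cfg)
            norms.append(np.abs(m.W).sum() + np.abs(m.temporal_filters).sum())
        assert norms[1] < norms[0]

    def test_lf_predictions_invariant_to_source_permutation(self, trained_small_lf):
        model, prep = trained_small_lf
        before = predict_proba(model, prep)
        perm = np.random.default_rng(0).permutation(model.config.k)
        model.params["W"] = model.params["W"][:, perm]
        model.params["H"] = model.params["H"][perm]
        model.params["b_temp"] = model.params["b_temp"][perm]
        model.params["w_out"] = model.params["w_out"][:, perm, :]
        after = predict_proba(model, prep)
        inv = np.argsort(perm)
        model.params["W"] = model.params["W"][:, inv]
        model.params["H"] = model.params["H"][inv]
        model.params["b_temp"] = model.params["b_temp"][inv]
        model.params["w_out"] = model.params["w_out"][:, inv, :]
        np.testing.assert_allclose(after, before, atol=1e-5)


class TestCheckpoint:
    def test_save_load_roundtrip(self, trained_small_lf, tmp_path):
        model, prep = trained_small_lf
        path = tmp_path / "model.h5"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.variant == model.variant
        assert loaded.config == model.config
        np.testing.assert_array_equal(loaded.W, model.W)
        np.testing.assert_allclose(predict_proba(loaded, prep), predict_proba(model, prep))
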