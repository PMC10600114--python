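"""Neural surrogate generators: codec, pairing, training mechanics, rollout."""

import warnings

import numpy as np
import pytest

from cestgen.dictionary import random_corpus
from cestgen.presets import load_preset
from cestgen.surrogate import (
    BOOTSTRAP_SIGNAL,
    AppOptimizedSurrogate,
    DynamicSurrogate,
    FeatureCodec,
    load_model,
    make_training_pairs,
    rollout_dynamic,
    save_model,
)


@pytest.fixture(scope="module")
def small_corpus():
    preset = load_preset("l-arginine", 9.4)
    return random_corpus(preset, 120, seed=5)


@pytest.fixture(scope="module")
def tiny_dynamic_model(small_corpus):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DynamicSurrogate(max_epochs=15, random_state=0).fit(small_corpus)


# ---------------------------------------------------------------------------
# codec


def test_codec_scaling_is_affine_and_invertible():
    codec = FeatureCodec(("a", "b"), np.array([0.0, 10.0]),
                         np.array([2.0, 30.0]))
    x = np.array([[1.0, 20.0], [0.0, 10.0], [2.0, 30.0]])
    xs = codec.transform(x)
    assert np.allclose(xs, [[0.5, 0.5], [0.0, 0.0], [1.0, 1.0]])
    # invertible on the declared range
    assert np.allclose(xs * (codec.hi - codec.lo) + codec.lo, x)


def test_codec_constant_feature_maps_to_half():
    codec = FeatureCodec(("c",), np.array([5.0]), np.array([5.0]))
    assert np.allclose(codec.transform(np.array([[5.0]])), 0.5)


def test_codec_clamps_out_of_range_with_warning():
    codec = FeatureCodec(("a",), np.array([0.0]), np.array([1.0]))
    with pytest.warns(UserWarning, match="clamped"):
        xs = codec.transform(np.array([[2.0], [-1.0]]))
    assert np.allclose(xs.ravel(), [1.0, 0.0])


# ---------------------------------------------------------------------------
# training pairs


def test_dynamic_pair_count_includes_bootstrap(small_corpus):
    one = small_corpus.subset([0])
    names, x, y = make_training_pairs(one, "dynamic")
    assert x.shape == (30, len(names))        # 29 consecutive + 1 bootstrap
    s_prev = x[:, names.index("s_prev")]
    first = x[:, names.index("first_cycle")]
    assert s_prev[0] == BOOTSTRAP_SIGNAL and first[0] == 1.0
    assert np.allclose(s_prev[1:], one.signals[0, :-1])
    assert np.allclose(first[1:], 0.0)
    assert np.allclose(y, one.signals[0])


def test_app_optimized_pair_is_whole_trajectory():
    preset = load_preset("seven-pool-brain", 4.7)
    d = random_corpus(preset, 2, seed=1)
    names, x, y = make_training_pairs(d, "app-optimized")
    assert x.shape == (2, len(names))
    assert y.shape == (2, 34)
    assert "n_p" in names and "s_prev" not in names


def test_pair_table_is_deterministic(small_corpus):
    _, x1, y1 = make_training_pairs(small_corpus, "dynamic")
    _, x2, y2 = make_training_pairs(small_corpus, "dynamic")
    assert np.array_equal(x1, x2) and np.array_equal(y1, y2)


# ---------------------------------------------------------------------------
# training mechanics


def test_overfit_capacity_on_tiny_pair_set():
    """Without early stopping the network memorizes a tiny pair set: the
    training loss falls orders of magnitude below the best achievable
    generalization error at this corpus size."""
    preset = load_preset("l-arginine", 9.4)
    d = random_corpus(preset, 4, seed=8)  # 120 dynamic pairs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = DynamicSurrogate(
            early_stopping=False, max_epochs=6000, learning_rate_init=1e-2,
            batch_size=120, patience=6000, random_state=0,
        ).fit(d)
    assert m.loss_curve_[-1] < 5e-4
    assert m.loss_curve_[-1] < 1e-3 * m.loss_curve_[0]


def test_early_stopping_selects_best_validation(tiny_dynamic_model):
    m = tiny_dynamic_model
    # sklearn scores are R^2: the selected score is the running maximum
    assert m.best_validation_score_ >= m.validation_scores_[0]
    assert m.best_validation_score_ == max(m.validation_scores_)


def test_architecture_defaults_match_training_recipe():
    m = DynamicSurrogate()
    assert m.hidden_layer_sizes == (256, 256)
    assert m.activation == "logistic"
    assert m.learning_rate_init == 1e-4
    assert m.batch_size == 2048
    assert m.validation_fraction == 0.1
    fitted = DynamicSurrogate(max_epochs=2, random_state=0)
    preset = load_preset("amide", 9.4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted.fit(random_corpus(preset, 30, seed=0))
    shapes = [w.shape for w, _ in fitted.weights_]
    assert shapes == [(fitted.n_features_in_, 256), (256, 256), (256, 1)]


# ---------------------------------------------------------------------------
# inference


def test_rollout_is_deterministic_and_respects_length(tiny_dynamic_model,
                                                      small_corpus):
    m = tiny_dynamic_model
    p1 = m.predict(small_corpus)
    p2 = m.predict(small_corpus)
    assert np.array_equal(p1, p2)
    assert p1.shape == small_corpus.signals.shape
    assert (p1 >= 0).all() and (p1 <= 1).all()


def test_rollout_accepts_arbitrary_protocol_length(tiny_dynamic_model):
    from cestgen.sequences import uniform_protocol

    protocol = uniform_protocol(9.4, [2.0], 3.0, tp_s=3.0, trec_s=3.0,
                                fa_deg=90.0)
    params = {"water.t1_s": 2.5, "water.t2_s": 0.8, "solute.t1_s": 2.5,
              "solute.t2_s": 0.01, "solute.f": 1e-3, "solute.k_sw": 400.0}
    out = rollout_dynamic(tiny_dynamic_model, params, protocol)
    assert out.shape == (1, 1)
    longer = uniform_protocol(9.4, np.full(57, 2.0), 3.0, tp_s=3.0,
                              trec_s=3.0, fa_deg=90.0)
    assert rollout_dynamic(tiny_dynamic_model, params, longer).shape == (1, 57)


def test_static_inference_batching_invariance():
    preset = load_preset("seven-pool-brain", 4.7)
    d = random_corpus(preset, 40, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = AppOptimizedSurrogate(max_epochs=10, random_state=0,
                                  validation_fraction=0.25).fit(d)
    batched = m.infer_static(d.params)
    assert batched.shape == (40, 34)
    rows = np.vstack([m.infer_static(d.params.iloc[[i]]) for i in range(40)])
    assert np.abs(batched - rows).max() < 1e-6


def test_static_model_rejects_missing_features(small_corpus,
                                               tiny_dynamic_model):
    m = AppOptimizedSurrogate()
    with pytest.raises(RuntimeError):
        m.infer_static(small_corpus.params)  # not fitted


def test_checkpoint_round_trip(tmp_path, tiny_dynamic_model, small_corpus):
    path = tmp_path / "model.npz"
    save_model(tiny_dynamic_model, path)
    back = load_model(path)
    assert isinstance(back, DynamicSurrogate)
    assert back.codec_.names == tiny_dynamic_model.codec_.names
    assert np.array_equal(back.predict(small_corpus),
                          tiny_dynamic_model.predict(small_corpus))


def test_get_set_params_round_trip():
    m = DynamicSurrogate(max_epochs=7, patience=3)
    params = m.get_params()
    assert params["max_epochs"] == 7
    m2 = DynamicSurrogate().set_params(**params)
    assert m2.get_params() == params
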