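"""Training loop semantics, gradient correctness, and prediction contracts."""

import numpy as np
import pytest

from snapqsar.errors import SnapQsarError
from snapqsar.trainer import (ARCHITECTURES, Hyperparams, TrainedModel,
                              _softmax, cross_entropy, preprocess_images,
                              train)


def toy_imageset(n_per_class=12, size=8, seed=0, separation=0.6):
    """Two Gaussian-blob image classes, linearly separable by mean colour."""
    rng = np.random.default_rng(seed)
    x, y = [], []
    for label in (0, 1):
        base = np.zeros(3)
        base[label] = separation  # class 1 is red-shifted, class 0 not
        for _ in range(n_per_class):
            img = np.clip(rng.normal(0.3, 0.1, (size, size, 3)) + base, 0, 1)
            x.append(img)
            y.append(label)
    return np.array(x), np.array(y)


# ---------------------------------------------------------------------------
# gradient correctness (finite differences through the whole stack)

@pytest.mark.parametrize("arch", ["tinycnn", "pixellr"])
def test_backprop_matches_finite_differences(arch):
    rng = np.random.default_rng(3)
    size = 8
    layers = ARCHITECTURES[arch](size, rng)
    x = rng.random((4, size, size, 3))
    y = np.array([0, 1, 1, 0])

    def loss_value():
        h = x
        for layer in layers:
            if hasattr(layer, "training"):
                layer.training = True
            h = layer.forward(h)
        p = _softmax(h)
        return -np.mean(np.log(p[np.arange(4), y]))

    # analytic gradients
    base = loss_value()
    h = x
    for layer in layers:
        h = layer.forward(h)
    p = _softmax(h)
    g = p.copy()
    g[np.arange(4), y] -= 1.0
    g /= 4.0
    for layer in reversed(layers):
        g = layer.backward(g)

    eps = 1e-6
    checked = 0
    for layer in layers:
        for key, param in layer.params.items():
            flat = param.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = layer.grads[key].ravel()[idx]
                assert analytic == pytest.approx(numeric, abs=2e-4)
                checked += 1
    assert checked >= 6


# ---------------------------------------------------------------------------
# training-loop semantics

def test_patience_zero_runs_all_epochs():
    x, y = toy_imageset()
    hp = Hyperparams(learning_rate=1e-2, batch_size=8, max_epochs=5,
                     patience=0, input_size=8)
    _, history = train(x, y, x, y, hp, arch="pixellr", seed=0)
    assert history.n_epochs == 5


def test_selected_epoch_is_argmin_of_valid_loss():
    x, y = toy_imageset()
    hp = Hyperparams(learning_rate=1e-2, batch_size=8, max_epochs=6,
                     patience=0, input_size=8)
    _, history = train(x, y, x, y, hp, arch="pixellr", seed=1)
    assert history.selected_epoch == int(np.argmin(history.loss_valid)) + 1


def test_early_stopping_halts_after_patience():
    x, y = toy_imageset()
    # absurd learning rate forces divergence, so valid loss stops improving
    hp = Hyperparams(learning_rate=50.0, batch_size=8, max_epochs=30,
                     patience=2, input_size=8)
    _, history = train(x, y, x, y, hp, arch="pixellr", seed=0)
    assert history.n_epochs < 30
    best = int(np.argmin(history.loss_valid))
    assert history.n_epochs <= best + 1 + 2  # last improvement + patience


def test_training_reduces_loss_and_reaches_separable_accuracy():
    x, y = toy_imageset(n_per_class=20)
    hp = Hyperparams(learning_rate=1e-2, batch_size=8, max_epochs=20,
                     patience=0, input_size=8)
    model, history = train(x, y, x, y, hp, arch="tinycnn", seed=0)
    assert history.loss_train[history.selected_epoch - 1] <= history.loss_train[0]
    acc = ((model.predict_proba(x) >= 0.5) == y).mean()
    assert acc >= 0.95


def test_history_reproducible_for_fixed_seed():
    x, y = toy_imageset()
    hp = Hyperparams(learning_rate=1e-2, batch_size=8, max_epochs=4,
                     patience=0, input_size=8)
    _, h1 = train(x, y, x, y, hp, arch="tinycnn", seed=7)
    _, h2 = train(x, y, x, y, hp, arch="tinycnn", seed=7)
    assert np.allclose(h1.loss_train, h2.loss_train, atol=1e-5)
    assert np.allclose(h1.loss_valid, h2.loss_valid, atol=1e-5)
    assert h1.selected_epoch == h2.selected_epoch


def test_single_class_training_rejected():
    x, y = toy_imageset()
    with pytest.raises(SnapQsarError):
        train(x, np.zeros(len(x), dtype=int), x, y,
              Hyperparams(input_size=8), arch="pixellr", seed=0)


def test_unknown_architecture_rejected():
    x, y = toy_imageset()
    with pytest.raises(SnapQsarError, match="architecture"):
        train(x, y, x, y, Hyperparams(input_size=8), arch="resnet152", seed=0)


# ---------------------------------------------------------------------------
# prediction contracts

def trained_toy_model(seed=0):
    x, y = toy_imageset()
    hp = Hyperparams(learning_rate=1e-2, batch_size=8, max_epochs=3,
                     patience=0, input_size=8)
    model, _ = train(x, y, x, y, hp, arch="tinycnn", seed=seed)
    return model, x, y


def test_probabilities_in_unit_interval_and_deterministic():
    model, x, _ = trained_toy_model()
    p1 = model.predict_proba(x)
    p2 = model.predict_proba(x)
    assert np.all((p1 >= 0) & (p1 <= 1))
    assert np.array_equal(p1, p2)


def test_duplicated_image_gets_identical_probability():
    model, x, _ = trained_toy_model()
    batch = np.stack([x[0], x[3], x[0]])
    p = model.predict_proba(batch)
    assert p[0] == p[2]


def test_shape_mismatch_raises():
    model, x, _ = trained_toy_model()
    with pytest.raises(ValueError):
        model.predict_proba(np.zeros((2, 16, 16, 3)))


def test_fresh_model_is_roughly_calibrated():
    rng = np.random.default_rng(0)
    layers = ARCHITECTURES["tinycnn"](8, rng)
    model = TrainedModel("tinycnn", layers, 8)
    x, _ = toy_imageset()
    assert 0.2 <= model.predict_proba(x).mean() <= 0.8


def test_model_save_load_roundtrip(tmp_path):
    model, x, _ = trained_toy_model()
    path = tmp_path / "ckpt.npz"
    model.save(path)
    clone = TrainedModel.load(path)
    assert np.allclose(model.predict_proba(x), clone.predict_proba(x))
    assert clone.selected_epoch == model.selected_epoch


# ---------------------------------------------------------------------------
# preprocessing

def test_preprocess_box_filter_conserves_mass():
    # a single bright pixel must survive an 8x downsample as a dimmer pixel
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    img[5, 5] = (255, 0, 0)
    small = preprocess_images([img], 8)[0]
    assert small[..., 0].sum() > 0


def test_cross_entropy_of_perfect_prediction_is_small():
    assert cross_entropy([1.0, 0.0], [1, 0]) < 1e-9
    assert cross_entropy([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2))
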