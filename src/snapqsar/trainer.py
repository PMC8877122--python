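"""Image-classifier training with early stopping and best-epoch selection.

The classifier consumes snapshot PNGs and produces a per-image probability of
the active class.  Training runs plain stochastic gradient descent with
momentum 0.9 at a constant learning rate for at most ``max_epochs`` epochs
(default 30); an early-stopping rule halts when the validation loss has not
improved for ``patience`` consecutive epochs, and the returned model is the
checkpoint from the epoch with the lowest validation loss.

The networks are implemented directly on numpy (im2col convolutions, ReLU,
max/global-average pooling, softmax cross-entropy), which keeps training
bit-reproducible for a fixed seed on a fixed machine.  Two architectures are
registered:

``tinycnn``
    3 conv blocks (8/16/32 filters, 3x3, max-pool) + global average pool +
    2-class head.  The desk-scale default.
``pixellr``
    multinomial logistic regression on raw pixels; the linear baseline.

Class imbalance is handled by optional inverse-frequency class weights in
the training loss (recorded train/valid losses are the unweighted mean
cross-entropy, so histories are comparable across weighting choices).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from .errors import SnapQsarError

DEFAULT_INPUT_SIZE = 64  # snapshots are downsampled to this edge length


@dataclass
class Hyperparams:
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 30
    patience: int = 5  # 0 disables early stopping
    momentum: float = 0.9
    class_weights: bool = True
    input_size: int = DEFAULT_INPUT_SIZE

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class TrainHistory:
    loss_train: list[float] = field(default_factory=list)
    loss_valid: list[float] = field(default_factory=list)
    selected_epoch: int = 0  # 1-based arg-min of loss_valid

    @property
    def n_epochs(self) -> int:
        return len(self.loss_valid)


# ---------------------------------------------------------------------------
# layers

class _Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # x: (N, H, W, C), already padded; returns (N, OH, OW, kh*kw*C)
    n, h, w, c = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, kh, kw, c), strides=(s0, s1, s2, s1, s2, s3))
    return cols.reshape(n, oh, ow, kh * kw * c)


class _Conv3x3(_Layer):
    """3x3 same-padding convolution."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = 9 * c_in
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in), (9 * c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.c_in = c_in
        self.c_out = c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._cols = _im2col(xp, 3, 3)  # (N, H, W, 9*Cin)
        self._in_shape = x.shape
        return self._cols @ self.params["w"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, _ = g.shape
        cols2d = self._cols.reshape(-1, self._cols.shape[-1])
        g2d = g.reshape(-1, self.c_out)
        self.grads = {"w": cols2d.T @ g2d, "b": g2d.sum(axis=0)}
        gcols = (g2d @ self.params["w"].T).reshape(n, h, w, 3, 3, self.c_in)
        gx = np.zeros((n, h + 2, w + 2, self.c_in))
        for di in range(3):
            for dj in range(3):
                gx[:, di:di + h, dj:dj + w] += gcols[:, :, :, di, dj]
        return gx[:, 1:-1, 1:-1]


class _ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class _BatchNorm(_Layer):
    """Per-channel batch normalisation over (N, H, W).

    Keeps exponential running statistics for inference; ``training`` toggles
    between batch and running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))  # all but the channel axis
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        axes = tuple(range(g.ndim - 1))
        self.grads = {"gamma": (g * self._xhat).sum(axis=axes),
                      "beta": g.sum(axis=axes)}
        gx = self.params["gamma"] * self._istd * (
            g - g.mean(axis=axes)
            - self._xhat * (g * self._xhat).mean(axis=axes))
        return gx


class _MaxPool2(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._in_shape = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._argmask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        # ties share the gradient equally, keeping backward deterministic
        counts = self._argmask.sum(axis=(2, 4), keepdims=True)
        spread = self._argmask * (g[:, :, None, :, None, :] / counts)
        n, h, w, c = self._in_shape
        return spread.reshape(n, h, w, c)


class _GlobalAvgPool(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        return np.broadcast_to(g[:, None, None, :] / (h * w), self._in_shape).copy()


class _Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._in_shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads = {"w": self._x.T @ g, "b": g.sum(axis=0)}
        return g @ self.params["w"].T


def _build_tinycnn(input_size: int, rng: np.random.Generator) -> list[_Layer]:
    if input_size % 4 != 0:
        raise ValueError("tinycnn needs an input size divisible by 4")
    return [
        _Conv3x3(3, 8, rng), _BatchNorm(8), _ReLU(), _MaxPool2(),
        _Conv3x3(8, 16, rng), _BatchNorm(16), _ReLU(), _MaxPool2(),
        _Conv3x3(16, 32, rng), _BatchNorm(32), _ReLU(), _GlobalAvgPool(),
        _Dense(32, 2, rng),
    ]


def _build_pixellr(input_size: int, rng: np.random.Generator) -> list[_Layer]:
    return [_Flatten(), _Dense(input_size * input_size * 3, 2, rng)]


ARCHITECTURES: dict[str, Callable[[int, np.random.Generator], list[_Layer]]] = {
    "tinycnn": _build_tinycnn,
    "pixellr": _build_pixellr,
}


# ---------------------------------------------------------------------------
# model

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TrainedModel:
    """An architecture plus weights; maps images to active-class probabilities.

    ``norm_mean``/``norm_std`` are the per-channel input statistics of the
    training set; ``predict_proba`` standardises its input with them, so the
    model is self-contained at inference.
    """

    def __init__(self, arch: str, layers: list[_Layer], input_size: int,
                 selected_epoch: int = 0):
        self.arch = arch
        self.layers = layers
        self.input_size = input_size
        self.selected_epoch = selected_epoch
        self.norm_mean = np.zeros(3)
        self.norm_std = np.ones(3)

    def _set_training(self, flag: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.training = flag

    def _forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Active-class probability per image.

        ``images`` is (N, S, S, 3) float in [0, 1] at the model's input size.
        """
        x = np.asarray(images, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.input_size \
                or x.shape[2] != self.input_size or x.shape[3] != 3:
            raise ValueError(
                f"expected (N, {self.input_size}, {self.input_size}, 3) images, "
                f"got {x.shape}")
        self._set_training(False)
        x = (x - self.norm_mean) / self.norm_std
        return _softmax(self._forward(x))[:, 1]

    def state_dict(self) -> dict:
        state = {f"{i}.{k}": v for i, layer in enumerate(self.layers)
                 for k, v in layer.params.items()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm):
                state[f"{i}.run_mean"] = layer.run_mean
                state[f"{i}.run_var"] = layer.run_var
        state["norm_mean"] = self.norm_mean
        state["norm_std"] = self.norm_std
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = np.array(state[f"{i}.{k}"])
            if isinstance(layer, _BatchNorm):
                layer.run_mean = np.array(state[f"{i}.run_mean"])
                layer.run_var = np.array(state[f"{i}.run_var"])
        self.norm_mean = np.array(state["norm_mean"])
        self.norm_std = np.array(state["norm_std"])

    def save(self, path: str | Path) -> None:
        np.savez(path, __arch__=self.arch, __input_size__=self.input_size,
                 __selected_epoch__=self.selected_epoch, **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = np.load(path)
        arch = str(data["__arch__"])
        input_size = int(data["__input_size__"])
        layers = ARCHITECTURES[arch](input_size, np.random.default_rng(0))
        model = cls(arch, layers, input_size,
                    selected_epoch=int(data["__selected_epoch__"]))
        model.load_state_dict({k: data[k] for k in data.files
                               if not k.startswith("__")})
        return model


def preprocess_images(images: Sequence[np.ndarray] | np.ndarray,
                      input_size: int = DEFAULT_INPUT_SIZE) -> np.ndarray:
    """Resize uint8 RGB rasters to the model input size and scale to [0, 1].

    Downsampling uses a box (area-average) filter so that small colour
    features survive large reductions instead of falling between the sample
    points of an interpolating filter.
    """
    out = np.empty((len(images), input_size, input_size, 3))
    for i, img in enumerate(images):
        pil = Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB")
        if pil.size != (input_size, input_size):
            pil = pil.resize((input_size, input_size), Image.BOX)
        out[i] = np.asarray(pil, dtype=np.float64) / 255.0
    return out


def cross_entropy(probs: np.ndarray, labels: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Unweighted mean binary cross-entropy of active-class probabilities."""
    p = np.clip(np.asarray(probs, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


def train(train_images: np.ndarray, train_labels: np.ndarray,
          valid_images: np.ndarray, valid_labels: np.ndarray,
          hp: Hyperparams | None = None, arch: str = "tinycnn",
          seed: int = 0) -> tuple[TrainedModel, TrainHistory]:
    """Fit a classifier, returning the lowest-valid-loss checkpoint.

    ``*_images`` are preprocessed arrays (N, S, S, 3) in [0, 1]; labels are
    0/1 with 1 = active.  Both partitions must contain both classes.
    """
    hp = hp or Hyperparams()
    train_labels = np.asarray(train_labels, dtype=int)
    valid_labels = np.asarray(valid_labels, dtype=int)
    if len(train_images) == 0 or len(valid_images) == 0:
        raise SnapQsarError("train and valid partitions must be non-empty")
    if len(set(train_labels.tolist())) < 2:
        raise SnapQsarError("training partition contains a single class")
    if arch not in ARCHITECTURES:
        raise SnapQsarError(
            f"unknown architecture {arch!r}; choose from {sorted(ARCHITECTURES)}")

    rng = np.random.default_rng(seed)
    layers = ARCHITECTURES[arch](hp.input_size, rng)
    model = TrainedModel(arch, layers, hp.input_size)

    if hp.class_weights:
        counts = np.bincount(train_labels, minlength=2).astype(float)
        w_class = len(train_labels) / (2.0 * counts)
    else:
        w_class = np.ones(2)

    velocity = {i: {k: np.zeros_like(v) for k, v in layer.params.items()}
                for i, layer in enumerate(layers)}
    x_train = np.asarray(train_images, dtype=np.float64)
    x_valid = np.asarray(valid_images, dtype=np.float64)

    # per-channel standardisation from the training set, stored on the model
    model.norm_mean = x_train.mean(axis=(0, 1, 2))
    model.norm_std = x_train.std(axis=(0, 1, 2)) + 1e-8
    x_train_n = (x_train - model.norm_mean) / model.norm_std

    history = TrainHistory()
    best_loss = np.inf
    best_state: dict | None = None
    since_improve = 0

    for epoch in range(1, hp.max_epochs + 1):
        order = rng.permutation(len(x_train))
        model._set_training(True)
        for start in range(0, len(order), hp.batch_size):
            idx = order[start:start + hp.batch_size]
            xb, yb = x_train_n[idx], train_labels[idx]
            logits = model._forward(xb)
            probs = _softmax(logits)
            wb = w_class[yb]
            # weighted softmax cross-entropy gradient
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            grad *= (wb / wb.sum())[:, None]
            for layer in reversed(layers):
                grad = layer.backward(grad)
            for i, layer in enumerate(layers):
                for k, p in layer.params.items():
                    v = velocity[i][k]
                    v *= hp.momentum
                    v -= hp.learning_rate * layer.grads[k]
                    p += v

        loss_tr = cross_entropy(model.predict_proba(x_train), train_labels)
        loss_va = cross_entropy(model.predict_proba(x_valid), valid_labels)
        history.loss_train.append(loss_tr)
        history.loss_valid.append(loss_va)

        if loss_va < best_loss:
            best_loss = loss_va
            best_state = copy.deepcopy(model.state_dict())
            since_improve = 0
        else:
            since_improve += 1
        if hp.patience > 0 and since_improve >= hp.patience:
            break

    history.selected_epoch = int(np.argmin(history.loss_valid)) + 1
    if best_state is not None:
        model.load_state_dict(best_state)
    model.selected_epoch = history.selected_epoch
    return model, history
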