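"""Output-stage classifiers: multi-class perceptron, MLP, and CNN.

These are the MSTd-analogue read-outs.  The perceptron (model 1) uses the
classic mistake-driven update: on an error the true class's weight vector
gains the input and the predicted class's loses it, so the total weight
mass over classes is conserved.  The MLP (model 2) is a
2048-256-156-50-4 fully connected network with logistic hidden units and a
softmax output trained by full-batch gradient descent on cross-entropy.
The CNN (model 3) reads the 480x480 concatenated velocity-mosaic response
through one 36-channel convolution (10x10 kernels, stride 10, no padding ->
48x48x36), four fully connected layers (350, 150, 150, 100) and an 8-way
softmax, trained with minibatch SGD.

Everything is plain numpy; the convolution's non-overlapping stride makes
it a block reshape plus matmul.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# multi-class perceptron
# ---------------------------------------------------------------------------

@dataclass
class Perceptron:
    """Multi-class perceptron with a constant bias feature."""

    W: np.ndarray  # (k, d + 1)
    classes: np.ndarray

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xb = np.hstack([X, np.ones((len(X), 1))])
        return Xb @ self.W.T

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[self.scores(np.atleast_2d(X)).argmax(axis=1)]


def perceptron_train(
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 500,
    seed=None,
    classes=None,
) -> Perceptron:
    """Mistake-driven training; examples are presented in random order.

    D = argmax_y W^y . x; on error W^true += x and W^pred -= x (tau = +1 /
    -1 / 0), which leaves sum_y W^y invariant.  Weights start at zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    class_index = {c: i for i, c in enumerate(classes)}
    yi = np.array([class_index[v] for v in y])
    Xb = np.hstack([X, np.ones((len(X), 1))])
    W = np.zeros((len(classes), Xb.shape[1]))
    rng = np.random.default_rng(seed)
    idx = np.arange(len(Xb))
    for _ in range(epochs):
        rng.shuffle(idx)
        errors = 0
        for i in idx:
            d = int((W @ Xb[i]).argmax())
            if d != yi[i]:
                W[yi[i]] += Xb[i]
                W[d] -= Xb[i]
                errors += 1
        if errors == 0:
            break
    return Perceptron(W=W, classes=np.asarray(classes))


def perceptron_accuracy(model: Perceptron, X, y) -> float:
    return float((model.predict(np.asarray(X, dtype=float)) == np.asarray(y)).mean())


# ---------------------------------------------------------------------------
# multi-layer perceptron
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class MLP:
    """Fully connected network, logistic hidden layers, softmax output."""

    weights: list  # [(W, b)] per layer
    layer_sizes: tuple

    def forward(self, X: np.ndarray):
        """Return per-layer activations; the last entry is the softmax output."""
        acts = [np.asarray(X, dtype=float)]
        h = acts[0]
        for li, (W, b) in enumerate(self.weights):
            z = h @ W + b
            h = _softmax(z) if li == len(self.weights) - 1 else _logistic(z)
            acts.append(h)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.atleast_2d(X))[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def mlp_init(layer_sizes=(2048, 256, 156, 50, 4), seed=None) -> MLP:
    rng = np.random.default_rng(seed)
    weights = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(
            (rng.uniform(-lim, lim, size=(fan_in, fan_out)), np.zeros(fan_out))
        )
    return MLP(weights=weights, layer_sizes=tuple(layer_sizes))


def mlp_train(
    X: np.ndarray,
    y: np.ndarray,
    layer_sizes=(2048, 256, 156, 50, 4),
    epochs: int = 5000,
    lr: float = 0.1,
    seed=None,
) -> MLP:
    """Full-batch gradient descent on mean cross-entropy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    model = mlp_init(layer_sizes, seed)
    n, k = len(X), layer_sizes[-1]
    Y = np.zeros((n, k))
    Y[np.arange(n), y] = 1.0
    for ep in range(epochs):
        acts = model.forward(X)
        out = acts[-1]
        if not np.all(np.isfinite(out)):
            raise DivergenceError(f"non-finite output at epoch {ep} (lr={lr}, seed={seed})")
        delta = (out - Y) / n  # softmax + cross-entropy
        for li in range(len(model.weights) - 1, -1, -1):
            W, b = model.weights[li]
            h = acts[li]
            gW = h.T @ delta
            gb = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ W.T) * acts[li] * (1.0 - acts[li])
            model.weights[li] = (W - lr * gW, b - lr * gb)
    return model


def mlp_accuracy(model: MLP, X, y) -> float:
    return float((model.predict(np.asarray(X, dtype=float)) == np.asarray(y)).mean())


# ---------------------------------------------------------------------------
# convolutional network
# ---------------------------------------------------------------------------

@dataclass
class CNNConfig:
    in_side: int = 480
    kernel: int = 10  # stride == kernel: non-overlapping blocks -> 48x48 maps
    n_maps: int = 36
    fc_sizes: tuple = (350, 150, 150, 100)
    n_classes: int = 8
    lr: float = 0.01
    batch_size: int = 20
    epochs: int = 350
    momentum: float = 0.9  # classical SGD momentum

    @property
    def conv_side(self) -> int:
        return self.in_side // self.kernel


@dataclass
class CNN:
    """conv1 (ReLU) -> fc1..fc4 (ReLU) -> softmax, float32 SGD.

    Inputs are zero-centered with the training-set mean image before the
    convolution (stored in ``mu``).
    """

    config: CNNConfig
    K: np.ndarray  # (kernel*kernel, n_maps)
    bK: np.ndarray  # (n_maps,)
    fc: list  # [(W, b)] for fc1..fc4 and the output layer
    mu: np.ndarray | None = None  # training mean image (zero-center normalization)
    _vel: dict | None = None  # momentum buffers (training only)

    def _blocks(self, X: np.ndarray) -> np.ndarray:
        """(B, side, side) -> (B, conv_side^2, kernel^2) non-overlapping blocks."""
        c = self.config
        B = X.shape[0]
        return (
            X.reshape(B, c.conv_side, c.kernel, c.conv_side, c.kernel)
            .transpose(0, 1, 3, 2, 4)
            .reshape(B, c.conv_side * c.conv_side, c.kernel * c.kernel)
        )

    def forward(self, X: np.ndarray):
        """Per-layer activations: [blocks, conv1, fc1..fc4, softmax]."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if self.mu is not None:
            X = X - self.mu
        blocks = self._blocks(X)
        conv = np.maximum(blocks @ self.K + self.bK, 0.0)  # (B, S^2, n_maps)
        acts = [blocks, conv]
        h = conv.reshape(len(X), -1)
        for li, (W, b) in enumerate(self.fc):
            z = h @ W + b
            h = _softmax(z) if li == len(self.fc) - 1 else np.maximum(z, 0.0)
            acts.append(h)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def layer_activations(self, X: np.ndarray) -> dict:
        """Named activations for analysis: conv1 maps, fc4, channel maxima.

        conv1 has shape (B, conv_side, conv_side, n_maps); ``conv1_max``
        holds per-channel maxima (B, n_maps); fc4 is the last hidden layer
        (B, 100).
        """
        c = self.config
        acts = self.forward(X)
        conv = acts[1].reshape(-1, c.conv_side, c.conv_side, c.n_maps)
        return {
            "conv1": conv,
            "conv1_max": conv.reshape(len(conv), -1, c.n_maps).max(axis=1),
            "fc4": acts[-2],
        }


def cnn_init(config: CNNConfig | None = None, seed=None) -> CNN:
    config = config or CNNConfig()
    rng = np.random.default_rng(seed)

    def he(fan_in, shape):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    K = he(config.kernel**2, (config.kernel**2, config.n_maps))
    bK = np.zeros(config.n_maps, dtype=np.float32)
    sizes = (
        [config.conv_side**2 * config.n_maps]
        + list(config.fc_sizes)
        + [config.n_classes]
    )
    fc = [
        (he(fi, (fi, fo)), np.zeros(fo, dtype=np.float32))
        for fi, fo in zip(sizes[:-1], sizes[1:])
    ]
    return CNN(config=config, K=K, bK=bK, fc=fc)


def cnn_train(
    images: np.ndarray,
    labels: np.ndarray,
    config: CNNConfig | None = None,
    seed=None,
) -> CNN:
    """Minibatch SGD with cross-entropy; shuffled batches each epoch."""
    config = config or CNNConfig()
    X = np.asarray(images, dtype=np.float32)
    y = np.asarray(labels, dtype=int)
    present = np.unique(y)
    if len(present) < config.n_classes:
        missing = sorted(set(range(config.n_classes)) - set(present.tolist()))
        raise ValueError(f"classes absent from training set: {missing}")
    model = cnn_init(config, seed)
    model.mu = X.mean(axis=0)
    model._vel = {}
    rng = np.random.default_rng(seed)
    n = len(X)
    idx = np.arange(n)
    for _ in range(config.epochs):
        rng.shuffle(idx)
        for b0 in range(0, n, config.batch_size):
            bi = idx[b0 : b0 + config.batch_size]
            _cnn_sgd_step(model, X[bi], y[bi])
    model._vel = None
    return model


def _cnn_sgd_step(model: CNN, Xb: np.ndarray, yb: np.ndarray) -> None:
    c = model.config
    acts = model.forward(Xb)
    blocks, conv = acts[0], acts[1]
    B = len(Xb)
    Y = np.zeros((B, c.n_classes), dtype=np.float32)
    Y[np.arange(B), yb] = 1.0
    delta = (acts[-1] - Y) / B
    fc_grads = [None] * len(model.fc)
    for li in range(len(model.fc) - 1, -1, -1):
        W, b = model.fc[li]
        h = acts[1].reshape(B, -1) if li == 0 else acts[li + 1]
        gW = h.T @ delta
        gb = delta.sum(axis=0)
        delta_prev = delta @ W.T
        if li > 0:
            delta = delta_prev * (acts[li + 1] > 0)
        else:
            delta_conv = delta_prev.reshape(conv.shape) * (conv > 0)
        fc_grads[li] = (gW, gb)
    BS = blocks.shape[0] * blocks.shape[1]
    gK = blocks.reshape(BS, -1).T @ delta_conv.reshape(BS, -1)
    gbK = delta_conv.sum(axis=(0, 1))
    grads = {"K": gK, "bK": gbK}
    for li, (gW, gb) in enumerate(fc_grads):
        grads[f"W{li}"] = gW
        grads[f"b{li}"] = gb
    vel = model._vel if model._vel is not None else {}
    for k, g in grads.items():
        vel[k] = c.momentum * vel.get(k, 0.0) - c.lr * g
    model.K += vel["K"]
    model.bK += vel["bK"]
    model.fc = [
        (W + vel[f"W{li}"], b + vel[f"b{li}"])
        for li, (W, b) in enumerate(model.fc)
    ]
    if model._vel is not None:
        model._vel = vel


def cnn_accuracy(model: CNN, X, y) -> float:
    return float((model.predict(X) == np.asarray(y)).mean())
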