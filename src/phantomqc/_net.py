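"""Minimal convolutional network in numpy with manual backprop.

Supports exactly what the dual-output lesion classifier needs: conv /
ReLU / max-pool / average-pool / linear layers, seeded He
initialization, SGD with momentum and weight decay, and gradients all
the way back to the input pixels (for saliency maps).  Kept deliberately
small: a ~80K-parameter backbone trains in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patch matrix, stride 1."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(cols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w = shape
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Conv:
    def __init__(self, c_in, c_out, k, rng):
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in))
        self.b = np.zeros(c_out)
        self.k, self.pad = k, k // 2
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k, self.pad)
        n, _, h, w = x.shape
        out = self.cols @ self.w.T + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, f, h, w = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(n, h * w, f)
        # incoming grads already carry the loss reduction (mean) factor
        self.gw = np.einsum("nlf,nlc->fc", g, self.cols)
        self.gb = g.sum(axis=(0, 1))
        dcols = g @ self.w
        return _col2im(dcols, self.x_shape, self.k, self.pad)

    @property
    def params(self):
        return [("w", True), ("b", False)]


class ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class MaxPool2:
    """Non-overlapping 2x2 max pool; odd trailing rows/cols dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        self.in_shape = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        xr = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h2, w2, 4)
        self.idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self.in_shape
        h2, w2 = h // 2, w // 2
        out = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(out, self.idx[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        full = np.zeros(self.in_shape)
        full[:, :, : 2 * h2, : 2 * w2] = out.reshape(n, c, 2 * h2, 2 * w2)
        return full


class AvgPool2:
    """2x2 average pool used as the 56->28 input reduction."""

    def forward(self, x):
        n, c, h, w = x.shape
        self.in_shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self.in_shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g


class Flatten:
    def forward(self, x):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.in_shape)


class Linear:
    def __init__(self, n_in, n_out, rng):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_out, n_in))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self.x = x
        return x @ self.w.T + self.b

    def backward(self, grad):
        self.gw = grad.T @ self.x
        self.gb = grad.sum(axis=0)
        return grad @ self.w

    @property
    def params(self):
        return [("w", True), ("b", False)]


class SmallCNN:
    """Default backbone: 56x56 tile -> 2 logits (exist, abnormal).

    avgpool2 -> conv5x5(8) -> relu -> pool -> conv3x3(16) -> relu ->
    pool -> conv3x3(32) -> relu -> pool -> fc(256) -> relu -> fc(2).
    About 80K parameters.
    """

    def __init__(self, seed: int = 0, hidden: int = 256):
        rng = np.random.default_rng(seed)
        self.layers = [
            AvgPool2(),
            Conv(1, 8, 5, rng),
            ReLU(),
            MaxPool2(),
            Conv(8, 16, 3, rng),
            ReLU(),
            MaxPool2(),
            Conv(16, 32, 3, rng),
            ReLU(),
            MaxPool2(),
            Flatten(),
            Linear(32 * 3 * 3, hidden, rng),
            ReLU(),
            Linear(hidden, 2, rng),
        ]
        self._velocity = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 56, 56) -> logits (N, 2)."""
        out = x[:, None, :, :].astype(float)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop from logit grads; returns grad w.r.t. input pixels
        (N, 56, 56) and leaves parameter grads on the layers."""
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad[:, 0, :, :]

    def n_params(self) -> int:
        return sum(
            getattr(layer, name).size
            for layer in self.layers
            if hasattr(layer, "params")
            for name, _ in layer.params
        )

    def sgd_step(self, lr: float, weight_decay: float, momentum: float):
        for li, layer in enumerate(self.layers):
            if not hasattr(layer, "params"):
                continue
            for name, decay in layer.params:
                p = getattr(layer, name)
                g = getattr(layer, "g" + name)
                if decay and weight_decay:
                    g = g + weight_decay * p
                key = (li, name)
                v = self._velocity.get(key)
                v = g if v is None else momentum * v + g
                self._velocity[key] = v
                p -= lr * v

    # --- portable checkpointing -------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for li, layer in enumerate(self.layers):
            if hasattr(layer, "params"):
                for name, _ in layer.params:
                    state[f"{li}.{name}"] = getattr(layer, name).copy()
        return state

    def load_state_dict(self, state: dict):
        for key, val in state.items():
            li, name = key.split(".")
            setattr(self.layers[int(li)], name, np.asarray(val, dtype=float))


def build_backbone(descriptor: str, seed: int) -> SmallCNN:
    """Build a backbone from a config string.

    ``cnn-small`` (default) or ``cnn-small:<hidden>`` to change the FC
    width.  The descriptor indirection exists so larger backbones can
    be plugged in without touching the classifier.
    """
    if descriptor.startswith("cnn-small"):
        hidden = 256
        if ":" in descriptor:
            hidden = int(descriptor.split(":", 1)[1])
        return SmallCNN(seed=seed, hidden=hidden)
    raise ValueError(f"unknown backbone descriptor {descriptor!r}")
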