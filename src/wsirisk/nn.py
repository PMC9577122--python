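"""Minimal NumPy convolutional network used as the desk-scale backbone.

Three 3x3 conv blocks with average pooling, a linear head, softmax
cross-entropy, and momentum SGD. Deterministic given a seeded generator
and single-threaded execution; small enough to train on a CPU in
seconds. A torch ResNet-18 backbone can be plugged in where available,
but nothing in the package requires it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN", "softmax_cross_entropy", "SGDMomentum"]


def _conv_forward(x, W, b):
    # x: (N, C, H, W); W: (O, C, 3, 3); 'same' padding.
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, W.shape[0], h, w))
    for i in range(3):
        for j in range(3):
            out += np.einsum("oc,nchw->nohw", W[:, :, i, j], xp[:, :, i : i + h, j : j + w])
    return out + b[None, :, None, None], xp


def _conv_backward(dout, xp, W):
    n, o, h, w = dout.shape
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            dW[:, :, i, j] = np.einsum(
                "nohw,nchw->oc", dout, xp[:, :, i : i + h, j : j + w]
            )
            dxp[:, :, i : i + h, j : j + w] += np.einsum(
                "oc,nohw->nchw", W[:, :, i, j], dout
            )
    db = dout.sum(axis=(0, 2, 3))
    return dW, db, dxp[:, :, 1:-1, 1:-1]


def _avgpool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_backward(dout):
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


def softmax_cross_entropy(logits, y):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-300)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class SmallCNN:
    """conv(3->8) -> conv(8->16) -> conv(16->32) -> linear(32->n_classes),
    each conv followed by ReLU and 2x average pooling (global for the
    last block). Input: (N, 3, 28, 28) standardized floats."""

    CHANNELS = (8, 16, 32)

    def __init__(self, rng: np.random.Generator, n_classes: int = 2, in_channels: int = 3):
        p = {}
        prev = in_channels
        for k, ch in enumerate(self.CHANNELS, start=1):
            fan_in = prev * 9
            # He-style init for conv layers.
            p[f"W{k}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(ch, prev, 3, 3))
            p[f"b{k}"] = np.zeros(ch)
            prev = ch
        # Final layer: zero-mean Gaussian, std 0.01.
        p["Wf"] = rng.normal(0.0, 0.01, size=(prev, n_classes))
        p["bf"] = np.zeros(n_classes)
        self.params = p
        self.n_classes = n_classes

    def forward(self, x):
        p = self.params
        cache = {"x": x}
        a = x
        for k in (1, 2):
            z, xp = _conv_forward(a, p[f"W{k}"], p[f"b{k}"])
            r = np.maximum(z, 0.0)
            a = _avgpool2(r)
            cache[f"xp{k}"], cache[f"z{k}"] = xp, z
        z3, xp3 = _conv_forward(a, p["W3"], p["b3"])
        r3 = np.maximum(z3, 0.0)
        cache["xp3"], cache["z3"], cache["r3shape"] = xp3, z3, r3.shape
        feat = r3.mean(axis=(2, 3))  # global average pool
        cache["feat"] = feat
        logits = feat @ p["Wf"] + p["bf"]
        return logits, cache

    def backward(self, cache, dlogits):
        p = self.params
        grads = {}
        grads["Wf"] = cache["feat"].T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["Wf"].T
        n, c, h, w = cache["r3shape"]
        dr3 = np.broadcast_to(dfeat[:, :, None, None], (n, c, h, w)) / (h * w)
        dz3 = dr3 * (cache["z3"] > 0)
        grads["W3"], grads["b3"], da = _conv_backward(dz3, cache["xp3"], p["W3"])
        for k in (2, 1):
            dr = _avgpool2_backward(da)
            dz = dr * (cache[f"z{k}"] > 0)
            grads[f"W{k}"], grads[f"b{k}"], da = _conv_backward(
                dz, cache[f"xp{k}"], p[f"W{k}"]
            )
        return grads

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[start : start + batch_size])
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            out.append(ez / ez.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)


class SGDMomentum:
    def __init__(self, params: dict, momentum: float = 0.9):
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, lr: float) -> None:
        for k in params:
            self.velocity[k] = self.momentum * self.velocity[k] - lr * grads[k]
            params[k] += self.velocity[k]


class Adam:
    def __init__(
        self,
        params: dict,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grads[k] ** 2
            params[k] -= lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
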