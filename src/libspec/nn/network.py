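"""Sequential network container, softmax cross-entropy loss and SGD training.

The network is a named sequence of layers; names let callers pull
intermediate activations (for t-SNE views) and the backward pass can be run
from an arbitrary logit seed, which is how input-gradient saliency maps are
computed.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer

__all__ = ["Network", "DivergenceError", "softmax"]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """An ordered list of (name, layer) pairs ending in a logits layer."""

    def __init__(self, layers: list[tuple[str, Layer]], n_classes: int, dtype=np.float32):
        self.layers = layers
        self.n_classes = n_classes
        self.dtype = np.dtype(dtype)
        self._velocity: dict[int, np.ndarray] = {}

    # -- structure -----------------------------------------------------------
    def params(self):
        out = []
        for _, layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def layer_names(self) -> list[str]:
        return [name for name, _ in self.layers]

    # -- passes --------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.asarray(x, dtype=self.dtype)
        for _, layer in self.layers:
            h = layer.forward(h, train)
        return h

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for _, layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    # -- inference -----------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        outs = [
            softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    def activations(self, x: np.ndarray, layer_name: str, batch_size: int = 256) -> np.ndarray:
        """Output of the named layer in eval mode, over all inputs."""
        if layer_name not in self.layer_names():
            raise KeyError(f"unknown layer '{layer_name}'; have {self.layer_names()}")
        x = np.asarray(x, dtype=self.dtype)
        chunks = []
        for i in range(0, x.shape[0], batch_size):
            h = x[i : i + batch_size]
            for name, layer in self.layers:
                h = layer.forward(h, train=False)
                if name == layer_name:
                    break
            chunks.append(h)
        return np.concatenate(chunks, axis=0)

    # -- training ------------------------------------------------------------
    def train_batch(self, x: np.ndarray, y_idx: np.ndarray, lr: float, momentum: float = 0.9) -> tuple[float, float]:
        """One SGD step on a mini-batch; returns (loss, batch accuracy).

        ``y_idx`` holds 0-based class indices.
        """
        logits = self.forward(x, train=True)
        probs = softmax(logits.astype(np.float64))
        n = x.shape[0]
        loss = float(-np.mean(np.log(probs[np.arange(n), y_idx] + 1e-12)))
        acc = float(np.mean(np.argmax(logits, axis=1) == y_idx))
        dlogits = probs
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        self.zero_grad()
        self.backward(dlogits.astype(self.dtype))
        for p in self.params():
            v = self._velocity.get(id(p))
            if v is None:
                v = self._velocity[id(p)] = np.zeros_like(p.value)
            v *= momentum
            v -= lr * p.grad
            p.value += v
        return loss, acc

    # -- attribution ---------------------------------------------------------
    def input_gradient(self, x: np.ndarray, class_index: int) -> np.ndarray:
        """Gradient of the target class's pre-softmax score w.r.t. the input.

        Runs in eval mode (dropout off, batch-norm running stats); parameters
        are untouched.
        """
        x = np.asarray(x, dtype=self.dtype)
        logits = self.forward(x, train=False)
        if not 0 <= class_index < logits.shape[1]:
            raise IndexError(f"class index {class_index} outside 0..{logits.shape[1] - 1}")
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        self.zero_grad()
        dx = self.backward(dlogits)
        self.zero_grad()
        return dx
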