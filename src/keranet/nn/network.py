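"""A sequential network with cross-entropy training utilities."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, BatchNorm, Dropout, Layer, Param, Softmax


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes NaN or infinite."""


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """An ordered stack of layers ending in a softmax classifier head.

    Training uses the numerically fused softmax + categorical
    cross-entropy gradient on the logits; the trailing :class:`Softmax`
    layer is still part of the stack so inference produces probabilities.
    """

    def __init__(self, layers: list[Layer]):
        if not layers or not isinstance(layers[-1], Softmax):
            raise ValueError("network must end with a Softmax layer")
        self.layers = layers

    # -- structure ---------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers[:-1]:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities for a batch of inputs, in inference mode."""
        x = np.asarray(x, dtype=DTYPE)
        chunks = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    # -- training ----------------------------------------------------------
    def train_batch(self, x: np.ndarray, y_onehot: np.ndarray, optimizer) -> tuple[float, float]:
        """One optimizer step on a mini-batch; returns (loss, accuracy)."""
        x = np.asarray(x, dtype=DTYPE)
        logits = self.forward_logits(x, training=True)
        p = softmax(logits)
        eps = 1e-12
        loss = float(-(y_onehot * np.log(np.clip(p, eps, 1.0))).sum(axis=1).mean())
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"loss diverged to {loss}")
        acc = float((p.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())

        for param in self.params():
            param.grad[...] = 0.0
        grad = (p - y_onehot) / len(x)
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)
        optimizer.step(self.params())
        return loss, acc

    def calibrate_bn(self, x: np.ndarray, max_samples: int = 256) -> None:
        """Recompute batch-norm population statistics with current weights.

        Runs one forward pass over up to ``max_samples`` training inputs
        (the leading rows of ``x``), setting each batch-norm layer's
        running statistics to the population statistics its inputs have
        under the current weights. Dropout is bypassed. This removes the
        lag of exponential running averages when epochs contain few
        optimizer steps.
        """
        h = np.asarray(x[:max_samples], dtype=DTYPE)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                h = layer.forward_calibrate(h)
            elif isinstance(layer, Dropout):
                continue
            else:
                h = layer.forward(h, training=False)

    # -- checkpointing -----------------------------------------------------
    def get_weights(self) -> dict:
        """Deep copy of all trainable values and batch-norm running stats."""
        state = {"params": [p.value.copy() for p in self.params()], "bn": []}
        for layer in self.layers:
            if hasattr(layer, "running_mean"):
                state["bn"].append(
                    (layer.running_mean.copy(), layer.running_var.copy())
                )
        return state

    def set_weights(self, state: dict) -> None:
        for param, value in zip(self.params(), state["params"], strict=True):
            param.value[...] = value
        bn_layers = [l for l in self.layers if hasattr(l, "running_mean")]
        for layer, (rm, rv) in zip(bn_layers, state["bn"], strict=True):
            layer.running_mean[...] = rm
            layer.running_var[...] = rv
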