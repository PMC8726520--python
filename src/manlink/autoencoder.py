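"""Stacked autoencoder for compressing wide node features to 64 dimensions.

A symmetric shallow autoencoder (sigmoid encoder, sigmoid decoder, mean
squared reconstruction error) is trained greedily layer by layer: the code
produced by one trained layer becomes the training input of the next, so a
widths chain like 1024 -> 256 -> 64 is realized as two independent single
layer autoencoders.  Training is plain minibatch stochastic gradient
descent; a fixed seed makes the encoder bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SAEError(ValueError):
    pass


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35.0, 35.0)))


@dataclass
class _Layer:
    w_enc: np.ndarray  # (n_in, n_out)
    b_enc: np.ndarray
    w_dec: np.ndarray  # (n_out, n_in)
    b_dec: np.ndarray

    def encode(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(x @ self.w_enc + self.b_enc)


@dataclass
class SAEModel:
    """Greedily pretrained encoder stack; ``loss_trace[i]`` is the per-epoch
    mean reconstruction loss of layer *i*."""

    widths: list[int]
    layers: list[_Layer] = field(default_factory=list)
    loss_trace: list[list[float]] = field(default_factory=list)

    @property
    def input_width(self) -> int:
        return self.widths[0]

    @property
    def output_width(self) -> int:
        return self.widths[-1]


def train_sae(
    inputs: np.ndarray,
    widths: list[int],
    epochs: int = 50,
    lr: float = 0.01,
    batch_size: int = 16,
    seed: int = 0,
) -> SAEModel:
    """Greedy layer-wise pretraining of the encoder stack.

    *widths* starts at the input width and ends at the code width; a single
    entry means an identity pass-through (the input is already at code
    width).  Each layer is a one-hidden-layer symmetric autoencoder trained
    to reconstruct its own input under MSE.
    """
    x = np.asarray(inputs, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise SAEError("need a 2-D input matrix with at least 2 rows")
    if list(widths) != sorted(widths, reverse=True) or len(set(widths)) != len(widths):
        raise SAEError(f"widths must be strictly decreasing, got {widths}")
    if x.shape[1] != widths[0]:
        raise SAEError(f"input width {x.shape[1]} != widths[0]={widths[0]}")
    model = SAEModel(widths=list(widths))
    if len(widths) == 1:
        return model

    rng = np.random.default_rng(seed)
    code = x
    for n_in, n_out in zip(widths[:-1], widths[1:]):
        scale = np.sqrt(6.0 / (n_in + n_out))  # Glorot-style init
        layer = _Layer(
            w_enc=rng.uniform(-scale, scale, size=(n_in, n_out)),
            b_enc=np.zeros(n_out),
            w_dec=rng.uniform(-scale, scale, size=(n_out, n_in)),
            b_dec=np.zeros(n_in),
        )
        trace: list[float] = []
        n = code.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                xb = code[order[start : start + batch_size]]
                h = _sigmoid(xb @ layer.w_enc + layer.b_enc)
                xr = _sigmoid(h @ layer.w_dec + layer.b_dec)
                err = xr - xb
                losses.append(float(np.mean(err**2)))
                # backprop through the two sigmoid layers, MSE loss
                d_out = (2.0 / xb.size) * err * xr * (1.0 - xr)
                g_wdec = h.T @ d_out
                g_bdec = d_out.sum(axis=0)
                d_h = (d_out @ layer.w_dec.T) * h * (1.0 - h)
                g_wenc = xb.T @ d_h
                g_benc = d_h.sum(axis=0)
                layer.w_dec -= lr * g_wdec
                layer.b_dec -= lr * g_bdec
                layer.w_enc -= lr * g_wenc
                layer.b_enc -= lr * g_benc
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise SAEError(f"non-finite reconstruction loss (lr={lr})")
            trace.append(epoch_loss)
        model.layers.append(layer)
        model.loss_trace.append(trace)
        code = layer.encode(code)
    return model


def encode(model: SAEModel, inputs: np.ndarray) -> np.ndarray:
    """Push rows through the trained encoder stack; deterministic."""
    x = np.asarray(inputs, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] == 0:
        return np.zeros((0, model.output_width))
    if x.shape[1] != model.input_width:
        raise SAEError(
            f"input width {x.shape[1]} does not match model ({model.input_width})"
        )
    for layer in model.layers:
        x = layer.encode(x)
    return x
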