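"""A small, self-contained convolutional network on numpy.

Fixed architecture: conv(32, 3x3) -> maxpool 2x2 -> conv(64, 3x3) ->
maxpool 2x2 -> flatten -> dense(128, ReLU) -> dense(n_classes, softmax),
trained with class-weighted cross-entropy and SGD (momentum). Convolutions
are valid (no padding) and run as one im2col matrix product per layer, so
the whole forward/backward pass is BLAS-bound. Everything is float32 and
seeded: two fits with the same data and seed produce identical weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNNParams", "init_params", "forward", "backward", "train"]

K = 3  # kernel size


def init_params(input_size: int, in_channels: int, n_classes: int,
                rng: np.random.Generator, f1: int = 32, f2: int = 64,
                dense: int = 128) -> dict:
    """He-normal initialization of all layers for a given input size."""
    s1 = input_size - K + 1          # after conv1
    p1 = s1 // 2                     # after pool1
    s2 = p1 - K + 1                  # after conv2
    p2 = s2 // 2                     # after pool2
    flat = p2 * p2 * f2

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    return {
        "W1": he((K * K * in_channels, f1), K * K * in_channels),
        "b1": np.zeros(f1, np.float32),
        "W2": he((K * K * f1, f2), K * K * f1),
        "b2": np.zeros(f2, np.float32),
        "W3": he((flat, dense), flat),
        "b3": np.zeros(dense, np.float32),
        "W4": he((dense, n_classes), dense),
        "b4": np.zeros(n_classes, np.float32),
    }


CNNParams = dict  # alias for readability in signatures


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B, OH, OW, K*K*C) patch matrix."""
    win = sliding_window_view(x, (K, K), axis=(1, 2))  # (B, OH, OW, C, K, K)
    b, oh, ow = win.shape[:3]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        b, oh, ow, K * K * x.shape[3]
    )


def _col2im(dcols: np.ndarray, shape) -> np.ndarray:
    """Adjoint of _im2col: scatter patch gradients back to the image."""
    b, h, w, c = shape
    oh, ow = h - K + 1, w - K + 1
    dwin = dcols.reshape(b, oh, ow, K, K, c)
    dx = np.zeros(shape, np.float32)
    for i in range(K):
        for j in range(K):
            dx[:, i : i + oh, j : j + ow, :] += dwin[:, :, :, i, j, :]
    return dx


def _conv(x, W, b):
    cols = _im2col(x)
    out = cols @ W + b
    return out, cols


def _pool(x, need_mask: bool = True):
    b, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xr = x[:, : h2 * 2, : w2 * 2, :].reshape(b, h2, 2, w2, 2, c)
    out = xr.max(axis=(2, 4))
    if not need_mask:
        return out, None
    mask = (xr == out[:, :, None, :, None, :]).astype(np.float32)
    # split ties evenly so the backward pass stays a true subgradient
    mask /= mask.sum(axis=(2, 4), keepdims=True)
    return out, (mask, x.shape)


def _unpool(dout, cache):
    mask, shape = cache
    b, h, w, c = shape
    h2, w2 = h // 2, w // 2
    dx = np.zeros(shape, np.float32)
    dxr = (mask * dout[:, :, None, :, None, :]).reshape(b, h2 * 2, w2 * 2, c)
    dx[:, : h2 * 2, : w2 * 2, :] = dxr
    return dx


def forward(params: dict, x: np.ndarray, need_cache: bool = False):
    """Class probabilities for a batch of (B, S, S, C) float32 images."""
    z1, cols1 = _conv(x, params["W1"], params["b1"])
    a1 = np.maximum(z1, np.float32(0.0))
    p1, cache1 = _pool(a1, need_cache)
    z2, cols2 = _conv(p1, params["W2"], params["b2"])
    a2 = np.maximum(z2, np.float32(0.0))
    p2, cache2 = _pool(a2, need_cache)
    flat = p2.reshape(len(x), -1)
    z3 = flat @ params["W3"] + params["b3"]
    a3 = np.maximum(z3, 0.0)
    logits = a3 @ params["W4"] + params["b4"]
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    probs = e / e.sum(axis=1, keepdims=True)
    if not need_cache:
        return probs
    return probs, (x, cols1, z1, cache1, p1, cols2, z2, cache2, p2, flat, z3, a3)


def backward(params: dict, probs: np.ndarray, cache, y_onehot: np.ndarray,
             sample_weight: np.ndarray) -> dict:
    """Gradients of the weighted mean cross-entropy w.r.t. all parameters."""
    x, cols1, z1, cache1, p1, cols2, z2, cache2, p2, flat, z3, a3 = cache
    b = len(x)
    # weighted *mean* over the batch: bounds the step size whatever mix of
    # high-weight minority samples the batch happens to contain
    norm = np.float32(max(sample_weight.sum(), 1e-8))
    dlogits = (probs - y_onehot) * sample_weight[:, None] / norm
    g = {}
    g["W4"] = a3.T @ dlogits
    g["b4"] = dlogits.sum(axis=0)
    da3 = dlogits @ params["W4"].T
    dz3 = da3 * (z3 > 0)
    g["W3"] = flat.T @ dz3
    g["b3"] = dz3.sum(axis=0)
    dflat = dz3 @ params["W3"].T
    dp2 = dflat.reshape(p2.shape)
    da2 = _unpool(dp2, cache2)
    dz2 = (da2 * (z2 > 0)).astype(np.float32)
    oh2 = dz2.shape[1]
    dz2f = dz2.reshape(-1, dz2.shape[-1])
    g["W2"] = cols2.reshape(-1, cols2.shape[-1]).T @ dz2f
    g["b2"] = dz2f.sum(axis=0)
    dcols2 = (dz2f @ params["W2"].T).reshape(b, oh2, oh2, -1)
    dp1 = _col2im(dcols2, p1.shape)
    da1 = _unpool(dp1, cache1)
    dz1 = (da1 * (z1 > 0)).astype(np.float32)
    dz1f = dz1.reshape(-1, dz1.shape[-1])
    g["W1"] = cols1.reshape(-1, cols1.shape[-1]).T @ dz1f
    g["b1"] = dz1f.sum(axis=0)
    return g


def loss_value(probs, y_onehot, sample_weight):
    ce = -np.log(np.clip((probs * y_onehot).sum(axis=1), 1e-12, None))
    return float((ce * sample_weight).sum() / max(sample_weight.sum(), 1e-8))


def train(
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    rng: np.random.Generator,
    lr: float = 0.01,
    momentum: float = 0.9,
    batch_size: int = 32,
    max_epochs: int = 30,
    patience: int = 6,
    clip_norm: float | None = 1.0,
    loss_tol: float = 0.02,
    eval_set=None,
) -> tuple[dict, list[float]]:
    """SGD with momentum; early stopping on validation loss when an
    ``eval_set=(X_val, y_val, w_val)`` is given, else on training loss.
    Training also stops once the monitored loss reaches ``loss_tol``
    (converged). Returns ``(best_params, loss_history)``."""
    n_classes = params["b4"].shape[0]
    onehot = np.eye(n_classes, dtype=np.float32)[y]
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    best_loss, best_params, bad = np.inf, {k: v.copy() for k, v in params.items()}, 0
    history = []
    n = len(X)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            probs, cache = forward(params, X[idx], need_cache=True)
            grads = backward(params, probs, cache, onehot[idx], sample_weight[idx])
            if clip_norm is not None:
                gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if gnorm > clip_norm:
                    scale = np.float32(clip_norm / gnorm)
                    for k in grads:
                        grads[k] *= scale
            for k in params:
                vel[k] = momentum * vel[k] - lr * grads[k]
                params[k] += vel[k]
        if eval_set is not None:
            Xv, yv, wv = eval_set
            pv = _forward_batched(params, Xv)
            monitor = loss_value(pv, np.eye(n_classes, dtype=np.float32)[yv], wv)
        else:
            pt = _forward_batched(params, X)
            monitor = loss_value(pt, onehot, sample_weight)
        history.append(monitor)
        if monitor <= loss_tol:
            best_loss = monitor
            best_params = {k: v.copy() for k, v in params.items()}
            break
        if monitor < best_loss - 1e-5:
            best_loss = monitor
            best_params = {k: v.copy() for k, v in params.items()}
            bad = 0
        else:
            bad += 1
            if bad > patience:
                break
    return best_params, history


def _forward_batched(params, X, batch_size: int = 64):
    out = [forward(params, X[lo : lo + batch_size]) for lo in range(0, len(X), batch_size)]
    return np.concatenate(out, axis=0)
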