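"""Minimal deterministic neural-network primitives on numpy.

Implements exactly what the dual-head classifier needs: valid/padded 2-D
convolution via im2col, non-overlapping average pooling, ReLU, dense layers,
a residual wrapper, and a decoupled-weight-decay Adam optimiser.  All
parameters live in a flat ``{name: ndarray}`` dict so that a training phase
can compute and apply gradients for an arbitrary subset of parameters,
leaving the rest bit-identical.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv", "AvgPool", "ReLU", "Flatten", "Dense", "Residual", "AdamW",
           "softmax", "init_params", "forward_layers", "backward_layers"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _param_rng(seed: int, name: str) -> np.random.Generator:
    # stable per-parameter stream: the same name always gets the same
    # weights for a given seed, independent of which other layers exist
    import zlib

    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


class Conv:
    """2-D convolution (stride 1) with optional zero padding, NCHW layout."""

    def __init__(self, name: str, cin: int, cout: int, k: int = 3, pad: int = 0):
        self.name, self.cin, self.cout, self.k, self.pad = name, cin, cout, k, pad

    def init(self, seed: int) -> dict:
        fan_in = self.cin * self.k * self.k
        rng = _param_rng(seed, self.name + "/W")
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, self.cout))
        return {self.name + "/W": W.astype(np.float32),
                self.name + "/b": np.zeros(self.cout, dtype=np.float32)}

    def _im2col(self, x: np.ndarray):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        B, C, H, W = x.shape
        k = self.k
        Ho, Wo = H - k + 1, W - k + 1
        s = x.strides
        win = np.lib.stride_tricks.as_strided(
            x, (B, C, k, k, Ho, Wo), (s[0], s[1], s[2], s[3], s[2], s[3])
        )
        cols = np.ascontiguousarray(win.transpose(0, 4, 5, 1, 2, 3)).reshape(
            B, Ho * Wo, C * k * k
        )
        return cols, (B, C, H, W, Ho, Wo)

    def forward(self, x, params):
        cols, dims = self._im2col(x)
        W = params[self.name + "/W"]
        b = params[self.name + "/b"]
        B, C, H, Wd, Ho, Wo = dims
        out = cols @ W + b
        out = out.reshape(B, Ho, Wo, self.cout).transpose(0, 3, 1, 2)
        return out, (cols, dims, x.shape)

    def backward(self, dout, cache, params):
        cols, dims, xshape = cache
        B, C, Hp, Wp, Ho, Wo = dims  # padded dims
        k = self.k
        dres = dout.transpose(0, 2, 3, 1).reshape(B, Ho * Wo, self.cout)
        W = params[self.name + "/W"]
        dW = np.einsum("bnk,bnf->kf", cols, dres)
        db = dres.sum(axis=(0, 1))
        dcols = dres @ W.T
        dxp = np.zeros((B, C, Hp, Wp), dtype=dout.dtype)
        dcols = dcols.reshape(B, Ho, Wo, C, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if self.pad:
            dxp = dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp, {self.name + "/W": dW, self.name + "/b": db}


class AvgPool:
    """Non-overlapping average pooling; trailing rows/cols beyond a multiple
    of the factor are dropped (and receive zero gradient)."""

    def __init__(self, factor: int):
        self.f = factor

    def init(self, seed):
        return {}

    def forward(self, x, params):
        B, C, H, W = x.shape
        f = self.f
        Ho, Wo = H // f, W // f
        xt = x[:, :, : Ho * f, : Wo * f].reshape(B, C, Ho, f, Wo, f)
        return xt.mean(axis=(3, 5)), (x.shape, Ho, Wo)

    def backward(self, dout, cache, params):
        (B, C, H, W), Ho, Wo = cache
        f = self.f
        dx = np.zeros((B, C, H, W), dtype=dout.dtype)
        expanded = np.repeat(np.repeat(dout, f, axis=2), f, axis=3) / (f * f)
        dx[:, :, : Ho * f, : Wo * f] = expanded
        return dx, {}


class ReLU:
    def init(self, seed):
        return {}

    def forward(self, x, params):
        mask = x > 0
        return x * mask, mask

    def backward(self, dout, mask, params):
        return dout * mask, {}


class Flatten:
    def init(self, seed):
        return {}

    def forward(self, x, params):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dout, shape, params):
        return dout.reshape(shape), {}


class Dense:
    def __init__(self, name: str, din: int, dout: int):
        self.name, self.din, self.dout = name, din, dout

    def init(self, seed: int) -> dict:
        rng = _param_rng(seed, self.name + "/W")
        W = rng.normal(0.0, np.sqrt(2.0 / self.din), size=(self.din, self.dout))
        return {self.name + "/W": W.astype(np.float32),
                self.name + "/b": np.zeros(self.dout, dtype=np.float32)}

    def forward(self, x, params):
        return x @ params[self.name + "/W"] + params[self.name + "/b"], x

    def backward(self, dout, x, params):
        dW = x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ params[self.name + "/W"].T
        return dx, {self.name + "/W": dW, self.name + "/b": db}


class Residual:
    """y = relu(x + inner(x)); inner layers must preserve shape."""

    def __init__(self, layers):
        self.layers = layers

    def init(self, seed):
        p = {}
        for lyr in self.layers:
            p.update(lyr.init(seed))
        return p

    def forward(self, x, params):
        h, caches = forward_layers(x, self.layers, params)
        out = x + h
        mask = out > 0
        return out * mask, (caches, mask)

    def backward(self, dout, cache, params):
        caches, mask = cache
        d = dout * mask
        dinner, grads = backward_layers(d, self.layers, caches, params)
        return d + dinner, grads


def init_params(layers, seed: int) -> dict:
    params = {}
    for lyr in layers:
        params.update(lyr.init(seed))
    return params


def forward_layers(x, layers, params):
    caches = []
    for lyr in layers:
        x, c = lyr.forward(x, params)
        caches.append(c)
    return x, caches


def backward_layers(dout, layers, caches, params, need_input_grad=True):
    grads = {}
    stop_at = 0
    if not need_input_grad:
        # gradients below the first parameterised layer are never used
        for i, lyr in enumerate(layers):
            if isinstance(lyr, (Conv, Dense, Residual)):
                stop_at = i
                break
    for i in reversed(range(len(layers))):
        if not need_input_grad and i < stop_at:
            dout = None
            break
        dout, g = layers[i].backward(dout, caches[i], params)
        grads.update(g)
    return dout, grads


class AdamW:
    """Adam with decoupled weight decay; maintains per-parameter state so a
    phase can update any subset of parameters without touching the rest."""

    def __init__(self, lr=1e-4, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.m: dict = {}
        self.v: dict = {}
        self.t: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        for name, g in grads.items():
            p = params[name]
            if name not in self.m:
                self.m[name] = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
                self.t[name] = 0
            self.t[name] += 1
            t = self.t[name]
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mh = self.m[name] / (1 - self.b1**t)
            vh = self.v[name] / (1 - self.b2**t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)
            if self.wd:
                p -= self.lr * self.wd * p
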