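"""Layer primitives for the 3D translation networks.

Layers are functional and reentrant: ``forward`` returns ``(y, cache)`` and
``backward(g, cache)`` returns the input gradient while accumulating parameter
gradients into ``layer.grads``. The same layer instance can therefore appear
several times in one computation graph (the cycle pass reuses each generator
twice) without clobbering state.

Weights initialize from N(0, 0.02) via a caller-supplied Generator, the usual
convention for image-translation networks.
"""

from __future__ import annotations

import numpy as np

from .functional import (
    conv3d_backward,
    conv3d_forward,
    conv_transpose3d_backward,
    conv_transpose3d_forward,
    weight_fingerprint,
)

__all__ = [
    "Layer",
    "Conv3d",
    "SNConv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Dropout",
    "Linear",
    "Sequential",
    "ResidualBlock",
    "spectral_normalize",
]

_INIT_STD = 0.02
_EPS = 1e-5


class Layer:
    """Base class: a dict of parameters and matching gradient accumulators."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, rng=None, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g, cache):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def named_layers(self):
        yield "", self

    def all_params(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, layer in self.named_layers():
            for k, v in layer.params.items():
                out[f"{prefix}{k}" if prefix else k] = v
        return out


class Conv3d(Layer):
    def __init__(self, cin, cout, k, stride=1, pad=0, pad_mode="zero",
                 bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad, self.pad_mode = stride, pad, pad_mode
        self.params["w"] = (rng.standard_normal((cout, cin, k, k, k)) * _INIT_STD).astype(np.float32)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self._spec_cache: dict = {}
        if bias:
            self.params["b"] = np.zeros(cout, dtype=np.float32)
            self.grads["b"] = np.zeros_like(self.params["b"])

    def _effective_weight(self) -> np.ndarray:
        return self.params["w"]

    def _accumulate_weight_grad(self, dw: np.ndarray) -> None:
        self.grads["w"] += dw

    def forward(self, x, rng=None, train=False):
        w = self._effective_weight()
        y, cache = conv3d_forward(x, w, self.params.get("b"),
                                  self.stride, self.pad, self.pad_mode,
                                  spec_cache=self._spec_cache)
        return y, cache

    def backward(self, g, cache):
        dx, dw, db = conv3d_backward(g, cache)
        self._accumulate_weight_grad(dw)
        if "b" in self.grads:
            self.grads["b"] += db
        return dx


def _power_iteration(w2: np.ndarray, u: np.ndarray, n_iters: int):
    """Update persistent left vector u; return (sigma, u, v)."""
    v = None
    for _ in range(n_iters):
        v = w2.T @ u
        v /= np.linalg.norm(v) + 1e-12
        u = w2 @ v
        u /= np.linalg.norm(u) + 1e-12
    sigma = float(u @ w2 @ v)
    return sigma, u, v


class SNConv3d(Conv3d):
    """Conv3d whose weight is divided by its largest singular value.

    The weight is viewed as an (out-channels x rest) matrix; a persistent
    power-iteration vector tracks the top singular direction. The gradient is
    the exact derivative through the normalization, including the rank-one
    term from d(sigma)/dW.
    """

    def __init__(self, *args, n_power_iters=3, **kwargs):
        super().__init__(*args, **kwargs)
        self.n_power_iters = n_power_iters
        cout = self.params["w"].shape[0]
        self.u = np.ones(cout, dtype=np.float64) / np.sqrt(cout)
        self._warm = False
        self._sn_state = None
        self._sn_key = None

    def _effective_weight(self) -> np.ndarray:
        w = self.params["w"].astype(np.float64)
        # skip the power iteration when the weight is unchanged since the
        # last call (fingerprint detects any update or perturbation)
        key = weight_fingerprint(w)
        if self._sn_state is not None and key == self._sn_key:
            return self._sn_state[3]
        w2 = w.reshape(w.shape[0], -1)
        # iterate from the persistent vector to a fixed point; warm restarts
        # converge in a handful of steps, keeping sigma estimates tight even
        # after large weight perturbations such as clipping
        max_iters = 500 if not self._warm else 100
        sigma_prev = 0.0
        sigma = v = None
        for it in range(max_iters):
            sigma, self.u, v = _power_iteration(w2, self.u, 1)
            if it + 1 >= self.n_power_iters and (
                abs(sigma - sigma_prev) <= 1e-7 * max(1.0, sigma)
            ):
                break
            sigma_prev = sigma
        self._warm = True
        if sigma <= 0:
            raise ValueError("spectral normalization undefined for all-zero weight")
        w_sn = (w / sigma).astype(np.float32)
        self._sn_state = (sigma, self.u.copy(), v, w_sn)
        self._sn_key = key
        return w_sn

    def _accumulate_weight_grad(self, dw_sn: np.ndarray) -> None:
        sigma, u, v, w_sn = self._sn_state
        g2 = dw_sn.reshape(dw_sn.shape[0], -1).astype(np.float64)
        wsn2 = w_sn.reshape(w_sn.shape[0], -1).astype(np.float64)
        inner = float((g2 * wsn2).sum())
        dw2 = (g2 - inner * np.outer(u, v)) / sigma
        self.grads["w"] += dw2.reshape(dw_sn.shape).astype(np.float32)


class ConvTranspose3d(Layer):
    def __init__(self, cin, cout, k, stride=2, pad=1, output_pad=1,
                 bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad, self.output_pad = stride, pad, output_pad
        self.params["w"] = (rng.standard_normal((cin, cout, k, k, k)) * _INIT_STD).astype(np.float32)
        self.grads["w"] = np.zeros_like(self.params["w"])
        if bias:
            self.params["b"] = np.zeros(cout, dtype=np.float32)
            self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, rng=None, train=False):
        return conv_transpose3d_forward(x, self.params["w"], self.params.get("b"),
                                        self.stride, self.pad, self.output_pad)

    def backward(self, g, cache):
        dx, dw, db = conv_transpose3d_backward(g, cache)
        self.grads["w"] += dw
        if "b" in self.grads:
            self.grads["b"] += db
        return dx


class InstanceNorm3d(Layer):
    """Per-sample, per-channel standardization over the spatial axes (no affine)."""

    def forward(self, x, rng=None, train=False):
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        var = x.var(axis=(2, 3, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + _EPS)
        y = ((x - mu) * inv).astype(np.float32)
        return y, (y, inv.astype(np.float32))

    def backward(self, g, cache):
        y, inv = cache
        gm = g.mean(axis=(2, 3, 4), keepdims=True)
        gym = (g * y).mean(axis=(2, 3, 4), keepdims=True)
        return ((g - gm - y * gym) * inv).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, rng=None, train=False):
        y = np.maximum(x, 0.0)
        return y, (x > 0)

    def backward(self, g, cache):
        return (g * cache).astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, rng=None, train=False):
        mask = x > 0
        y = np.where(mask, x, self.slope * x).astype(np.float32)
        return y, mask

    def backward(self, g, cache):
        return np.where(cache, g, self.slope * g).astype(np.float32)


class Tanh(Layer):
    def forward(self, x, rng=None, train=False):
        y = np.tanh(x).astype(np.float32)
        return y, y

    def backward(self, g, cache):
        return (g * (1.0 - cache * cache)).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity unless training with rate > 0."""

    def __init__(self, rate=0.0):
        super().__init__()
        self.rate = rate

    def forward(self, x, rng=None, train=False):
        if not train or self.rate <= 0.0:
            return x, None
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return (x * mask).astype(np.float32), mask

    def backward(self, g, cache):
        if cache is None:
            return g
        return (g * cache).astype(np.float32)


class Linear(Layer):
    def __init__(self, fin, fout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = 1.0 / np.sqrt(fin)
        self.params["w"] = (rng.uniform(-scale, scale, (fout, fin))).astype(np.float32)
        self.params["b"] = np.zeros(fout, dtype=np.float32)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros_like(self.params["b"])

    def forward(self, x, rng=None, train=False):
        y = x @ self.params["w"].T + self.params["b"]
        return y.astype(np.float32), x

    def backward(self, g, cache):
        self.grads["w"] += g.T @ cache
        self.grads["b"] += g.sum(axis=0)
        return (g @ self.params["w"]).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, rng=None, train=False):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, rng=rng, train=train)
            caches.append(c)
        return x, caches

    def backward(self, g, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            g = layer.backward(g, c)
        return g

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def named_layers(self):
        for i, layer in enumerate(self.layers):
            for name, sub in layer.named_layers():
                yield (f"{i}.{name}" if name else str(i)), sub


class ResidualBlock(Layer):
    """Two 3x3x3 convs with instance norm; identity skip; optional dropout.

    Dropout, when enabled for uncertainty estimation, sits after the second
    conv's normalization, inside the residual branch.
    """

    def __init__(self, channels, rng=None, dropout_rate=0.0):
        super().__init__()
        self.branch = Sequential(
            Conv3d(channels, channels, 3, pad=1, rng=rng),
            InstanceNorm3d(),
            ReLU(),
            Conv3d(channels, channels, 3, pad=1, rng=rng),
            InstanceNorm3d(),
            Dropout(dropout_rate),
        )

    @property
    def dropout(self) -> Dropout:
        return self.branch.layers[-1]

    def forward(self, x, rng=None, train=False):
        y, c = self.branch.forward(x, rng=rng, train=train)
        return (x + y).astype(np.float32), c

    def backward(self, g, cache):
        return (g + self.branch.backward(g, cache)).astype(np.float32)

    def zero_grad(self):
        self.branch.zero_grad()

    def named_layers(self):
        yield from self.branch.named_layers()


def spectral_normalize(weight_matrix: np.ndarray, n_power_iters: int | None = None) -> np.ndarray:
    """Divide a matrix by its largest singular value (power iteration).

    With ``n_power_iters=None`` the iteration runs to a 1e-12 fixed-point
    tolerance, so the result's top singular value is 1 to within 1e-3 even on
    ill-conditioned inputs. An all-zero matrix has no direction to normalize
    and raises.
    """
    w = np.asarray(weight_matrix, dtype=np.float64)
    if not np.any(w):
        raise ValueError("cannot spectrally normalize an all-zero matrix")
    u = np.ones(w.shape[0]) / np.sqrt(w.shape[0])
    if n_power_iters is not None:
        sigma, _, _ = _power_iteration(w, u, max(1, n_power_iters))
    else:
        sigma_prev = 0.0
        sigma = None
        for _ in range(1000):
            sigma, u, _ = _power_iteration(w, u, 1)
            if abs(sigma - sigma_prev) < 1e-12:
                break
            sigma_prev = sigma
    return w / sigma
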