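"""A small, deterministic 1D-CNN engine (forward, backward, Adam) in numpy.

The transfer protocol studied here needs exact control over which layers are
frozen, what "frozen" means for batch-norm statistics, and bit-identical
reproducibility from a seed — so the engine is owned by the package rather
than hidden behind a framework. It implements exactly what the two
architectures require: valid (unpadded) strided 1-D convolution, batch
normalization, max/average/global-average pooling and dense layers, with
rectified-linear hidden activations and a softmax cross-entropy head.

Activations flow through the stack in channels-last layout ``(batch, length,
channels)`` so the im2col expansion of each convolution copies contiguous
channel vectors and the heavy contractions stay inside BLAS; the public
interface (``Network.forward`` and friends) accepts the conventional
``(batch, channels, length)``. Convolution weights are stored as
``(filters, in_channels, kernel)``. All parameters and activations are
float32.

Layer freezing excludes a layer's parameters from gradient updates; a frozen
batch-norm layer also runs in inference mode (stored statistics) by default,
since fixed weights should not be re-scaled by a shifted target
distribution — re-estimation on the target domain is available as an option.
Backpropagation stops below the deepest trainable layer, which is what makes
heavily frozen fine-tuning cheap.
"""

from __future__ import annotations

import numpy as np


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base layer: named, optionally parameterized, optionally frozen."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.frozen = False
        #: frozen batch-norm statistics mode: "source" | "reestimate"
        self.frozen_bn_mode = "source"

    def init_params(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv1D(Layer):
    """Valid (unpadded) strided 1-D convolution; optional fused ReLU."""

    def __init__(self, name: str, in_channels: int, n_filters: int, filter_size: int, stride: int, relu: bool = False):
        super().__init__(name)
        self.in_channels = in_channels
        self.n_filters = n_filters
        self.k = filter_size
        self.stride = stride
        self.relu = relu

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.in_channels * self.k
        self.params = {
            "W": _he_init(rng, (self.n_filters, self.in_channels, self.k), fan_in),
            "b": np.zeros(self.n_filters, dtype=np.float32),
        }

    def _w_flat(self) -> np.ndarray:
        # (F, C, K) -> (K*C, F) matching the (…, k, c) im2col column order
        return np.ascontiguousarray(self.params["W"].transpose(2, 1, 0)).reshape(
            self.k * self.in_channels, self.n_filters
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        L_out = (L - self.k) // self.stride + 1
        view = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)[:, :: self.stride][:, :L_out]
        cols = np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(B * L_out, self.k * C)
        out = cols @ self._w_flat() + self.params["b"]
        out = out.reshape(B, L_out, self.n_filters)
        if self.relu:
            self._mask = out > 0
            np.maximum(out, 0.0, out=out)
        if training:
            self._cols, self._in_shape, self._L_out = cols, (B, L, C), L_out
        return out

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if self.relu:
            dout = dout * self._mask
        B, L, C = self._in_shape
        L_out = self._L_out
        dflat = dout.reshape(B * L_out, self.n_filters)
        if not self.frozen:
            dW = (self._cols.T @ dflat).reshape(self.k, C, self.n_filters)
            self.grads = {"W": np.ascontiguousarray(dW.transpose(2, 1, 0)), "b": dflat.sum(axis=0)}
        if not need_input_grad:
            return None
        dcols = (dflat @ self._w_flat().T).reshape(B, L_out, self.k, C)
        dx = np.zeros((B, L, C), dtype=np.float32)
        s = self.stride
        for kk in range(self.k):
            dx[:, kk : kk + s * L_out : s, :] += dcols[:, :, kk, :]
        return dx


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, time); optional fused ReLU.

    Running statistics use momentum 0.1. When the layer is frozen it uses the
    stored statistics and updates nothing (mode "source"); in mode
    "reestimate" a frozen layer keeps its affine parameters fixed but
    normalizes with — and tracks — target-batch statistics.
    """

    EPS = 1e-5
    MOMENTUM = 0.1

    def __init__(self, name: str, n_channels: int, relu: bool = True):
        super().__init__(name)
        self.n_channels = n_channels
        self.relu = relu

    def init_params(self, rng: np.random.Generator) -> None:
        c = self.n_channels
        self.params = {"gamma": np.ones(c, dtype=np.float32), "beta": np.zeros(c, dtype=np.float32)}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        use_batch_stats = training and (not self.frozen or self.frozen_bn_mode == "reestimate")
        if use_batch_stats:
            flat = x.reshape(-1, x.shape[-1])
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean += self.MOMENTUM * (mu - self.running_mean)
            self.running_var += self.MOMENTUM * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.EPS)
        scale = self.params["gamma"] * ivar
        out = x * scale + (self.params["beta"] - mu * scale)
        if self.relu:
            self._mask = out > 0
            np.maximum(out, 0.0, out=out)
        if training:
            self._x, self._mu, self._ivar = x, mu, ivar
            self._batch_stats = use_batch_stats
        return out

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if self.relu:
            dout = dout * self._mask
        gamma = self.params["gamma"]
        xhat = (self._x - self._mu) * self._ivar
        if not self.frozen:
            flat_d = dout.reshape(-1, dout.shape[-1])
            self.grads = {
                "gamma": (flat_d * xhat.reshape(-1, xhat.shape[-1])).sum(axis=0),
                "beta": flat_d.sum(axis=0),
            }
        if not need_input_grad:
            return None
        if not self._batch_stats:
            return dout * (gamma * self._ivar)
        B, L, C = dout.shape
        m = B * L
        dxhat = dout * gamma
        s1 = dxhat.reshape(-1, C).sum(axis=0)
        s2 = (dxhat * xhat).reshape(-1, C).sum(axis=0)
        dx = (self._ivar / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(np.float32)


class _Pool1D(Layer):
    def __init__(self, name: str, pool_size: int, stride: int):
        super().__init__(name)
        self.k = pool_size
        self.stride = stride

    def _out_len(self, L: int) -> int:
        return (L - self.k) // self.stride + 1


class MaxPool1D(_Pool1D):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, L, C = x.shape
        L_out = self._out_len(L)
        s = self.stride
        best = x[:, 0 : s * L_out : s, :].copy()
        arg = np.zeros(best.shape, dtype=np.int8)
        for kk in range(1, self.k):
            sl = x[:, kk : kk + s * L_out : s, :]
            sel = sl > best
            arg[sel] = kk
            np.maximum(best, sl, out=best)
        if training:
            self._arg, self._in_shape, self._L_out = arg, x.shape, L_out
        return best

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if not need_input_grad:
            return None
        dx = np.zeros(self._in_shape, dtype=np.float32)
        s, L_out = self.stride, self._L_out
        for kk in range(self.k):
            dx[:, kk : kk + s * L_out : s, :] += dout * (self._arg == kk)
        return dx


class AvgPool1D(_Pool1D):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        L_out = self._out_len(x.shape[1])
        s = self.stride
        acc = x[:, 0 : s * L_out : s, :].astype(np.float32, copy=True)
        for kk in range(1, self.k):
            acc += x[:, kk : kk + s * L_out : s, :]
        acc /= self.k
        if training:
            self._in_shape, self._L_out = x.shape, L_out
        return acc

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if not need_input_grad:
            return None
        dx = np.zeros(self._in_shape, dtype=np.float32)
        s, L_out = self.stride, self._L_out
        share = dout / self.k
        for kk in range(self.k):
            dx[:, kk : kk + s * L_out : s, :] += share
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._in_shape = x.shape
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if not need_input_grad:
            return None
        B, L, C = self._in_shape
        return np.broadcast_to(dout[:, None, :] / L, (B, L, C)).astype(np.float32)


class Dense(Layer):
    def __init__(self, name: str, in_features: int, units: int, relu: bool):
        super().__init__(name)
        self.in_features = in_features
        self.units = units
        self.relu = relu

    def init_params(self, rng: np.random.Generator) -> None:
        self.params = {
            "W": _he_init(rng, (self.in_features, self.units), self.in_features),
            "b": np.zeros(self.units, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = x @ self.params["W"] + self.params["b"]
        if self.relu:
            self._mask = out > 0
            np.maximum(out, 0.0, out=out)
        if training:
            self._x = x
        return out

    def backward(self, dout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if self.relu:
            dout = dout * self._mask
        if not self.frozen:
            self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        if not need_input_grad:
            return None
        return dout @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-300))))
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Network:
    """An ordered stack of layers with a softmax classification head."""

    def __init__(self, layers: list[Layer], seed: int = 0):
        self.layers = layers
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init_params(rng)

    # -- inference ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a ``(batch, channels, length)`` input batch."""
        out = np.ascontiguousarray(np.asarray(x, dtype=np.float32).transpose(0, 2, 1))
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        parts = [softmax(self.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(parts, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- training -----------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate; skips gradient work below the deepest trainable layer."""
        lowest = len(self.layers)
        for i, layer in enumerate(self.layers):
            if layer.params and not layer.frozen:
                lowest = i
                break
        d: np.ndarray | None = dlogits
        for i in range(len(self.layers) - 1, -1, -1):
            if i < lowest:
                break
            d = self.layers[i].backward(d, need_input_grad=i > lowest)

    # -- freezing -----------------------------------------------------------
    def set_frozen(self, names: set[str] | frozenset[str], bn_mode: str = "source") -> None:
        known = {layer.name for layer in self.layers}
        unknown = sorted(set(names) - known)
        if unknown:
            raise KeyError(f"unknown layer name(s): {unknown}")
        if bn_mode not in ("source", "reestimate"):
            raise ValueError(f"bn_mode must be 'source' or 'reestimate', got {bn_mode!r}")
        for layer in self.layers:
            layer.frozen = layer.name in names
            layer.frozen_bn_mode = bn_mode

    @property
    def frozen_layers(self) -> tuple[str, ...]:
        return tuple(layer.name for layer in self.layers if layer.frozen)

    # -- state --------------------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for layer in self.layers:
            for pname, arr in layer.params.items():
                state[f"{layer.name}/{pname}"] = arr.copy()
            if isinstance(layer, BatchNorm1D):
                state[f"{layer.name}/running_mean"] = layer.running_mean.copy()
                state[f"{layer.name}/running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for pname in layer.params:
                layer.params[pname] = state[f"{layer.name}/{pname}"].copy()
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = state[f"{layer.name}/running_mean"].copy()
                layer.running_var = state[f"{layer.name}/running_var"].copy()


class Adam:
    """Adam with per-tensor moment slots; frozen layers are skipped."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, network: Network) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for layer in network.layers:
            if layer.frozen or not layer.params:
                continue
            for pname, p in layer.params.items():
                g = layer.grads[pname].astype(np.float32)
                key = f"{layer.name}/{pname}"
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m += (1 - b1) * (g - m)
                v += (1 - b2) * (g * g - v)
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
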