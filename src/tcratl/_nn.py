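"""Minimal NumPy neural-network layers with manual backpropagation.

Just enough machinery for the surrogate sequence-to-profile trunk, the
replaceable output head and the from-scratch CNN baseline: 1-D convolution,
linear maps, ReLU/softplus, layer norm, single-head self-attention, and an
Adam optimizer that can be restricted to a named parameter subset (which is
how the fine-tuning freeze levels are enforced).

Layers cache activations on ``forward`` and consume them on ``backward``;
models are used sequentially, never concurrently. Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: parameter / activation dtype; float32 for training throughput. Tests that
#: verify gradients against finite differences switch this to float64.
DEFAULT_DTYPE = np.float32


class Module:
    """Base class: named parameters/gradients plus named submodules."""

    def __init__(self):
        self._params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self._params[name] = np.asarray(value, dtype=DEFAULT_DTYPE)
        self._grads[name] = np.zeros_like(self._params[name])
        return self._params[name]

    def add_module(self, name: str, mod: "Module") -> "Module":
        self._children[name] = mod
        return mod

    def named_parameters(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + n: p for n, p in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + n: g for n, g in self._grads.items()}
        for cname, child in self._children.items():
            out.update(child.named_grads(prefix + cname + "."))
        return out

    def zero_grad(self) -> None:
        for g in self._grads.values():
            g[...] = 0.0
        for child in self._children.values():
            child.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.copy() for n, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for n, v in state.items():
            params[n][...] = v

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _glorot(rng, fan_in, fan_out, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Linear(Module):
    """Affine map over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.W = self.add_param("W", _glorot(rng, d_in, d_out, (d_in, d_out)))
        self.b = self.add_param("b", np.zeros(d_out)) if bias else None

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, dy):
        xf = self._x.reshape(-1, self.d_in)
        dyf = dy.reshape(-1, self.d_out)
        self._grads["W"] += xf.T @ dyf
        if self.b is not None:
            self._grads["b"] += dyf.sum(axis=0)
        return dy @ self.W.T


class Conv1d(Module):
    """'same'-padded strided 1-D convolution on (B, L, C_in) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        fan_in = kernel * c_in
        self.W = self.add_param("W", _glorot(rng, fan_in, c_out, (fan_in, c_out)))
        self.b = self.add_param("b", np.zeros(c_out))

    def _pad(self, L: int) -> tuple[int, int, int]:
        L_out = -(-L // self.stride)  # ceil
        total = max((L_out - 1) * self.stride + self.kernel - L, 0)
        return L_out, total // 2, total - total // 2

    def forward(self, x, train=False):
        B, L, _ = x.shape
        L_out, pl, pr = self._pad(L)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # (B, n_win, c_in, kernel) -> (B, L_out, kernel, c_in)
        win = sliding_window_view(xp, self.kernel, axis=1)[:, :: self.stride]
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            B * L_out, self.kernel * self.c_in
        )
        self._cache = (col, B, L, L_out, pl, xp.shape[1])
        return (col @ self.W + self.b).reshape(B, L_out, self.c_out)

    def backward(self, dy):
        col, B, L, L_out, pl, Lp = self._cache
        dyf = dy.reshape(B * L_out, self.c_out)
        self._grads["W"] += col.T @ dyf
        self._grads["b"] += dyf.sum(axis=0)
        dcol = (dyf @ self.W.T).reshape(B, L_out, self.kernel, self.c_in)
        dxp = np.zeros((B, Lp, self.c_in), dtype=dcol.dtype)
        for t in range(self.kernel):
            dxp[:, t : t + self.stride * L_out : self.stride] += dcol[:, :, t]
        return dxp[:, pl : pl + L]


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Softplus(Module):
    """y = log(1 + exp(x)); strictly positive output."""

    def forward(self, x, train=False):
        self._x = x
        return np.logaddexp(0.0, x)

    def backward(self, dy):
        return dy / (1.0 + np.exp(-self._x))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.g = self.add_param("g", np.ones(dim))
        self.b = self.add_param("b", np.zeros(dim))

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.g + self.b

    def backward(self, dy):
        xhat, inv = self._cache
        self._grads["g"] += (dy * xhat).reshape(-1, self.dim).sum(axis=0)
        self._grads["b"] += dy.reshape(-1, self.dim).sum(axis=0)
        dxh = dy * self.g
        m = dxh.mean(axis=-1, keepdims=True)
        mx = (dxh * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxh - m - xhat * mx)


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention on (B, T, C)."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        for n in ("Wq", "Wk", "Wv", "Wo"):
            self.add_param(n, _glorot(rng, dim, dim, (dim, dim)))

    def forward(self, x, train=False):
        p = self._params
        Q, K, V = x @ p["Wq"], x @ p["Wk"], x @ p["Wv"]
        s = 1.0 / np.sqrt(self.dim)
        S = (Q @ K.transpose(0, 2, 1)) * s
        S -= S.max(axis=-1, keepdims=True)
        E = np.exp(S)
        A = E / E.sum(axis=-1, keepdims=True)
        H = A @ V
        self._cache = (x, Q, K, V, A, H, s)
        return H @ p["Wo"]

    def backward(self, dy):
        x, Q, K, V, A, H, s = self._cache
        p, g = self._params, self._grads
        C = self.dim
        g["Wo"] += H.reshape(-1, C).T @ dy.reshape(-1, C)
        dH = dy @ p["Wo"].T
        dA = dH @ V.transpose(0, 2, 1)
        dV = A.transpose(0, 2, 1) @ dH
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = (dS * s) @ K
        dK = (dS * s).transpose(0, 2, 1) @ Q
        xf = x.reshape(-1, C)
        g["Wq"] += xf.T @ dQ.reshape(-1, C)
        g["Wk"] += xf.T @ dK.reshape(-1, C)
        g["Wv"] += xf.T @ dV.reshape(-1, C)
        return dQ @ p["Wq"].T + dK @ p["Wk"].T + dV @ p["Wv"].T


class TransformerBlock(Module):
    """Pre-norm attention + position-wise MLP, both with residuals."""

    def __init__(self, dim: int, rng: np.random.Generator, hidden: int | None = None):
        super().__init__()
        hidden = hidden or 2 * dim
        self.ln1 = self.add_module("ln1", LayerNorm(dim))
        self.attn = self.add_module("attn", SelfAttention(dim, rng))
        self.ln2 = self.add_module("ln2", LayerNorm(dim))
        self.fc1 = self.add_module("fc1", Linear(dim, hidden, rng))
        self.act = self.add_module("act", ReLU())
        self.fc2 = self.add_module("fc2", Linear(hidden, dim, rng))
        # near-identity start: residual branches contribute little at init so
        # early training is carried by the (translation-equivariant) conv path
        self.attn._params["Wo"] *= 0.1
        self.fc2._params["W"] *= 0.1

    def forward(self, x, train=False):
        h = x + self.attn(self.ln1(x, train), train)
        return h + self.fc2(self.act(self.fc1(self.ln2(h, train), train), train), train)

    def backward(self, dy):
        dh = dy + self.ln2.backward(self.fc1.backward(self.act.backward(self.fc2.backward(dy))))
        return dh + self.ln1.backward(self.attn.backward(dh))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self.add_module(str(i), layer)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam restricted to a named subset of a model's parameters.

    Only parameters in ``trainable`` are ever touched, which is what makes
    the fine-tuning freeze contract a structural guarantee rather than a
    convention.
    """

    def __init__(
        self,
        model: Module,
        trainable: set[str],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.model = model
        all_names = set(model.named_parameters())
        unknown = trainable - all_names
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        self.trainable = sorted(trainable)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        params = model.named_parameters()
        self._m = {n: np.zeros_like(params[n]) for n in self.trainable}
        self._v = {n: np.zeros_like(params[n]) for n in self.trainable}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        params = self.model.named_parameters()
        grads = self.model.named_grads()
        c1 = 1 - self.b1**self._t
        c2 = 1 - self.b2**self._t
        for n in self.trainable:
            g = grads[n]
            self._m[n] = self.b1 * self._m[n] + (1 - self.b1) * g
            self._v[n] = self.b2 * self._v[n] + (1 - self.b2) * g * g
            params[n] -= self.lr * (self._m[n] / c1) / (np.sqrt(self._v[n] / c2) + self.eps)
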