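"""A compact, fully seeded numpy neural-network toolkit.

Implements exactly the pieces the pipeline's networks need — valid-padding
2-D convolution, dense layers, ReLU, batch normalization, dropout and a
softmax cross-entropy head — with Adam training. Everything is deterministic
given the seed: weight initialization, batch shuffling and dropout masks all
draw from one ``numpy.random.Generator``, so repeated training runs
reproduce metrics bit for bit.

Tensors are ``(N, H, W, C)`` for images and ``(N, D)`` for features,
float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: subclasses fill ``params``/``grads`` dicts by name."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv2D(Layer):
    """Valid-padding 2-D convolution, stride >= 1, He-initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int],
                 stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        kh, kw = kernel
        self.kh, self.kw, self.stride = kh, kw, stride
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (kh * kw * c_in))
        self.params["W"] = (rng.standard_normal((c_in * kh * kw, c_out)) * scale
                            ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, train, rng):
        s = self.stride
        win = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        win = win[:, ::s, ::s]  # (N, Ho, Wo, C, kh, kw)
        n, ho, wo = win.shape[:3]
        cols = win.reshape(n, ho, wo, -1)
        self._cache = (x.shape, cols)
        out = cols @ self.params["W"] + self.params["b"]
        return out.astype(np.float32)

    def backward(self, dout):
        x_shape, cols = self._cache
        n, ho, wo, _ = dout.shape
        flat_cols = cols.reshape(-1, cols.shape[-1])
        flat_dout = dout.reshape(-1, self.c_out)
        self.grads["W"] = (flat_cols.T @ flat_dout).astype(np.float32)
        self.grads["b"] = flat_dout.sum(axis=0).astype(np.float32)
        dcols = (flat_dout @ self.params["W"].T).reshape(
            n, ho, wo, self.c_in, self.kh, self.kw
        )
        dx = np.zeros(x_shape, dtype=np.float32)
        s = self.stride
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i : i + ho * s : s, j : j + wo * s : s, :] += \
                    dcols[:, :, :, :, i, j]
        return dx


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.params["W"] = (rng.standard_normal((d_in, d_out)) * scale
                            ).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (self._x.T @ dout).astype(np.float32)
        self.grads["b"] = dout.sum(axis=0).astype(np.float32)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalization over the feature axis of (N, D) inputs."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(dim, dtype=np.float32)
        self.params["beta"] = np.zeros(dim, dtype=np.float32)
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train, rng):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv = self._cache
        n = dout.shape[0]
        self.grads["gamma"] = (dout * xhat).sum(axis=0).astype(np.float32)
        self.grads["beta"] = dout.sum(axis=0).astype(np.float32)
        dxhat = dout * self.params["gamma"]
        dx = (inv / n) * (n * dxhat - dxhat.sum(axis=0)
                          - xhat * (dxhat * xhat).sum(axis=0))
        return dx.astype(np.float32)


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask.astype(np.float32)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    """A feed-forward stack trained with Adam on softmax cross-entropy."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(outs) if outs else np.empty((0, 2))

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    # -- training ----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int,
        batch_size: int,
        lr: float,
        rng: np.random.Generator,
        sample_weight: np.ndarray | None = None,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> dict[str, list[float]]:
        """Train with Adam; returns per-epoch loss (and val accuracy) history."""
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        n = len(x)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        state = _AdamState(self.layers, lr)
        history: dict[str, list[float]] = {"loss": []}
        if x_val is not None:
            history["val_accuracy"] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            total, wsum = 0.0, 0.0
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb, wb = x[idx], y[idx], w[idx]
                logits = self.forward(xb, train=True, rng=rng)
                probs = softmax(logits)
                eps = 1e-12
                losses = -np.log(probs[np.arange(len(yb)), yb] + eps)
                total += float((losses * wb).sum())
                wsum += float(wb.sum())
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits *= (wb / wb.sum())[:, None]
                grad = dlogits.astype(np.float32)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                state.step(self.layers)
            history["loss"].append(total / max(wsum, 1e-12))
            if x_val is not None:
                pred = self.predict_proba(x_val).argmax(axis=1)
                history["val_accuracy"].append(float((pred == y_val).mean()))
        return history

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                state[f"{i}.{name}"] = p
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"{i}.{name}"], np.float32)
            if isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(state[f"{i}.running_mean"], np.float32)
                layer.running_var = np.asarray(state[f"{i}.running_var"], np.float32)


class _AdamState:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in la.params.items()} for la in layers]
        self.v = [{k: np.zeros_like(v) for k, v in la.params.items()} for la in layers]

    def step(self, layers):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for la, m, v in zip(layers, self.m, self.v):
            for k, p in la.params.items():
                g = la.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
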