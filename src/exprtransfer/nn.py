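"""Minimal feed-forward neural network engine.

Dense layers with relu/elu/softplus/linear activations, inverted dropout,
an Adam optimizer and manual reverse-mode gradients. The models in this
package are small multilayer perceptrons over a few hundred genes, so a
compact numpy implementation is both sufficient and fully inspectable;
its gradients are verified against finite differences in the test suite.

All forward passes are functional: ``forward`` returns ``(output, cache)``
and ``backward(grad, cache)`` returns ``(grad_input, param_grads)``, so the
same parameter set can be run through several passes per step (the shared
decoder of the transferor) and the parameter gradients summed.
"""

from __future__ import annotations

import hashlib

import numpy as np

SUPPORTED_ACTIVATIONS = ("relu", "elu", "softplus", "linear")


def activation_fn(name: str, x):
    """Apply a named activation elementwise.

    relu: max(0, x); softplus: ln(1 + e^x); linear: x;
    elu: e^x - 1 for x <= 0 and x for x > 0.
    """
    x = np.asarray(x, dtype=float)
    if name == "relu":
        return np.maximum(0.0, x)
    if name == "elu":
        return np.where(x > 0, x, np.expm1(x))
    if name == "softplus":
        # log1p(exp(x)) overflows for large x; use the stable split form.
        return np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))
    if name == "linear":
        return x
    raise ValueError(f"unknown activation {name!r}; supported: {SUPPORTED_ACTIVATIONS}")


def activation_grad(name: str, x):
    x = np.asarray(x, dtype=float)
    if name == "relu":
        return (x > 0).astype(float)
    if name == "elu":
        return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))
    if name == "softplus":
        return 1.0 / (1.0 + np.exp(-x))
    if name == "linear":
        return np.ones_like(x)
    raise ValueError(f"unknown activation {name!r}; supported: {SUPPORTED_ACTIVATIONS}")


class Dense:
    """Affine layer y = xW + b with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        return x @ self.W + self.b, x

    def backward(self, grad, cache):
        x = cache
        dW = x.T @ grad
        db = grad.sum(axis=0)
        dx = grad @ self.W.T
        return dx, [dW, db]


class MLP:
    """Stack of Dense layers with a shared hidden activation and dropout.

    ``sizes`` lists the full width sequence including input and output; the
    hidden activation is applied after every layer but the last, which uses
    ``out_activation`` (default linear). Dropout (inverted, rate ``dropout``)
    follows each hidden activation during training only.
    """

    def __init__(self, sizes, activation="relu", dropout=0.0,
                 out_activation="linear", rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output widths")
        if any(int(s) < 1 for s in sizes):
            raise ValueError("all layer widths must be >= 1")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        if activation not in SUPPORTED_ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        if out_activation not in SUPPORTED_ACTIVATIONS:
            raise ValueError(f"unknown activation {out_activation!r}")
        self.sizes = [int(s) for s in sizes]
        self.activation = activation
        self.out_activation = out_activation
        self.dropout = float(dropout)
        self.layers = [
            Dense(self.sizes[i], self.sizes[i + 1], rng)
            for i in range(len(self.sizes) - 1)
        ]

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x, train=False, rng=None):
        """Run the network; returns (output, cache) for backward."""
        x = np.asarray(x, dtype=float)
        caches = []
        h = x
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            h, lin_cache = layer.forward(h)
            act = self.activation if i < n - 1 else self.out_activation
            pre = h
            h = activation_fn(act, pre)
            mask = None
            if train and self.dropout > 0 and i < n - 1:
                if rng is None:
                    raise ValueError("dropout during training requires an rng")
                keep = 1.0 - self.dropout
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
            caches.append((lin_cache, pre, mask))
        return h, caches

    def backward(self, grad, caches):
        """Backpropagate; returns (grad wrt input, per-parameter grads)."""
        n = len(self.layers)
        param_grads = [None] * (2 * n)
        g = np.asarray(grad, dtype=float)
        for i in range(n - 1, -1, -1):
            lin_cache, pre, mask = caches[i]
            if mask is not None:
                g = g * mask
            act = self.activation if i < n - 1 else self.out_activation
            g = g * activation_grad(act, pre)
            g, (dW, db) = self.layers[i].backward(g, lin_cache)
            param_grads[2 * i] = dW
            param_grads[2 * i + 1] = db
        return g, param_grads


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred, target):
    """Per-element mean squared error and its gradient wrt pred."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    diff = pred - target
    value = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return value, grad


def cosine_distance_rows(pred, target, eps=1e-12):
    """Mean over rows of 1 - cos(pred_i, target_i), with gradient wrt pred.

    An ``eps`` guard on the norms keeps the value and gradient finite for
    vanishing vectors; for any vector of non-negligible norm the result is
    identical to the exact cosine distance to float precision.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    nu = np.linalg.norm(pred, axis=1, keepdims=True) + eps
    nv = np.linalg.norm(target, axis=1, keepdims=True) + eps
    dot = np.sum(pred * target, axis=1, keepdims=True)
    cos = dot / (nu * nv)
    value = float(np.mean(1.0 - cos))
    n = pred.shape[0]
    # d(1-cos)/dpred = -(target/(nu*nv) - cos * pred/nu^2)
    grad = -(target / (nu * nv) - cos * pred / (nu * nu)) / n
    return value, grad


def params_checksum(params) -> str:
    """SHA-256 over the exact bytes of a parameter list (order-sensitive)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p).tobytes())
        h.update(str(p.shape).encode())
    return h.hexdigest()
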