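"""A compact numpy neural-network engine with relevance-propagation hooks.

The classifier in this package is a small 3D convolutional network.  Because
explanation by layer-wise relevance propagation (LRP) needs direct access to
every layer's cached input and linear pre-activations, the network is
implemented here as an explicit stack of layers on plain numpy arrays:
``Conv3d``, ``Dense``, ``AvgPool3d``, ``GlobalAvgPool``, ``Flatten`` and
``ReLU``, trained with Adam on the softmax cross-entropy.

Every linear layer exposes two primitives shared by backpropagation and LRP:
``_input_grad`` (the adjoint of the layer's linear map) and the cached
forward input.  The ε-stabilized LRP rule for a linear layer is then

    R_in = x ⊙ Jᵀ( R_out / (z + ε·sign(z)) )

with z the layer's output.  Layers are bias-free by default: bias terms
absorb relevance under the ε-rule and would break the conservation property
Σ R_in ≈ Σ R_out that makes heatmaps comparable across subjects.

Arrays are batched: convolutional layers take (N, C, D, H, W), dense layers
(N, F).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Dense", "Conv3d", "ReLU", "AvgPool3d", "GlobalAvgPool",
    "Flatten", "Sequential", "softmax",
]


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _stabilize(z, eps):
    """z + ε·sign(z), with sign(0) taken as +1."""
    s = np.where(z >= 0, 1.0, -1.0)
    return z + eps * s


class Layer:
    """Base layer; subclasses cache their forward input for LRP."""

    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []
        self._x = None

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - abstract
        raise NotImplementedError

    def relprop(self, r, eps):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class _LinearLayer(Layer):
    """Shared ε-rule relevance propagation for purely linear layers."""

    def _linear(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def _input_grad(self, g):  # pragma: no cover - abstract
        raise NotImplementedError

    def relprop(self, r, eps):
        z = self._linear(self._x)
        s = r / _stabilize(z, eps)
        return self._x * self._input_grad(s)


class Dense(_LinearLayer):
    """Fully connected layer y = x Wᵀ (+ b)."""

    def __init__(self, n_in, n_out, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_out, n_in))
        self.b = np.zeros(n_out) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])
        self._reset_grads()

    def _reset_grads(self):
        self.grads = [np.zeros_like(p) for p in self.params]

    def _linear(self, x):
        y = x @ self.w.T
        if self.b is not None:
            y = y + self.b
        return y

    def forward(self, x):
        self._x = x
        return self._linear(x)

    def _input_grad(self, g):
        return g @ self.w

    def backward(self, g):
        self.grads[0] += g.T @ self._x
        if self.b is not None:
            self.grads[1] += g.sum(axis=0)
        return self._input_grad(g)


class Conv3d(_LinearLayer):
    """3D convolution (cross-correlation), 'valid' padding, stride 1."""

    def __init__(self, c_in, c_out, kernel_size=3, bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = int(kernel_size)
        self.k = k
        scale = np.sqrt(2.0 / (c_in * k**3))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k, k))
        self.b = np.zeros(c_out) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])
        self._reset_grads()

    def _reset_grads(self):
        self.grads = [np.zeros_like(p) for p in self.params]

    def _linear(self, x):
        win = sliding_window_view(x, (self.k,) * 3, axis=(2, 3, 4))
        y = np.einsum("ncdhwijk,ocijk->nodhw", win, self.w, optimize=True)
        if self.b is not None:
            y = y + self.b[None, :, None, None, None]
        return y

    def forward(self, x):
        self._x = x
        return self._linear(x)

    def _input_grad(self, g):
        # Full correlation of the upstream gradient with the flipped kernel.
        k = self.k
        gp = np.pad(g, ((0, 0), (0, 0)) + ((k - 1, k - 1),) * 3)
        win = sliding_window_view(gp, (k,) * 3, axis=(2, 3, 4))
        w_flip = self.w[:, :, ::-1, ::-1, ::-1]
        return np.einsum("nodhwijk,ocijk->ncdhw", win, w_flip, optimize=True)

    def backward(self, g):
        win = sliding_window_view(self._x, g.shape[2:], axis=(2, 3, 4))
        self.grads[0] += np.einsum(
            "ncijkdhw,nodhw->ocijk", win, g, optimize=True
        )
        if self.b is not None:
            self.grads[1] += g.sum(axis=(0, 2, 3, 4))
        return self._input_grad(g)


class AvgPool3d(_LinearLayer):
    """Non-overlapping average pooling; trailing remainders are cropped."""

    def __init__(self, factor):
        super().__init__()
        self.f = int(factor)
        self.params, self.grads = [], []

    def _crop(self, x):
        f = self.f
        _, _, d, h, w = x.shape
        return x[:, :, : d - d % f, : h - h % f, : w - w % f]

    def _linear(self, x):
        f = self.f
        xc = self._crop(x)
        n, c, d, h, w = xc.shape
        return xc.reshape(n, c, d // f, f, h // f, f, w // f, f).mean(
            axis=(3, 5, 7)
        )

    def forward(self, x):
        self._x = x
        return self._linear(x)

    def _input_grad(self, g):
        f = self.f
        up = np.repeat(np.repeat(np.repeat(g, f, 2), f, 3), f, 4) / f**3
        out = np.zeros_like(self._x)
        out[:, :, : up.shape[2], : up.shape[3], : up.shape[4]] = up
        return out

    def backward(self, g):
        return self._input_grad(g)


class GlobalAvgPool(_LinearLayer):
    """Average over all spatial positions: (N,C,D,H,W) → (N,C)."""

    def __init__(self):
        super().__init__()

    def _linear(self, x):
        return x.mean(axis=(2, 3, 4))

    def forward(self, x):
        self._x = x
        return self._linear(x)

    def _input_grad(self, g):
        n, c, d, h, w = self._x.shape
        return np.broadcast_to(
            g[:, :, None, None, None], self._x.shape
        ) / (d * h * w)

    def backward(self, g):
        return self._input_grad(g)


class Flatten(Layer):
    def forward(self, x):
        self._x = x
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._x.shape)

    def relprop(self, r, eps):
        return r.reshape(self._x.shape)


class ReLU(Layer):
    """Rectifier; relevance passes through unchanged (inactive units carry
    zero output, hence zero downstream relevance already)."""

    def forward(self, x):
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, g):
        return g * (self._x > 0)

    def relprop(self, r, eps):
        return r


class Sequential:
    """A feed-forward layer stack with Adam training and LRP propagation."""

    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self):
        return [g for lay in self.layers for g in lay.grads]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    __call__ = forward

    def zero_grad(self):
        for lay in self.layers:
            for g in lay.grads:
                g[...] = 0.0

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def relprop(self, r, eps=1e-6):
        """Propagate output-layer relevance back to the input (after a
        forward pass has cached layer inputs)."""
        for lay in reversed(self.layers):
            try:
                r = lay.relprop(r, eps)
            except NotImplementedError:
                raise TypeError(
                    f"layer {type(lay).__name__} does not support relevance "
                    "propagation"
                ) from None
        return r

    def fit(
        self,
        x,
        y,
        epochs=150,
        lr=1e-2,
        weight_decay=0.0,
        batch_size=None,
        seed=0,
        x_val=None,
        y_val=None,
        patience=30,
        verbose=False,
    ):
        """Adam on softmax cross-entropy; optional early stopping on
        validation balanced accuracy (restores the best parameters)."""
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        params = self.params
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        t = 0
        best_score, best_state, since_best = -np.inf, None, 0
        history = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            bs = batch_size or n
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb, yb = x[idx], y[idx]
                self.zero_grad()
                logits = self.forward(xb)
                probs = softmax(logits)
                grad = probs.copy()
                grad[np.arange(len(idx)), yb] -= 1.0
                grad /= len(idx)
                self.backward(grad)
                t += 1
                for p, g, mi, vi in zip(params, self.grads, m, v):
                    if weight_decay:
                        g = g + weight_decay * p
                    mi[...] = beta1 * mi + (1 - beta1) * g
                    vi[...] = beta2 * vi + (1 - beta2) * g**2
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + adam_eps)
            if x_val is not None:
                score = _bac_fraction(self.predict(x_val), y_val)
                history.append(score)
                if score > best_score:
                    best_score = score
                    best_state = [p.copy() for p in params]
                    since_best = 0
                else:
                    since_best += 1
                    if since_best >= patience:
                        break
        if best_state is not None:
            for p, bp in zip(params, best_state):
                p[...] = bp
        return history

    def predict_scores(self, x):
        return self.forward(x)

    def predict(self, x):
        return np.argmax(self.forward(x), axis=1)


def _bac_fraction(pred, y):
    """Balanced accuracy as a fraction (internal model-selection score)."""
    accs = []
    for cls in np.unique(y):
        sel = y == cls
        accs.append((pred[sel] == cls).mean())
    return float(np.mean(accs))
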