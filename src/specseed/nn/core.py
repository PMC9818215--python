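"""Small 1-D CNN engine in numpy: layers, backprop, Adam.

Built for spectra (short 1-D sequences, small batches) with exact, fully
deterministic arithmetic given a seed.  Convolutions are im2col GEMMs in
float32; every layer implements ``forward`` / ``backward`` with explicit
caches, and trainable tensors are ``Param`` objects so the optimizer and the
L2 penalty can iterate over them uniformly.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """Trainable tensor with gradient and an L2-penalty flag."""

    __slots__ = ("value", "grad", "l2")

    def __init__(self, value: np.ndarray, l2: bool = False):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.l2 = l2


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y_onehot: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch; returns (loss, dlogits, probs)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -float(np.sum(y_onehot * np.log(np.clip(p, 1e-12, 1.0)))) / n
    dlogits = ((p - y_onehot) / n).astype(DTYPE)
    return loss, dlogits, p


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class FWGate(Layer):
    """Feature-weight gate: softmax-normalized per-band scores multiply the input.

    The trainable score vector w (length L) yields coefficients
    c = softmax(w), strictly positive and summing to one, and the layer
    outputs c * x elementwise.  A penalty lambda_reg * sum(c^2) discourages
    concentrating mass before the data demand it; its gradient with respect
    to the scores, 2*lambda*c_j*(c_j - sum(c^2)), is added during backward.
    """

    def __init__(self, L: int, lambda_reg: float = 0.0):
        self.scores = Param(np.zeros(L), l2=False)
        self.lambda_reg = float(lambda_reg)
        self._x: np.ndarray | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return softmax(self.scores.value.astype(np.float64))

    def regularizer(self) -> float:
        c = self.coefficients
        return self.lambda_reg * float(np.sum(c**2))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        c = self.coefficients.astype(DTYPE)
        return x * c[None, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        c = self.coefficients
        gx = (g * self._x).sum(axis=0).astype(np.float64)  # dL/dc
        dscores = c * (gx - float(c @ gx))
        if self.lambda_reg:
            R = float(np.sum(c**2))
            dscores = dscores + self.lambda_reg * 2.0 * c * (c - R)
        self.scores.grad = dscores.astype(DTYPE)
        return g * c.astype(DTYPE)[None, :]

    def params(self) -> list[Param]:
        return [self.scores]


class SEGate(Layer):
    """Squeeze-excitation gate for band-channels of unit spatial extent.

    With the squeeze an identity (each band is its own channel), the
    excitation is s = sigmoid(relu(x @ W1) @ W2) with bottleneck width
    max(1, floor(L/r)), and the output is s * x.  No biases; the gate can
    shrink but never change the sign of an input component.
    """

    def __init__(self, L: int, r: int = 8, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        m = max(1, L // r)
        lim1 = np.sqrt(6.0 / (L + m))
        lim2 = np.sqrt(6.0 / (m + L))
        self.W1 = Param(rng.uniform(-lim1, lim1, size=(L, m)), l2=False)
        self.W2 = Param(rng.uniform(-lim2, lim2, size=(m, L)), l2=False)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        u = x @ self.W1.value
        h = np.maximum(u, 0.0)
        s = 1.0 / (1.0 + np.exp(-(h @ self.W2.value)))
        self._cache = (x, u, h, s)
        return (s * x).astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, u, h, s = self._cache
        ds = g * x * s * (1.0 - s)
        self.W2.grad = (h.T @ ds).astype(DTYPE)
        dh = ds @ self.W2.value.T
        du = dh * (u > 0)
        self.W1.grad = (x.T @ du).astype(DTYPE)
        dx = du @ self.W1.value.T
        return (g * s + dx).astype(DTYPE)

    def params(self) -> list[Param]:
        return [self.W1, self.W2]

    def gate(self, x: np.ndarray) -> np.ndarray:
        """Excitation weights s for given input (inference helper)."""
        h = np.maximum(x @ self.W1.value, 0.0)
        return 1.0 / (1.0 + np.exp(-(h @ self.W2.value)))


class ExpandDims(Layer):
    """(N, L) -> (N, L, 1) so a gated spectrum enters the conv stack."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x[:, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g[:, :, 0]


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1, via im2col GEMM.

    Input (N, len, in_ch) -> output (N, len-width+1, filters).  Kernels are
    Glorot-uniform initialized and carry the L2 flag.
    """

    def __init__(
        self,
        in_ch: int,
        filters: int,
        width: int,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = width * in_ch
        fan_out = width * filters
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = Param(rng.uniform(-lim, lim, size=(fan_in, filters)), l2=True)
        self.b = Param(np.zeros(filters), l2=False)
        self.width = width
        self.in_ch = in_ch
        self.filters = filters
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, length, C = x.shape
        if length < self.width:
            raise ValueError(f"input length {length} < kernel width {self.width}")
        self._in_len = length
        out_len = length - self.width + 1
        win = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        # (N, out_len, C, width) -> (N*out_len, width*C)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            N * out_len, self.width * C
        )
        self._cols = cols if train else None
        y = cols @ self.W.value + self.b.value
        return y.reshape(N, out_len, self.filters)

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, out_len, F = g.shape
        gf = g.reshape(N * out_len, F)
        self.W.grad = self._cols.T @ gf
        self.b.grad = gf.sum(axis=0)
        dcols = (gf @ self.W.value.T).reshape(N, out_len, self.width, self.in_ch)
        dx = np.zeros((N, self._in_len, self.in_ch), dtype=DTYPE)
        for j in range(self.width):
            dx[:, j : j + out_len, :] += dcols[:, :, j, :]
        return dx

    def params(self) -> list[Param]:
        return [self.W, self.b]


class MaxPool1D(Layer):
    """Max pooling, window 2, stride 1; identity on length-1 inputs."""

    def __init__(self):
        self._mask: np.ndarray | None = None
        self._skip = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] < 2:
            self._skip = True
            return x
        self._skip = False
        a, b = x[:, :-1], x[:, 1:]
        if not train:
            return np.maximum(a, b)
        self._mask = a >= b  # ties go left
        return np.where(self._mask, a, b)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._skip:
            return g
        dx = np.zeros(
            (g.shape[0], g.shape[1] + 1) + g.shape[2:], dtype=g.dtype
        )
        left = g * self._mask
        dx[:, :-1] += left
        g -= left  # remainder routes right
        dx[:, 1:] += g
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._pos = x > 0
        return np.maximum(x, 0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        # upstream gradients are freshly allocated; in-place is safe
        g *= self._pos
        return g


class ELU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        neg = x < 0
        y[neg] = np.expm1(x[neg])
        if train:
            deriv = np.ones_like(y)
            deriv[neg] = y[neg] + 1.0  # d/dx expm1(x) = exp(x) = y + 1
            self._deriv = deriv
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        g *= self._deriv
        return g


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None
    ):
        rng = rng or np.random.default_rng()
        lim = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Param(rng.uniform(-lim, lim, size=(in_dim, out_dim)), l2=True)
        self.b = Param(np.zeros(out_dim), l2=False)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad = self._x.T @ g
        self.b.grad = g.sum(axis=0)
        return g @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        self.rate = float(rate)
        self.rng = rng or np.random.default_rng()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return (g * self._mask).astype(DTYPE)


class Network:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def l2_penalty(self, coef: float) -> float:
        return coef * sum(float(np.sum(p.value.astype(np.float64) ** 2))
                          for p in self.params() if p.l2)

    def predict_proba(self, x: np.ndarray, chunk: int = 128) -> np.ndarray:
        """Softmax class probabilities, evaluated in chunks to bound memory."""
        x = np.asarray(x, dtype=DTYPE)
        outs = [
            self.forward(x[i : i + chunk], train=False).astype(np.float64)
            for i in range(0, x.shape[0], chunk)
        ]
        return softmax(np.concatenate(outs, axis=0))


class Adam:
    """Adam with inverse-time learning-rate decay lr = lr0 / (1 + decay*step).

    ``weight_decay`` is applied decoupled from the adaptive step (AdamW
    convention): kernels flagged ``l2`` shrink by ``lr * wd * value`` each
    update.  Folding the penalty into the gradient instead would let Adam's
    per-coordinate normalization blow the decay up to the full learning
    rate whenever data gradients are small, collapsing the network.
    """

    def __init__(
        self,
        params: list[Param],
        lr0: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        decay: float = 1e-4,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr0, self.beta1, self.beta2, self.eps, self.decay = (
            lr0, beta1, beta2, eps, decay,
        )
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        lr = self.lr0 / (1.0 + self.decay * self.t)
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
            if self.weight_decay and p.l2:
                p.value -= (lr * self.weight_decay) * p.value


def fit_network(
    net: Network,
    X: np.ndarray,
    y_onehot: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    lr0: float = 1e-3,
    beta1: float = 0.9,
    lr_decay: float = 1e-4,
    weight_decay: float = 0.0,
    rng: np.random.Generator,
    eval_sets: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    extra_loss: callable | None = None,
) -> dict[str, np.ndarray]:
    """Mini-batch Adam training of a softmax classifier network.

    ``weight_decay`` is the L2 coefficient applied to kernels flagged ``l2``
    (decoupled, AdamW-style; see ``Adam``).  ``extra_loss`` is an optional
    callable returning an additional reported loss term (e.g. the FW-gate
    penalty, whose gradient the gate layer itself contributes).  Returns a
    history dict with per-epoch mean training loss and accuracy (accumulated
    over the minibatch forward passes, as Keras reports them) and, for each
    extra eval set, per-epoch accuracy and loss.  Raises on divergence
    (NaN loss).
    """
    X = np.asarray(X, dtype=DTYPE)
    y_onehot = np.asarray(y_onehot, dtype=DTYPE)
    n = X.shape[0]
    params = net.params()
    opt = Adam(params, lr0=lr0, beta1=beta1, decay=lr_decay,
               weight_decay=weight_decay)
    history: dict[str, list[float]] = {"loss": [], "train_acc": []}
    if eval_sets:
        for name in eval_sets:
            history[f"{name}_acc"] = []
            history[f"{name}_loss"] = []

    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        n_correct = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = net.forward(X[idx], train=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, y_onehot[idx])
            if extra_loss is not None:
                loss += float(extra_loss())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss!r}) at step {opt.t}"
                )
            n_correct += int(
                np.sum(probs.argmax(axis=1) == y_onehot[idx].argmax(axis=1))
            )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(n_correct / n)
        if eval_sets:
            for name, (Xe, ye) in eval_sets.items():
                probs = net.predict_proba(Xe)
                loss_e = -float(
                    np.mean(
                        np.sum(ye * np.log(np.clip(probs, 1e-12, 1.0)), axis=1)
                    )
                )
                acc = float(
                    np.mean(probs.argmax(axis=1) == np.argmax(ye, axis=1))
                )
                history[f"{name}_acc"].append(acc)
                history[f"{name}_loss"].append(loss_e)
    return {k: np.array(v) for k, v in history.items()}
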