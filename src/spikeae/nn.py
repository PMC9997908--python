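"""Minimal numpy neural-network core used by the autoencoder variants.

Implements exactly what the variants need and nothing more: dense layers
(optionally weight-tied to a partner layer), stacked LSTM layers with full
backpropagation through time, the Adam optimizer, and the machinery for the
contractive penalty lambda * ||J_f(x)||_F^2 (exact Jacobian evaluation plus an
unbiased forward-mode estimator whose gradient is backpropagated
analytically).

Conventions: row-major batches (n, d); dense weights have shape
(d_in, d_out) so a layer computes ``A = act(X @ W + b)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "LSTM",
    "Adam",
    "glorot",
    "ACTIVATIONS",
    "encoder_jacobians",
    "contractive_forward_backward",
]


# ---------------------------------------------------------------------------
# Activations: value, first derivative (as a function of the value where
# possible), and second derivative for the contractive double-backward.
# ---------------------------------------------------------------------------

def _relu(z):
    return np.maximum(z, 0.0)


def _relu_prime(z, a):
    return (z > 0).astype(float)


def _relu_second(z, a):
    return np.zeros_like(z)


def _tanh(z):
    return np.tanh(z)


def _tanh_prime(z, a):
    return 1.0 - a * a


def _tanh_second(z, a):
    return -2.0 * a * (1.0 - a * a)


def _linear(z):
    return z


def _linear_prime(z, a):
    return np.ones_like(z)


def _linear_second(z, a):
    return np.zeros_like(z)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


ACTIVATIONS = {
    "relu": (_relu, _relu_prime, _relu_second),
    "tanh": (_tanh, _tanh_prime, _tanh_second),
    "linear": (_linear, _linear_prime, _linear_second),
}


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


# ---------------------------------------------------------------------------
# Dense layer (optionally tied)
# ---------------------------------------------------------------------------

class Dense:
    """Fully connected layer ``A = act(X @ W + b)``.

    When ``tied_to`` is another Dense layer, this layer's weight matrix is the
    transpose of the partner's at all times; gradients w.r.t. the shared
    matrix are accumulated into the partner and only the bias is owned here.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str,
        rng: np.random.Generator,
        tied_to: "Dense | None" = None,
    ):
        self.n_in, self.n_out = n_in, n_out
        self.activation = activation
        self.act, self.act_prime, self.act_second = ACTIVATIONS[activation]
        self.tied_to = tied_to
        if tied_to is None:
            self.W_own = glorot(rng, n_in, n_out)
        else:
            if (tied_to.n_out, tied_to.n_in) != (n_in, n_out):
                raise ValueError("tied partner has incompatible shape")
            self.W_own = None
        self.b = np.zeros(n_out)
        self.dW = np.zeros((n_in, n_out)) if tied_to is None else None
        self.db = np.zeros(n_out)
        self.X = self.Z = self.A = None

    @property
    def W(self) -> np.ndarray:
        return self.W_own if self.tied_to is None else self.tied_to.W_own.T

    def zero_grad(self) -> None:
        if self.dW is not None:
            self.dW[...] = 0.0
        self.db[...] = 0.0

    def forward(self, X: np.ndarray) -> np.ndarray:
        self.X = X
        self.Z = X @ self.W + self.b
        self.A = self.act(self.Z)
        return self.A

    def backward(self, dA: np.ndarray) -> np.ndarray:
        dZ = dA * self.act_prime(self.Z, self.A)
        self.accumulate_dW(self.X.T @ dZ)
        self.db += dZ.sum(axis=0)
        return dZ @ self.W.T

    def accumulate_dW(self, g: np.ndarray) -> None:
        if self.tied_to is None:
            self.dW += g
        else:
            self.tied_to.dW += g.T

    def params(self):
        if self.tied_to is None:
            return [("W", self.W_own, self.dW), ("b", self.b, self.db)]
        return [("b", self.b, self.db)]

    @property
    def n_params(self) -> int:
        return sum(p.size for _, p, _ in self.params())


# ---------------------------------------------------------------------------
# LSTM layer with BPTT
# ---------------------------------------------------------------------------

class LSTM:
    """Standard LSTM over batches of sequences, shape (n, T, d_in).

    Gate order in the stacked weight matrices is (input, forget, cell, output).
    ``return_sequences`` yields (n, T, H); otherwise the final hidden state
    (n, H). The forget-gate bias starts at 1.
    """

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        rng: np.random.Generator,
        return_sequences: bool = True,
    ):
        self.n_in, self.n_hidden = n_in, n_hidden
        self.return_sequences = return_sequences
        H = n_hidden
        self.Wx = glorot(rng, n_in, 4 * H)
        self.Wh = glorot(rng, H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def zero_grad(self) -> None:
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0

    def forward(self, X: np.ndarray) -> np.ndarray:
        n, T, _ = X.shape
        H = self.n_hidden
        hs = np.zeros((n, T + 1, H))
        cs = np.zeros((n, T + 1, H))
        gates = np.zeros((n, T, 4 * H))
        tanh_c = np.zeros((n, T, H))
        for t in range(T):
            z = X[:, t, :] @ self.Wx + hs[:, t, :] @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            cs[:, t + 1, :] = f * cs[:, t, :] + i * g
            tc = np.tanh(cs[:, t + 1, :])
            hs[:, t + 1, :] = o * tc
            gates[:, t, :] = np.concatenate([i, f, g, o], axis=1)
            tanh_c[:, t, :] = tc
        self._cache = (X, hs, cs, gates, tanh_c)
        return hs[:, 1:, :] if self.return_sequences else hs[:, -1, :]

    def backward(self, dOut: np.ndarray) -> np.ndarray:
        X, hs, cs, gates, tanh_c = self._cache
        n, T, _ = X.shape
        H = self.n_hidden
        if self.return_sequences:
            dH_seq = dOut
        else:
            dH_seq = np.zeros((n, T, H))
            dH_seq[:, -1, :] = dOut
        dX = np.zeros_like(X)
        dh_next = np.zeros((n, H))
        dc_next = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = tanh_c[:, t, :]
            dh = dH_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * cs[:, t, :]
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWx += X[:, t, :].T @ dz
            self.dWh += hs[:, t, :].T @ dz
            self.db += dz.sum(axis=0)
            dX[:, t, :] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dX

    def params(self):
        return [
            ("Wx", self.Wx, self.dWx),
            ("Wh", self.Wh, self.dWh),
            ("b", self.b, self.db),
        ]

    @property
    def n_params(self) -> int:
        return self.Wx.size + self.Wh.size + self.b.size


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, layers, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = {}
        for li, layer in enumerate(layers):
            for name, p, _ in layer.params():
                self.state[(li, name)] = (np.zeros_like(p), np.zeros_like(p))

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, p, g in layer.params():
                m, v = self.state[(li, name)]
                m[...] = self.b1 * m + (1 - self.b1) * g
                v[...] = self.b2 * v + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Contractive-penalty machinery
# ---------------------------------------------------------------------------

def encoder_jacobians(encoder_layers: list[Dense], X: np.ndarray) -> np.ndarray:
    """Exact per-sample Jacobians of the dense encoder map, shape (n, d_in, d_code).

    Chain product G_l = (G_{l-1} @ W_l) * act'(z_l), with G_0 = I.
    """
    n, d = X.shape
    A = X
    G = np.broadcast_to(np.eye(d), (n, d, d)).copy()
    for layer in encoder_layers:
        Z = A @ layer.W + layer.b
        A_next = layer.act(Z)
        s = layer.act_prime(Z, A_next)  # (n, d_out)
        G = np.einsum("nij,jk->nik", G, layer.W) * s[:, None, :]
        A = A_next
    return G


def contractive_forward_backward(
    encoder_layers: list[Dense],
    X: np.ndarray,
    rng: np.random.Generator,
    lam: float,
):
    """Hutchinson estimate of sum_x ||J_f(x)||_F^2 with analytic parameter grads.

    Forward-mode: v_0 = eps ~ N(0, I); u_l = v_{l-1} @ W_l;
    v_l = act'(z_l) * u_l, so E||v_L||^2 = ||J||_F^2 per sample (exact in
    expectation, no finite-difference step). The backward pass accumulates
    lam * d/dtheta of the estimate into the layers' gradient buffers, walking
    both the tangent stream and the act''(z) dependence.

    Returns the estimated penalty (already scaled by lam, summed over batch).
    """
    caches = []
    A = X
    V = rng.standard_normal(X.shape)
    for layer in encoder_layers:
        Z = A @ layer.W + layer.b
        A_next = layer.act(Z)
        s = layer.act_prime(Z, A_next)
        U = V @ layer.W
        V_next = s * U
        caches.append((A, Z, A_next, s, U, V))
        A, V = A_next, V_next
    penalty = float(np.sum(V * V))

    gV = 2.0 * V * lam
    gA = np.zeros_like(A)
    for layer, (A_prev, Z, A_cur, s, U, V_prev) in zip(
        reversed(encoder_layers), reversed(caches)
    ):
        gZ = gA * s
        gU = gV * s
        gZ += gV * U * layer.act_second(Z, A_cur)
        layer.accumulate_dW(V_prev.T @ gU + A_prev.T @ gZ)
        layer.db += gZ.sum(axis=0)
        gV = gU @ layer.W.T
        gA = gZ @ layer.W.T
    return lam * penalty
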