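"""Minimal recurrent-network engine (numpy, CPU).

Implements exactly what the AP-GRF regressor needs: stacked bidirectional
LSTM layers, a small fully-connected head read out at the sub-sequence
mid-point, inverted dropout, the smooth-L1 loss, and AdamW — with analytic
backpropagation throughout.  Everything is float32 and deterministic given
the seeds supplied by the caller.

Shapes: inputs are ``(batch, time, channels)``; LSTM gate order is
(input, forget, output, cell) — the three sigmoid gates are contiguous so
one vectorized ``expit`` call covers them; weights follow the convention
``z = x @ Wx + h_prev @ Wh + b`` with ``Wx: (D, 4H)``, ``Wh: (H, 4H)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Single-direction LSTM
# ---------------------------------------------------------------------------

def lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                 b: np.ndarray):
    """Run an LSTM over ``x`` (N, T, D); return outputs (N, T, H) + cache."""
    N, T, D = x.shape
    H = Wh.shape[0]
    xp = x.reshape(N * T, D) @ Wx
    xp = xp.reshape(N, T, 4 * H) + b
    Hs = np.empty((N, T, H), dtype=DTYPE)
    Cs = np.empty((N, T, H), dtype=DTYPE)
    Tc = np.empty((N, T, H), dtype=DTYPE)   # tanh(c), reused in backward
    G = np.empty((N, T, 4 * H), dtype=DTYPE)
    h = np.zeros((N, H), dtype=DTYPE)
    c = np.zeros((N, H), dtype=DTYPE)
    for t in range(T):
        z = xp[:, t] + h @ Wh
        gates = G[:, t]
        sigmoid(z[:, :3 * H], out=gates[:, :3 * H])      # i, f, o
        np.tanh(z[:, 3 * H:], out=gates[:, 3 * H:])      # g
        i = gates[:, :H]
        f = gates[:, H:2 * H]
        o = gates[:, 2 * H:3 * H]
        g = gates[:, 3 * H:]
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        Cs[:, t] = c
        Tc[:, t] = tc
        Hs[:, t] = h
    cache = (x, G, Cs, Tc, Hs)
    return Hs, cache


def lstm_forward_nocache(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                         b: np.ndarray) -> np.ndarray:
    """Inference-only LSTM pass: outputs (N, T, H) without gradient caches."""
    N, T, D = x.shape
    H = Wh.shape[0]
    xp = (x.reshape(N * T, D) @ Wx).reshape(N, T, 4 * H) + b
    Hs = np.empty((N, T, H), dtype=DTYPE)
    h = np.zeros((N, H), dtype=DTYPE)
    c = np.zeros((N, H), dtype=DTYPE)
    z = np.empty((N, 4 * H), dtype=DTYPE)
    for t in range(T):
        np.add(xp[:, t], h @ Wh, out=z)
        sigmoid(z[:, :3 * H], out=z[:, :3 * H])
        np.tanh(z[:, 3 * H:], out=z[:, 3 * H:])
        c = z[:, H:2 * H] * c + z[:, :H] * z[:, 3 * H:]
        h = z[:, 2 * H:3 * H] * np.tanh(c)
        Hs[:, t] = h
    return Hs


def lstm_backward(dH: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray):
    """Backprop through an LSTM given dL/doutputs ``dH`` (N, T, H)."""
    x, G, Cs, Tc, Hs = cache
    N, T, D = x.shape
    H = Wh.shape[0]
    dZ = np.empty((N, T, 4 * H), dtype=DTYPE)
    dh = np.zeros((N, H), dtype=DTYPE)
    dc = np.zeros((N, H), dtype=DTYPE)
    WhT = Wh.T.copy()
    for t in range(T - 1, -1, -1):
        dh_t = dH[:, t] + dh
        i = G[:, t, :H]
        f = G[:, t, H:2 * H]
        o = G[:, t, 2 * H:3 * H]
        g = G[:, t, 3 * H:]
        tc = Tc[:, t]
        do = dh_t * tc
        dct = dc + dh_t * o * (1.0 - tc * tc)
        c_prev = Cs[:, t - 1] if t > 0 else 0.0
        df = dct * c_prev
        di = dct * g
        dg = dct * i
        dZ[:, t, :H] = di * i * (1.0 - i)
        dZ[:, t, H:2 * H] = df * f * (1.0 - f)
        dZ[:, t, 2 * H:3 * H] = do * o * (1.0 - o)
        dZ[:, t, 3 * H:] = dg * (1.0 - g * g)
        dh = dZ[:, t] @ WhT
        dc = dct * f
    dZ2 = dZ.reshape(N * T, 4 * H)
    dWx = x.reshape(N * T, D).T @ dZ2
    dWh = np.zeros_like(Wh)
    for t in range(1, T):
        dWh += Hs[:, t - 1].T @ dZ[:, t]
    db = dZ2.sum(axis=0)
    dx = (dZ2 @ Wx.T).reshape(N, T, D)
    return dx, dWx, dWh, db


# ---------------------------------------------------------------------------
# Bidirectional layer
# ---------------------------------------------------------------------------

def bilstm_forward(x, params, layer):
    """Forward + time-reversed LSTM passes, outputs concatenated (N, T, 2H)."""
    Hf, cf = lstm_forward(x, params[f"l{layer}_f_Wx"],
                          params[f"l{layer}_f_Wh"], params[f"l{layer}_f_b"])
    xr = x[:, ::-1]
    Hb, cb = lstm_forward(np.ascontiguousarray(xr), params[f"l{layer}_b_Wx"],
                          params[f"l{layer}_b_Wh"], params[f"l{layer}_b_b"])
    out = np.concatenate([Hf, Hb[:, ::-1]], axis=2)
    return out, (cf, cb)


def bilstm_forward_nocache(x, params, layer):
    Hf = lstm_forward_nocache(x, params[f"l{layer}_f_Wx"],
                              params[f"l{layer}_f_Wh"], params[f"l{layer}_f_b"])
    Hb = lstm_forward_nocache(np.ascontiguousarray(x[:, ::-1]),
                              params[f"l{layer}_b_Wx"],
                              params[f"l{layer}_b_Wh"], params[f"l{layer}_b_b"])
    return np.concatenate([Hf, Hb[:, ::-1]], axis=2)


def bilstm_backward(dOut, caches, params, layer, grads):
    cf, cb = caches
    H = params[f"l{layer}_f_Wh"].shape[0]
    dxf, dWxf, dWhf, dbf = lstm_backward(
        np.ascontiguousarray(dOut[:, :, :H]), cf,
        params[f"l{layer}_f_Wx"], params[f"l{layer}_f_Wh"])
    dHb = np.ascontiguousarray(dOut[:, ::-1, H:])
    dxb, dWxb, dWhb, dbb = lstm_backward(
        dHb, cb, params[f"l{layer}_b_Wx"], params[f"l{layer}_b_Wh"])
    grads[f"l{layer}_f_Wx"] = dWxf
    grads[f"l{layer}_f_Wh"] = dWhf
    grads[f"l{layer}_f_b"] = dbf
    grads[f"l{layer}_b_Wx"] = dWxb
    grads[f"l{layer}_b_Wh"] = dWhb
    grads[f"l{layer}_b_b"] = dbb
    return dxf + dxb[:, ::-1]


# ---------------------------------------------------------------------------
# Full regressor
# ---------------------------------------------------------------------------

class BiLSTMRegressor:
    """Two bidirectional LSTM layers + dense head read at the mid-point.

    Architecture: BiLSTM(64) -> BiLSTM(64) -> dropout(0.2) on the mid-point
    output -> Dense(128, ReLU) -> Dense(64, ReLU) -> Dense(1).
    """

    def __init__(self, n_channels: int, hidden: int = 64,
                 dense: tuple[int, int] = (128, 64), dropout: float = 0.2,
                 t_mid: int = 11, seed: int = 0):
        self.n_channels = n_channels
        self.hidden = hidden
        self.dense = tuple(dense)
        self.dropout = dropout
        self.t_mid = t_mid
        rng = np.random.default_rng(seed)
        H = hidden
        self.params: dict[str, np.ndarray] = {}

        def uniform(shape, fan):
            k = 1.0 / np.sqrt(fan)
            return rng.uniform(-k, k, size=shape).astype(DTYPE)

        for layer, d_in in ((0, n_channels), (1, 2 * H)):
            for dirn in ("f", "b"):
                self.params[f"l{layer}_{dirn}_Wx"] = uniform((d_in, 4 * H), H)
                self.params[f"l{layer}_{dirn}_Wh"] = uniform((H, 4 * H), H)
                bias = np.zeros(4 * H, dtype=DTYPE)
                bias[H:2 * H] = 1.0  # forget-gate bias
                self.params[f"l{layer}_{dirn}_b"] = bias
        d1, d2 = self.dense
        self.params["W1"] = uniform((2 * H, d1), 2 * H)
        self.params["b1"] = np.zeros(d1, dtype=DTYPE)
        self.params["W2"] = uniform((d1, d2), d1)
        self.params["b2"] = np.zeros(d2, dtype=DTYPE)
        self.params["W3"] = uniform((d2, 1), d2)
        self.params["b3"] = np.zeros(1, dtype=DTYPE)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        out1, c1 = bilstm_forward(x, self.params, 0)
        out2, c2 = bilstm_forward(out1, self.params, 1)
        mid = out2[:, self.t_mid]
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            mask = (rng.random(mid.shape) >= self.dropout).astype(DTYPE)
            mask /= DTYPE(1.0 - self.dropout)
            mid = mid * mask
        else:
            mask = None
        z1 = mid @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.params["W2"] + self.params["b2"]
        a2 = np.maximum(z2, 0.0)
        y = (a2 @ self.params["W3"] + self.params["b3"])[:, 0]
        cache = (x, c1, c2, out1, out2, mask, mid, a1, a2)
        return y, cache

    def backward(self, dy: np.ndarray, cache) -> dict[str, np.ndarray]:
        x, c1, c2, out1, out2, mask, mid, a1, a2 = cache
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dy = dy.astype(DTYPE)[:, None]                      # (N, 1)
        grads["W3"] = a2.T @ dy
        grads["b3"] = dy.sum(axis=0)
        da2 = dy @ p["W3"].T
        dz2 = da2 * (a2 > 0)
        grads["W2"] = a1.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * (a1 > 0)
        grads["W1"] = mid.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dmid = dz1 @ p["W1"].T
        if mask is not None:
            dmid = dmid * mask
        dOut2 = np.zeros_like(out2)
        dOut2[:, self.t_mid] = dmid
        dOut1 = bilstm_backward(dOut2, c2, p, 1, grads)
        bilstm_backward(dOut1, c1, p, 0, grads)
        return grads

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic inference (dropout off), batched, cache-free."""
        outs = []
        p = self.params
        for s in range(0, len(x), batch_size):
            xb = np.ascontiguousarray(x[s:s + batch_size], dtype=DTYPE)
            out1 = bilstm_forward_nocache(xb, p, 0)
            out2 = bilstm_forward_nocache(out1, p, 1)
            mid = out2[:, self.t_mid]
            a1 = np.maximum(mid @ p["W1"] + p["b1"], 0.0)
            a2 = np.maximum(a1 @ p["W2"] + p["b2"], 0.0)
            outs.append((a2 @ p["W3"] + p["b3"])[:, 0])
        return np.concatenate(outs) if outs else np.empty(0, dtype=DTYPE)

    # -- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=DTYPE).copy()

    def config(self) -> dict:
        return {"n_channels": self.n_channels, "hidden": self.hidden,
                "dense": list(self.dense), "dropout": self.dropout,
                "t_mid": self.t_mid}

    @classmethod
    def from_config(cls, cfg: dict) -> "BiLSTMRegressor":
        return cls(n_channels=cfg["n_channels"], hidden=cfg["hidden"],
                   dense=tuple(cfg["dense"]), dropout=cfg["dropout"],
                   t_mid=cfg["t_mid"])


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def smooth_l1(pred: np.ndarray, target: np.ndarray,
              beta: float = 1.0) -> float:
    """Huber-style smooth L1 loss (mean over the batch)."""
    e = np.abs(pred - target)
    quad = 0.5 * e * e / beta
    lin = e - 0.5 * beta
    return float(np.mean(np.where(e < beta, quad, lin)))


def smooth_l1_grad(pred: np.ndarray, target: np.ndarray,
                   beta: float = 1.0) -> np.ndarray:
    """d(mean smooth-L1)/d(pred)."""
    e = pred - target
    return np.clip(e / beta, -1.0, 1.0) / len(pred)


class AdamW:
    """AdamW with decoupled weight decay (applied to every parameter)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k].astype(DTYPE)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= DTYPE(self.lr) * (mhat / (np.sqrt(vhat) + self.eps)
                                   + DTYPE(self.wd) * p)
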