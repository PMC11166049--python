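"""Minimal seed-reproducible recurrent regressors (LSTM / GRU) in numpy.

One recurrent layer followed by a dense readout of the hidden state at the
window's last time step. Trained with mean-squared-error loss, Adam, and
early stopping on validation MAE; optional inverted dropout on the readout
input and an optional Gaussian-noise layer on the (standardized) inputs
during training — the latter serves the overfitting diagnostic.

Inputs are windows shaped (n_windows, window, n_features); targets are the
standardized outcome at each window's last sample.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RecurrentRegressor"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class RecurrentRegressor:
    """Sequence-to-one regressor with an LSTM or GRU cell."""

    def __init__(self, n_features: int, cell: str = "lstm", units: int = 50,
                 learning_rate: float = 0.01, batch_size: int = 128,
                 dropout: float = 0.1, epochs: int = 200, patience: int = 20,
                 noise_sd: float = 0.0, seed: int = 0):
        if cell not in ("lstm", "gru"):
            raise ValueError("cell must be 'lstm' or 'gru'")
        self.cell = cell
        self.nf = n_features
        self.units = units
        self.lr = learning_rate
        self.batch_size = batch_size
        self.dropout = dropout
        self.epochs = epochs
        self.patience = patience
        self.noise_sd = noise_sd
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self._init_params()
        self.history_: list = []

    # ---- parameters ------------------------------------------------
    def _glorot(self, shape):
        lim = np.sqrt(6.0 / sum(shape))
        return self.rng.uniform(-lim, lim, size=shape)

    def _init_params(self):
        H, F = self.units, self.nf
        ngates = 4 if self.cell == "lstm" else 3
        self.Wx = self._glorot((F, ngates * H))
        self.Wh = self._glorot((H, ngates * H))
        self.b = np.zeros(ngates * H)
        if self.cell == "lstm":
            self.b[H:2 * H] = 1.0  # forget-gate bias
        self.Wy = self._glorot((H, 1))[:, 0]
        self.by = 0.0

    @property
    def _params(self):
        return [self.Wx, self.Wh, self.b, self.Wy]

    # ---- forward ---------------------------------------------------
    def _forward(self, X, cache: bool):
        B, T, _ = X.shape
        H = self.units
        h = np.zeros((B, H))
        caches = []
        if self.cell == "lstm":
            c = np.zeros((B, H))
            for t in range(T):
                z = X[:, t] @ self.Wx + h @ self.Wh + self.b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_prev = c
                c = f * c_prev + i * g
                h_prev = h
                h = o * np.tanh(c)
                if cache:
                    caches.append((i, f, g, o, c_prev, c, h_prev))
            return h, c, caches
        # GRU
        for t in range(T):
            xz = X[:, t] @ self.Wx
            hz = h @ self.Wh
            u = _sigmoid(xz[:, :H] + hz[:, :H] + self.b[:H])        # update
            r = _sigmoid(xz[:, H:2 * H] + hz[:, H:2 * H] + self.b[H:2 * H])
            n = np.tanh(xz[:, 2 * H:] + r * hz[:, 2 * H:] + self.b[2 * H:])
            h_prev = h
            h = (1 - u) * n + u * h_prev
            if cache:
                caches.append((u, r, n, h_prev, hz[:, 2 * H:]))
        return h, None, caches

    def _readout(self, h, train: bool):
        if train and self.dropout > 0:
            mask = (self.rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
            h = h * mask
        else:
            mask = None
        return h @ self.Wy + self.by, mask, h

    # ---- backward --------------------------------------------------
    def _backward(self, X, dy, caches, h_drop, mask):
        B, T, _ = X.shape
        H = self.units
        dWy = h_drop.T @ dy
        dby = float(dy.sum())
        dh = np.outer(dy, self.Wy)
        if mask is not None:
            dh = dh * mask
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        if self.cell == "lstm":
            dc = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i, f, g, o, c_prev, c, h_prev = caches[t]
                tc = np.tanh(c)
                do = dh * tc
                dc = dc + dh * o * (1 - tc * tc)
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dz = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f),
                     dg * (1 - g * g), do * o * (1 - o)], axis=1)
                dWx += X[:, t].T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                dh = dz @ self.Wh.T
                dc = dc * f
        else:
            for t in range(T - 1, -1, -1):
                u, r, n, h_prev, hz_n = caches[t]
                du = dh * (h_prev - n)
                dn = dh * (1 - u)
                dh_next = dh * u
                dzn = dn * (1 - n * n)
                dr = dzn * hz_n
                dzu = du * u * (1 - u)
                dzr = dr * r * (1 - r)
                dz = np.concatenate([dzu, dzr, dzn], axis=1)
                dWx += X[:, t].T @ dz
                db += dz.sum(axis=0)
                # hidden-to-hidden path: n gate sees r * (h Wh_n)
                dhz = np.concatenate([dzu, dzr, dzn * r], axis=1)
                dWh += h_prev.T @ dhz
                dh = dh_next + dhz @ self.Wh.T
        return [dWx, dWh, db, dWy], dby

    # ---- training --------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None, verbose: bool = False):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        opt = _Adam(self._params, self.lr)
        n = len(X)
        best_metric = np.inf
        best = None
        bad = 0
        for epoch in range(self.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                Xb = X[idx]
                if self.noise_sd > 0:
                    Xb = Xb + self.rng.normal(0.0, self.noise_sd, size=Xb.shape)
                h, _, caches = self._forward(Xb, cache=True)
                yhat, mask, h_drop = self._readout(h, train=True)
                dy = 2.0 * (yhat - y[idx]) / len(idx)
                grads, dby = self._backward(Xb, dy, caches, h_drop, mask)
                for g in grads:
                    np.clip(g, -5.0, 5.0, out=g)
                opt.step(self._params, grads)
                self.by -= self.lr * dby
            if X_val is not None and len(X_val):
                metric = float(np.mean(np.abs(self.predict(X_val) - y_val)))
            else:
                metric = float(np.mean(np.abs(self.predict(X) - y)))
            self.history_.append(metric)
            if metric < best_metric - 1e-6:
                best_metric = metric
                best = [p.copy() for p in self._params] + [self.by]
                bad = 0
            else:
                bad += 1
                if bad >= self.patience:
                    break
            if verbose:
                print(f"epoch {epoch:3d}  val MAE {metric:.4f}")
        if best is not None:
            self.Wx, self.Wh, self.b, self.Wy = best[:4]
            self.by = best[4]
        return self

    def predict(self, X, chunk: int = 4096):
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        for start in range(0, len(X), chunk):
            h, _, _ = self._forward(X[start:start + chunk], cache=False)
            out[start:start + chunk] = h @ self.Wy + self.by
        return out

    # ---- persistence -----------------------------------------------
    def get_weights(self) -> dict:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b,
                "Wy": self.Wy, "by": np.array([self.by])}

    def set_weights(self, weights: dict) -> None:
        self.Wx = np.asarray(weights["Wx"], dtype=float)
        self.Wh = np.asarray(weights["Wh"], dtype=float)
        self.b = np.asarray(weights["b"], dtype=float)
        self.Wy = np.asarray(weights["Wy"], dtype=float)
        self.by = float(np.asarray(weights["by"]).ravel()[0])
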