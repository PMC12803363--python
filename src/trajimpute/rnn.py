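"""Minimal recurrent regressor in numpy.

A single tanh recurrent layer consumes the ordered biomarker window as a
short sequence; static covariates enter at the linear readout.  Trained
with Adam on mean squared error, early-stopped on a held-out validation
split.  Sequences here are length 2-3, so a simple recurrent cell is
adequate and keeps the package free of deep-learning runtime dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RNNConfig:
    hidden_size: int = 32
    learning_rate: float = 0.01
    max_epochs: int = 300
    batch_size: int = 64
    patience: int = 25
    validation_fraction: float = 0.1
    l2: float = 1e-5


class RecurrentRegressor:
    """Elman-style recurrent net: h_t = tanh(wx*x_t + Wh h_{t-1} + b)."""

    def __init__(self, config: RNNConfig | None = None, seed: int = 0) -> None:
        self.config = config or RNNConfig()
        self.seed = seed
        self._params: dict[str, np.ndarray] | None = None
        self._scale: dict[str, np.ndarray] = {}

    # ---- forward / backward -------------------------------------------------

    def _forward(self, seq: np.ndarray, static: np.ndarray, p: dict) -> tuple:
        B, T = seq.shape
        H = p["wx"].size
        hs = np.zeros((T + 1, B, H))
        for t in range(T):
            a = np.outer(seq[:, t], p["wx"]) + hs[t] @ p["Wh"] + p["b"]
            hs[t + 1] = np.tanh(a)
        y = hs[T] @ p["v"] + static @ p["u"] + p["c"]
        return y, hs

    def _backward(
        self, seq: np.ndarray, static: np.ndarray, target: np.ndarray, p: dict
    ) -> tuple[float, dict]:
        B, T = seq.shape
        y, hs = self._forward(seq, static, p)
        err = y - target
        loss = float(np.mean(err**2))
        dy = 2.0 * err / B
        g = {
            "v": hs[T].T @ dy,
            "u": static.T @ dy,
            "c": np.array(dy.sum()),
            "wx": np.zeros_like(p["wx"]),
            "Wh": np.zeros_like(p["Wh"]),
            "b": np.zeros_like(p["b"]),
        }
        dh = np.outer(dy, p["v"])
        for t in range(T, 0, -1):
            da = dh * (1.0 - hs[t] ** 2)
            g["wx"] += seq[:, t - 1] @ da
            g["Wh"] += hs[t - 1].T @ da
            g["b"] += da.sum(axis=0)
            dh = da @ p["Wh"].T
        if self.config.l2 > 0:
            for k in ("wx", "Wh", "v", "u"):
                g[k] += 2 * self.config.l2 * p[k]
        return loss, g

    # ---- training -----------------------------------------------------------

    def fit(self, seq: np.ndarray, static: np.ndarray, target: np.ndarray) -> "RecurrentRegressor":
        cfg = self.config
        rng = np.random.default_rng(self.seed)
        seq = np.asarray(seq, float)
        static = np.asarray(static, float)
        target = np.asarray(target, float)
        n, T = seq.shape

        # standardize inputs and target with training statistics
        s_mu, s_sd = seq.mean(), max(seq.std(), 1e-8)
        st_mu = static.mean(axis=0)
        st_sd = np.maximum(static.std(axis=0), 1e-8)
        t_mu, t_sd = target.mean(), max(target.std(), 1e-8)
        self._scale = {"s_mu": s_mu, "s_sd": s_sd, "st_mu": st_mu, "st_sd": st_sd,
                       "t_mu": t_mu, "t_sd": t_sd}
        seq = (seq - s_mu) / s_sd
        static = (static - st_mu) / st_sd
        target = (target - t_mu) / t_sd

        H, K = cfg.hidden_size, static.shape[1]
        p = {
            "wx": rng.normal(0, 0.5, H),
            "Wh": rng.normal(0, 1.0 / np.sqrt(H), (H, H)),
            "b": np.zeros(H),
            "v": rng.normal(0, 1.0 / np.sqrt(H), H),
            "u": rng.normal(0, 0.1, K),
            "c": np.array(0.0),
        }

        n_val = max(1, int(round(cfg.validation_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if tr_idx.size == 0:
            tr_idx, val_idx = perm, perm[:0]

        m_adam = {k: np.zeros_like(v) for k, v in p.items()}
        v_adam = {k: np.zeros_like(v) for k, v in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_p = {k: v.copy() for k, v in p.items()}
        stale = 0

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(tr_idx)
            for lo in range(0, order.size, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                _, g = self._backward(seq[idx], static[idx], target[idx], p)
                step += 1
                for k in p:
                    m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * g[k]
                    v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * g[k] ** 2
                    m_hat = m_adam[k] / (1 - beta1**step)
                    v_hat = v_adam[k] / (1 - beta2**step)
                    p[k] = p[k] - cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            if val_idx.size:
                yv, _ = self._forward(seq[val_idx], static[val_idx], p)
                val = float(np.mean((yv - target[val_idx]) ** 2))
            else:
                yt, _ = self._forward(seq[tr_idx], static[tr_idx], p)
                val = float(np.mean((yt - target[tr_idx]) ** 2))
            if val < best_val - 1e-7:
                best_val = val
                best_p = {k: v.copy() for k, v in p.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        self._params = best_p
        return self

    def predict(self, seq: np.ndarray, static: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("model is not fitted")
        sc = self._scale
        seq = (np.asarray(seq, float) - sc["s_mu"]) / sc["s_sd"]
        static = (np.asarray(static, float) - sc["st_mu"]) / sc["st_sd"]
        y, _ = self._forward(seq, static, self._params)
        return y * sc["t_sd"] + sc["t_mu"]
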