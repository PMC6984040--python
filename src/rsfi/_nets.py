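"""Small fully-connected VAE and row/column-convolution CNN in numpy.

Both networks are deliberately tiny (tens of thousands of parameters) --
they classify or model 528-dimensional feature vectors and 33x33 feature
matrices from cohorts of under a hundred subjects, where anything larger
would only overfit. Gradients are hand-derived; optimization is Adam.
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _relu(x):
    return np.maximum(x, 0.0)


def _he(rng, *shape):
    fan_in = shape[-1] if len(shape) == 2 else int(np.prod(shape[1:]))
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class VAE:
    """Variational autoencoder: two fully-connected layers on each side,
    a 2-D Gaussian latent, MSE reconstruction loss + KL latent loss."""

    def __init__(self, input_dim: int, hidden: tuple[int, int] = (256, 64),
                 latent_dim: int = 2, lr: float = 1e-3, seed: int = 0):
        self.input_dim = input_dim
        self.hidden = hidden
        self.latent_dim = latent_dim
        self.lr = lr
        self.rng = np.random.default_rng(seed)
        h1, h2 = hidden
        d, L, r = input_dim, latent_dim, self.rng
        self.p = {
            "W1": _he(r, h1, d), "b1": np.zeros(h1),
            "W2": _he(r, h2, h1), "b2": np.zeros(h2),
            "Wm": _he(r, L, h2) * 0.1, "bm": np.zeros(L),
            "Wv": _he(r, L, h2) * 0.1, "bv": np.zeros(L),
            "W3": _he(r, h2, L), "b3": np.zeros(h2),
            "W4": _he(r, h1, h2), "b4": np.zeros(h1),
            "W5": _he(r, d, h1) * 0.1, "b5": np.zeros(d),
        }
        self.opt = Adam(self.p, lr=lr)

    # forward pieces -----------------------------------------------------
    def _encode(self, X):
        p = self.p
        a1 = X @ p["W1"].T + p["b1"]; h1 = _relu(a1)
        a2 = h1 @ p["W2"].T + p["b2"]; h2 = _relu(a2)
        mu = h2 @ p["Wm"].T + p["bm"]
        logvar = np.clip(h2 @ p["Wv"].T + p["bv"], -10.0, 10.0)
        return a1, h1, a2, h2, mu, logvar

    def _decode(self, Z):
        p = self.p
        a3 = Z @ p["W3"].T + p["b3"]; h3 = _relu(a3)
        a4 = h3 @ p["W4"].T + p["b4"]; h4 = _relu(a4)
        Xhat = h4 @ p["W5"].T + p["b5"]
        return a3, h3, a4, h4, Xhat

    def _step(self, X: np.ndarray) -> float:
        p = self.p
        B = X.shape[0]
        a1, h1, a2, h2, mu, logvar = self._encode(X)
        eps = self.rng.standard_normal(mu.shape)
        sigma = np.exp(0.5 * logvar)
        Z = mu + sigma * eps
        a3, h3, a4, h4, Xhat = self._decode(Z)

        diff = Xhat - X
        recon = np.sum(diff**2) / B
        kl = -0.5 * np.sum(1 + logvar - mu**2 - np.exp(logvar)) / B
        loss = recon + kl
        if not np.isfinite(loss):
            raise FloatingPointError("VAE training diverged (non-finite loss)")

        g = {}
        dXhat = 2.0 * diff / B
        g["W5"] = dXhat.T @ h4; g["b5"] = dXhat.sum(0)
        dh4 = (dXhat @ p["W5"]) * (a4 > 0)
        g["W4"] = dh4.T @ h3; g["b4"] = dh4.sum(0)
        dh3 = (dh4 @ p["W4"]) * (a3 > 0)
        g["W3"] = dh3.T @ Z; g["b3"] = dh3.sum(0)
        dZ = dh3 @ p["W3"]
        dmu = dZ + mu / B
        dlogvar = dZ * 0.5 * sigma * eps + 0.5 * (np.exp(logvar) - 1.0) / B
        dh2 = dmu @ p["Wm"] + dlogvar @ p["Wv"]
        g["Wm"] = dmu.T @ h2; g["bm"] = dmu.sum(0)
        g["Wv"] = dlogvar.T @ h2; g["bv"] = dlogvar.sum(0)
        dh2 *= (a2 > 0)
        g["W2"] = dh2.T @ h1; g["b2"] = dh2.sum(0)
        dh1 = (dh2 @ p["W2"]) * (a1 > 0)
        g["W1"] = dh1.T @ X; g["b1"] = dh1.sum(0)

        self.opt.step(g)
        return float(loss)

    def fit(self, X: np.ndarray, epochs: int = 200, batch_size: int = 32,
            patience: int = 30) -> list[float]:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        history, best, since = [], np.inf, 0
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                batch = X[order[start : start + batch_size]]
                losses.append(self._step(batch))
            ep = float(np.mean(losses))
            history.append(ep)
            if ep < best - 1e-6:
                best, since = ep, 0
            else:
                since += 1
                if since >= patience:
                    break
        return history

    def sample(self, n: int) -> np.ndarray:
        Z = self.rng.standard_normal((n, self.latent_dim))
        return self._decode(Z)[-1]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        *_, mu, _ = self._encode(np.asarray(X, dtype=float))
        return self._decode(mu)[-1]


class RowColumnCNN:
    """CNN over square feature matrices: a 1xN convolution stage (one shared
    filter row applied to every matrix row), an Nx1 stage collapsing rows,
    then a dense layer with dropout and a 2-way softmax."""

    def __init__(self, n: int, filters1: int = 16, filters2: int = 32,
                 dense: int = 64, dropout: float = 0.5, lr: float = 1e-3,
                 seed: int = 0):
        self.n = n
        self.dropout = dropout
        self.rng = np.random.default_rng(seed)
        r = self.rng
        self.p = {
            "W1": _he(r, filters1, n), "b1": np.zeros(filters1),
            "W2": _he(r, filters2, n, filters1), "b2": np.zeros(filters2),
            "W3": _he(r, dense, filters2), "b3": np.zeros(dense),
            "W4": _he(r, 2, dense) * 0.1, "b4": np.zeros(2),
        }
        self.opt = Adam(self.p, lr=lr)

    def _forward(self, X, train: bool):
        p = self.p
        a1 = np.einsum("bij,fj->bif", X, p["W1"]) + p["b1"]
        h1 = _relu(a1)                                   # (B, n, F1)
        a2 = np.einsum("bif,gif->bg", h1, p["W2"]) + p["b2"]
        h2 = _relu(a2)                                   # (B, F2)
        a3 = h2 @ p["W3"].T + p["b3"]
        h3 = _relu(a3)                                   # (B, D)
        if train and self.dropout > 0:
            mask = (self.rng.random(h3.shape) >= self.dropout) / (1 - self.dropout)
            h3 = h3 * mask
        else:
            mask = None
        logits = h3 @ p["W4"].T + p["b4"]
        return a1, h1, a2, h2, a3, h3, mask, logits

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _step(self, X, y) -> float:
        p = self.p
        B = X.shape[0]
        a1, h1, a2, h2, a3, h3, mask, logits = self._forward(X, train=True)
        prob = self._softmax(logits)
        loss = -np.log(prob[np.arange(B), y] + 1e-12).mean()
        if not np.isfinite(loss):
            raise FloatingPointError("CNN training diverged (non-finite loss)")
        dlogits = prob.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        g = {}
        g["W4"] = dlogits.T @ h3; g["b4"] = dlogits.sum(0)
        dh3 = dlogits @ p["W4"]
        if mask is not None:
            dh3 = dh3 * mask
        dh3 = dh3 * (a3 > 0)
        g["W3"] = dh3.T @ h2; g["b3"] = dh3.sum(0)
        dh2 = (dh3 @ p["W3"]) * (a2 > 0)
        g["W2"] = np.einsum("bg,bif->gif", dh2, h1); g["b2"] = dh2.sum(0)
        dh1 = np.einsum("bg,gif->bif", dh2, p["W2"]) * (a1 > 0)
        g["W1"] = np.einsum("bif,bij->fj", dh1, X); g["b1"] = dh1.sum((0, 1))
        self.opt.step(g)
        return float(loss)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 60,
            batch_size: int = 16) -> list[float]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = X.shape[0]
        history = []
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                losses.append(self._step(X[idx], y[idx]))
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self._forward(np.asarray(X, dtype=float), train=False)[-1]
        return self._softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
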