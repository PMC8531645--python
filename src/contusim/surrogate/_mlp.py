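"""Minimal fully-connected regressor trained with full-batch Adam.

Hidden layers use Softplus, ln(1 + e^x); the output layer is a rectifier,
max(0, x), so predictions are non-negative by construction. The loss is the
Huber function of the residuals,

    L(e) = e^2 / 2           if |e| <= d
           d^2 / 2 + d(|e| - d)   otherwise,

averaged over samples and outputs, plus an L2 penalty on the weights.
Training is deterministic under a fixed seed (pure numpy, full batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["huber_loss", "MLP", "FitTrace"]


def huber_loss(residuals, d: float = 0.1) -> float:
    """Mean Huber loss of a residual array; quadratic inside |e| <= d,
    linear outside, continuous and once-differentiable at the joint."""
    if d <= 0:
        raise ValueError("Huber threshold d must be positive")
    e = np.abs(np.asarray(residuals, dtype=float))
    quad = 0.5 * e**2
    lin = 0.5 * d**2 + d * (e - d)
    return float(np.mean(np.where(e <= d, quad, lin)))


def _huber_grad(residuals: np.ndarray, d: float) -> np.ndarray:
    """d/d(pred) of the elementwise Huber loss (residual = obs - pred)."""
    return -np.clip(residuals, -d, d)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class FitTrace:
    """Per-epoch training diagnostics."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    final_lr: float = np.nan


class MLP:
    """Softplus MLP with rectified output, Huber loss and Adam.

    Operates on already-normalized inputs/outputs; normalization is owned
    by the ensemble layer.
    """

    def __init__(self, layers: tuple[int, ...], seed: int = 0):
        if len(layers) < 2:
            raise ValueError("need at least input and output layer widths")
        self.layers = tuple(int(w) for w in layers)
        rng = np.random.default_rng(seed)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(self.layers[:-1], self.layers[1:])
        ]
        self.b = [np.zeros(fan_out) for fan_out in self.layers[1:]]
        # start the rectified output layer alive (targets live in [0, 1])
        self.b[-1][:] = 0.5

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray):
        """Returns (prediction, per-layer pre-activations, activations)."""
        zs, acts = [], [X]
        a = X
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            a = np.maximum(z, 0.0) if i == n_layers - 1 else _softplus(z)
            acts.append(a)
        return a, zs, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[0]

    def _gradients(self, X: np.ndarray, Y: np.ndarray, d: float, l2: float):
        pred, zs, acts = self._forward(X)
        n_elem = Y.size
        delta = _huber_grad(Y - pred, d) / n_elem
        delta = delta * (zs[-1] > 0)  # rectifier gate at the output
        gW, gb = [None] * len(self.W), [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta + l2 * self.W[i]
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * _sigmoid(zs[i - 1])
        return pred, gW, gb

    def _loss(self, X: np.ndarray, Y: np.ndarray, d: float, l2: float) -> float:
        pred = self.predict(X)
        penalty = 0.5 * l2 * sum(float(np.sum(W**2)) for W in self.W)
        return huber_loss(Y - pred, d) + penalty

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        X_val: np.ndarray,
        Y_val: np.ndarray,
        huber_d: float = 0.1,
        learning_rate: float = 1e-3,
        l2: float = 1e-4,
        max_epochs: int = 5000,
        patience: int = 500,
        plateau_patience: int = 200,
        plateau_factor: float = 0.5,
        lr_floor: float = 1e-5,
    ) -> FitTrace:
        """Full-batch Adam with reduce-on-plateau and early stopping.

        The learning rate halves when the training loss has not improved
        for ``plateau_patience`` epochs (floor ``lr_floor``); training stops
        once the validation Huber loss has not improved for ``patience``
        epochs, and the best-validation parameters are restored.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if len(X) == 0 or len(X_val) == 0:
            raise ValueError("training and validation sets must be non-empty")

        mW = [np.zeros_like(W) for W in self.W]
        vW = [np.zeros_like(W) for W in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = learning_rate
        trace = FitTrace()
        best_W = [W.copy() for W in self.W]
        best_b = [b.copy() for b in self.b]
        best_train = np.inf
        since_train_improve = 0
        since_val_improve = 0

        for epoch in range(max_epochs):
            _, gW, gb = self._gradients(X, Y, huber_d, l2)
            t = epoch + 1
            for i in range(len(self.W)):
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                mW_hat = mW[i] / (1 - beta1**t)
                vW_hat = vW[i] / (1 - beta2**t)
                mb_hat = mb[i] / (1 - beta1**t)
                vb_hat = vb[i] / (1 - beta2**t)
                self.W[i] -= lr * mW_hat / (np.sqrt(vW_hat) + eps)
                self.b[i] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)

            train_loss = self._loss(X, Y, huber_d, l2)
            val_loss = huber_loss(Y_val - self.predict(X_val), huber_d)
            trace.train_loss.append(train_loss)
            trace.val_loss.append(val_loss)

            if train_loss < best_train * (1 - 1e-4):
                best_train = train_loss
                since_train_improve = 0
            else:
                since_train_improve += 1
                if since_train_improve >= plateau_patience and lr > lr_floor:
                    lr = max(lr * plateau_factor, lr_floor)
                    since_train_improve = 0

            if val_loss < trace.best_val_loss:
                trace.best_val_loss = val_loss
                trace.best_epoch = epoch
                best_W = [W.copy() for W in self.W]
                best_b = [b.copy() for b in self.b]
                since_val_improve = 0
            else:
                since_val_improve += 1
                if since_val_improve >= patience:
                    break

        self.W, self.b = best_W, best_b
        trace.final_lr = lr
        return trace
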