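"""Seeded dense neural network for binary image quality classification.

Architecture: three fully-connected hidden layers of 150 rectifier
units, dropout 0.24 after the first two hidden layers, and a single
logistic output trained with binary cross-entropy, L2 weight decay and
the Adam optimizer (initial learning rate 1.5e-3, batch size 16). Two
callbacks watch the validation loss: a plateau scheduler multiplying the
learning rate by 0.18 when it fails to improve by 0.01 for 12
consecutive epochs, and an early stop after 24, restoring the best
weights.

A two-unit softmax head trained with categorical cross-entropy is
available behind ``output="softmax"`` for fidelity experiments; the
probability of the positive class is reported either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NNConfig", "DenseNetwork", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class NNConfig:
    """Training schedule and architecture of the quality-control net."""

    hidden_layers: int = 3
    units_per_layer: int = 150
    dropout_p: float = 0.24  # after hidden layers 1 and 2
    l2_coefficient: float = 1e-4
    initial_lr: float = 1.5e-3
    lr_reduction_factor: float = 0.18
    lr_min_delta: float = 0.01
    lr_patience: int = 12
    stop_patience: int = 24
    max_epochs: int = 1000
    batch_size: int = 16
    output: str = "sigmoid"  # or "softmax"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        for name in ("lr_patience", "stop_patience", "max_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.output not in ("sigmoid", "softmax"):
            raise ValueError("output must be 'sigmoid' or 'softmax'")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class DenseNetwork:
    """A small seeded multilayer perceptron with Adam and dropout."""

    def __init__(self, n_features: int, config: NNConfig | None = None):
        self.config = config or NNConfig()
        self.n_features = n_features
        rng = np.random.default_rng(self.config.rng_seed)
        n_out = 1 if self.config.output == "sigmoid" else 2
        sizes = [n_features] + [self.config.units_per_layer] * self.config.hidden_layers + [n_out]
        # He initialization, fan-in scaled
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes, sizes[1:])
        ]
        self.biases = [np.zeros(fan_out) for fan_out in sizes[1:]]
        self._rng = rng
        self.history: dict[str, list[float]] = {
            "epoch": [], "lr": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        }

    # -- forward ---------------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool = False):
        """Forward pass; returns activations and dropout masks."""
        cfg = self.config
        acts = [x]
        masks: list[np.ndarray | None] = []
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            last = i == len(self.weights) - 1
            if last:
                h = z  # head nonlinearity applied by the loss wrapper
            else:
                h = _relu(z)
                if train and cfg.dropout_p > 0 and i < 2:  # after hidden layers 1 & 2
                    mask = (self._rng.random(h.shape) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            acts.append(h)
        return acts, masks

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each row."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError(f"expected (n, {self.n_features}) input, got {x.shape}")
        logits = self._forward(x, train=False)[0][-1]
        if self.config.output == "sigmoid":
            return _sigmoid(logits[:, 0])
        shifted = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(shifted)
        return (ex[:, 1] / ex.sum(axis=1))

    # -- loss ------------------------------------------------------------

    def _loss_and_output_grad(self, logits: np.ndarray, y: np.ndarray):
        n = y.shape[0]
        if self.config.output == "sigmoid":
            z = logits[:, 0]
            # stable BCE on logits: max(z,0) - z*y + log(1+exp(-|z|))
            loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
            grad = ((_sigmoid(z) - y) / n)[:, None]
        else:
            shifted = logits - logits.max(axis=1, keepdims=True)
            logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
            loss = float(-np.mean(logp[np.arange(n), y.astype(int)]))
            grad = np.exp(logp)
            grad[np.arange(n), y.astype(int)] -= 1.0
            grad /= n
        return loss, grad

    def _evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        logits = self._forward(x, train=False)[0][-1]
        loss, _ = self._loss_and_output_grad(logits, y)
        proba = self.predict_proba(x)
        acc = float(np.mean((proba > 0.5) == (y > 0.5)))
        l2 = self.config.l2_coefficient * sum(float(np.sum(w * w)) for w in self.weights)
        return loss + l2, acc

    # -- training --------------------------------------------------------

    def fit(self, x_train: np.ndarray, y_train: np.ndarray, x_val: np.ndarray, y_val: np.ndarray) -> "DenseNetwork":
        """Mini-batch Adam training with plateau LR reduction + early stop."""
        cfg = self.config
        x_train = np.asarray(x_train, dtype=np.float64)
        y_train = np.asarray(y_train, dtype=np.float64).ravel()
        x_val = np.asarray(x_val, dtype=np.float64)
        y_val = np.asarray(y_val, dtype=np.float64).ravel()

        m = [np.zeros_like(w) for w in self.weights + self.biases]
        v = [np.zeros_like(w) for w in self.weights + self.biases]
        lr = cfg.initial_lr
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_weights = None
        since_improve_lr = 0
        since_improve_stop = 0

        for epoch in range(cfg.max_epochs):
            order = self._rng.permutation(x_train.shape[0])
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, x_train.shape[0], cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x_train[idx], y_train[idx]
                acts, masks = self._forward(xb, train=True)
                loss, delta = self._loss_and_output_grad(acts[-1], yb)
                if not np.isfinite(loss):
                    raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
                epoch_loss += loss
                n_batches += 1
                grads_w, grads_b = [], []
                for layer in range(len(self.weights) - 1, -1, -1):
                    grads_w.append(acts[layer].T @ delta + 2.0 * cfg.l2_coefficient * self.weights[layer])
                    grads_b.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = delta @ self.weights[layer].T
                        delta *= acts[layer] > 0  # relu gate
                        mask = masks[layer - 1]
                        if mask is not None:
                            delta *= mask
                grads = grads_w[::-1] + grads_b[::-1]
                params = self.weights + self.biases
                t += 1
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**t)
                    vhat = v[i] / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)

            train_loss, train_acc = self._evaluate(x_train, y_train)
            val_loss, val_acc = self._evaluate(x_val, y_val)
            if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
                raise TrainingDiverged(f"non-finite evaluation loss at epoch {epoch}")
            self.history["epoch"].append(epoch)
            self.history["lr"].append(lr)
            self.history["train_loss"].append(train_loss)
            self.history["train_acc"].append(train_acc)
            self.history["val_loss"].append(val_loss)
            self.history["val_acc"].append(val_acc)

            if val_loss < best_val - cfg.lr_min_delta:
                since_improve_lr = 0
                since_improve_stop = 0
            else:
                since_improve_lr += 1
                since_improve_stop += 1
            if val_loss < best_val:
                best_val = val_loss
                best_weights = ([w.copy() for w in self.weights], [b.copy() for b in self.biases])
            if since_improve_stop >= cfg.stop_patience:
                break
            if since_improve_lr >= cfg.lr_patience:
                lr *= cfg.lr_reduction_factor
                since_improve_lr = 0

        if best_weights is not None:
            self.weights, self.biases = best_weights
        return self
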