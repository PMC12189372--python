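"""Embedding-free multi-kernel 1D convolutional classifier with attention.

The classifier treats each encoded protein as a one-dimensional feature
map of length n with a single channel.  Parallel 1D convolutions with
kernel sizes 3, 4, 5 (64 filters each, valid padding) extract local
patterns across adjacent feature dimensions; global max pooling reduces
each branch to one 64-dim vector.  The three pooled vectors are fused —
by scaled dot-product self-attention over the branch set (query = key =
value) followed by concatenation, or by plain concatenation — and a dense
head with dropout produces the RBP probability.

A baseline variant keeps the classic text-CNN design: residues are
integer-encoded, passed through a learned embedding table, and convolved
across positions; it exists to quantify what replacing the embedding with
composition features buys.

Everything is implemented directly in NumPy (forward, backward, Adam),
so training is CPU-only and bit-reproducible from one integer seed that
controls weight initialization, minibatch shuffling, and dropout masks.
Convolution feature maps are held in (batch, filter, position) layout and
float32 so pooling reduces over the contiguous axis; pass
``dtype=np.float64`` for high-precision work such as gradient checking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import AMINO_ACIDS, LabeledSequence


class DimensionMismatchError(ValueError):
    """Input width does not match the model's expected feature count."""


@dataclass
class TextCNNConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference configuration: 424 input features,
    kernel sizes 3/4/5 with 64 filters each, attention fusion, one hidden
    dense layer of 64 units with dropout 0.5, Adam at 1e-3, batches of 32,
    at most 50 epochs with early-stopping patience 5.
    """

    input_dim: int = 424
    kernel_sizes: tuple[int, ...] = (3, 4, 5)
    filters_per_kernel: int = 64
    use_attention: bool = True
    dense_units: int = 64
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(self.kernel_sizes)
        if not self.kernel_sizes:
            raise ValueError("at least one kernel size required")
        if any(s >= self.input_dim for s in self.kernel_sizes):
            raise ValueError(
                f"kernel sizes {self.kernel_sizes} must all be < input_dim="
                f"{self.input_dim}"
            )
        if self.filters_per_kernel < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("filters_per_kernel, max_epochs, patience must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy curves plus stopping bookkeeping.

    Training loss/accuracy are running averages over the epoch's
    minibatches (computed in training mode, i.e. with dropout active);
    validation metrics come from a full forward pass in inference mode.
    """

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "epoch": range(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_acc": self.train_acc,
                "val_acc": self.val_acc,
            }
        ).to_csv(path, index=False)


def attend(branches) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product self-attention over a set of branch vectors.

    ``branches`` is (T, d) or (B, T, d); the T vectors act as query, key,
    and value.  Returns (concatenated attended tokens of width T*d,
    attention weights with rows summing to 1).
    """
    T = np.asarray(branches, dtype=float)
    single = T.ndim == 2
    if single:
        T = T[None]
    if T.ndim != 3:
        raise ValueError("branches must be (T, d) or (B, T, d)")
    d = T.shape[-1]
    scores = T @ T.transpose(0, 2, 1) / np.sqrt(d)
    scores -= scores.max(axis=-1, keepdims=True)
    weights = np.exp(scores)
    weights /= weights.sum(axis=-1, keepdims=True)
    out = weights @ T
    fused = out.reshape(out.shape[0], -1)
    if single:
        return fused[0], weights[0]
    return fused, weights


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-7
    p = np.clip(p.astype(np.float64), eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class _AdamNet:
    """Shared parameter store, Adam optimizer, and early-stopped fit loop."""

    config: TextCNNConfig
    params: dict[str, np.ndarray]
    dtype: np.dtype

    def _init_adam(self) -> None:
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._t += 1
        for k, g in grads.items():
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1**self._t)
            vhat = self._v[k] / (1 - b2**self._t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(self.dtype)

    # subclasses implement:
    def _forward(self, X, train=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def _backward(self, cache, dlogits):  # pragma: no cover
        raise NotImplementedError

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_input(X)
        p, _ = self._forward(X, train=False)
        return p.astype(np.float64)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def _check_input(self, X) -> np.ndarray:  # overridden by embedding model
        X = np.asarray(X)
        if X.ndim == 3 and X.shape[-1] == 1:  # accept (B, n, 1) tensors
            X = X[..., 0]
        if X.ndim != 2 or X.shape[1] != self.config.input_dim:
            raise DimensionMismatchError(
                f"expected {self.config.input_dim} features, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return np.ascontiguousarray(X, dtype=self.dtype)

    def fit(self, X_train, y_train, X_val, y_val) -> TrainingHistory:
        """Minibatch Adam training with strict early stopping.

        Training halts after ``patience`` consecutive epochs whose
        validation loss is not strictly lower than the best seen, or at
        ``max_epochs``; the returned model carries the best-epoch weights.
        """
        cfg = self.config
        X_train = self._check_input(X_train)
        X_val = self._check_input(X_val)
        y_train = np.asarray(y_train, dtype=np.float64).ravel()
        y_val = np.asarray(y_val, dtype=np.float64).ravel()
        if len(np.unique(y_train)) < 2:
            raise ValueError("training labels contain a single class")
        rng = np.random.default_rng(cfg.seed)
        history = TrainingHistory()
        best_loss = np.inf
        best_params: dict[str, np.ndarray] | None = None
        bad_epochs = 0
        n = len(y_train)
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            loss_sum = acc_sum = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, yb = X_train[idx], y_train[idx]
                p, cache = self._forward(Xb, train=True, rng=rng)
                eps = 1e-7
                dlogits = ((np.clip(p, eps, 1 - eps) - yb) / len(yb)).astype(self.dtype)
                grads = self._backward(cache, dlogits)
                self._adam_step(grads)
                loss_sum += _bce(p, yb) * len(yb)
                acc_sum += float(np.sum((p >= 0.5) == yb))
            p_va, _ = self._forward(X_val, train=False)
            history.train_loss.append(loss_sum / n)
            history.train_acc.append(acc_sum / n)
            history.val_loss.append(_bce(p_va, y_val))
            history.val_acc.append(float(np.mean((p_va >= 0.5) == y_val)))
            if history.val_loss[-1] < best_loss:
                best_loss = history.val_loss[-1]
                best_params = {k: v.copy() for k, v in self.params.items()}
                history.best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
            history.stopped_epoch = epoch
            if bad_epochs >= cfg.patience:
                break
        if best_params is not None:
            self.params = best_params
            self._init_adam()  # moments refer to restored weights
        self.history_ = history
        return history

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "weights.npz", **self.params)
        cfg = asdict(self.config)
        cfg["kernel_sizes"] = list(self.config.kernel_sizes)
        cfg["model_class"] = type(self).__name__
        if hasattr(self, "vocab_size"):
            cfg["vocab_size"] = self.vocab_size
            cfg["embed_dim"] = self.embed_dim
            cfg["max_len"] = self.max_len
        (out_dir / "config.json").write_text(json.dumps(cfg, indent=2))

    # -- shared attention/dense head ----------------------------------

    def _head_forward(self, tokens: np.ndarray, train: bool, rng):
        """Fuse branch tokens (B, K, F) and run the dense head."""
        cfg = self.config
        B, _, F = tokens.shape
        if cfg.use_attention:
            scores = tokens @ tokens.transpose(0, 2, 1) / np.sqrt(
                np.asarray(F, dtype=self.dtype))
            scores -= scores.max(axis=-1, keepdims=True)
            A = np.exp(scores)
            A /= A.sum(axis=-1, keepdims=True)
            fused = (A @ tokens).reshape(B, -1)
        else:
            A = None
            fused = tokens.reshape(B, -1)
        pre = fused @ self.params["W1"] + self.params["b1"]
        H = np.maximum(pre, 0)
        if train and cfg.dropout_rate > 0:
            mask = ((rng.random(H.shape) >= cfg.dropout_rate) /
                    (1 - cfg.dropout_rate)).astype(self.dtype)
            Hd = H * mask
        else:
            mask = None
            Hd = H
        logits = (Hd @ self.params["W2"] + self.params["b2"]).ravel()
        p = _sigmoid(logits.astype(np.float64))
        return p, (tokens, A, fused, pre, H, mask, Hd)

    def _head_backward(self, head_cache, dlogits, grads) -> np.ndarray:
        """Backprop the head; returns gradient w.r.t. the branch tokens."""
        cfg = self.config
        tokens, A, fused, pre, H, mask, Hd = head_cache
        B, K, F = tokens.shape
        grads["W2"] = Hd.T @ dlogits[:, None]
        grads["b2"] = dlogits.sum(keepdims=True)
        dHd = dlogits[:, None] @ self.params["W2"].T
        dH = dHd * mask if mask is not None else dHd
        dpre = dH * (pre > 0)
        grads["W1"] = fused.T @ dpre
        grads["b1"] = dpre.sum(axis=0)
        dfused = dpre @ self.params["W1"].T
        dout = dfused.reshape(B, K, F)
        if cfg.use_attention:
            dA = dout @ tokens.transpose(0, 2, 1)
            dT = A.transpose(0, 2, 1) @ dout
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dT += (dS + dS.transpose(0, 2, 1)) @ tokens / np.sqrt(
                np.asarray(F, dtype=self.dtype))
        else:
            dT = dout
        return dT


class ImprovedTextCNN(_AdamNet):
    """The embedding-free variant: feature vector in, RBP probability out."""

    def __init__(self, config: TextCNNConfig | None = None, dtype=np.float32):
        self.config = config or TextCNNConfig()
        self.dtype = np.dtype(dtype)
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        F = cfg.filters_per_kernel
        K = len(cfg.kernel_sizes)
        self.params = {}
        for s in cfg.kernel_sizes:
            self.params[f"W_conv{s}"] = rng.normal(
                0, np.sqrt(2.0 / s), size=(s, F)).astype(self.dtype)
            self.params[f"b_conv{s}"] = np.zeros(F, dtype=self.dtype)
        fused = K * F
        self.params["W1"] = rng.normal(
            0, np.sqrt(2.0 / fused), size=(fused, cfg.dense_units)).astype(self.dtype)
        self.params["b1"] = np.zeros(cfg.dense_units, dtype=self.dtype)
        self.params["W2"] = rng.normal(
            0, np.sqrt(2.0 / cfg.dense_units),
            size=(cfg.dense_units, 1)).astype(self.dtype)
        self.params["b2"] = np.zeros(1, dtype=self.dtype)
        self._init_adam()

    def _forward(self, X: np.ndarray, train: bool = False, rng=None):
        cfg = self.config
        B = X.shape[0]
        F = cfg.filters_per_kernel
        tokens = np.empty((B, len(cfg.kernel_sizes), F), dtype=self.dtype)
        branch_cache = []
        for bi, s in enumerate(cfg.kernel_sizes):
            # (B, s, Lw) strided view; feature maps in (B, F, Lw) layout so
            # pooling reduces over the contiguous last axis
            wt = sliding_window_view(X, s, axis=1).transpose(0, 2, 1)
            Z = self.params[f"W_conv{s}"].T @ wt + self.params[f"b_conv{s}"][:, None]
            R = np.maximum(Z, 0)
            tokens[:, bi, :] = R.max(axis=2)
            arg = R.argmax(axis=2) if train else None
            branch_cache.append((wt, Z, arg))
        p, head_cache = self._head_forward(tokens, train, rng)
        return p, (branch_cache, head_cache)

    def _backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        branch_cache, head_cache = cache
        grads: dict[str, np.ndarray] = {}
        dT = self._head_backward(head_cache, dlogits, grads)
        for bi, s in enumerate(self.config.kernel_sizes):
            wt, Z, arg = branch_cache[bi]
            dR = np.zeros_like(Z)
            np.put_along_axis(dR, arg[:, :, None], dT[:, bi, :][:, :, None], axis=2)
            dZ = dR * (Z > 0)
            grads[f"W_conv{s}"] = (dZ @ wt.transpose(0, 2, 1)).sum(axis=0).T
            grads[f"b_conv{s}"] = dZ.sum(axis=(0, 2))
        return grads


def encode_residue_indices(
    seqs: Sequence[LabeledSequence], max_len: int
) -> np.ndarray:
    """Integer-encode residues (1..20, canonical order) padded/truncated
    to ``max_len``; 0 is the padding token."""
    index = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
    out = np.zeros((len(seqs), max_len), dtype=np.int64)
    for i, s in enumerate(seqs):
        res = s.residues[:max_len]
        out[i, : len(res)] = [index[c] for c in res]
    return out


class OriginalTextCNN(_AdamNet):
    """Classic text-CNN baseline: embedding over integer-encoded residues.

    Same convolution / pooling / attention / dense stack as the
    embedding-free model, but the input is a padded residue index sequence
    passed through a learned embedding table (vocabulary = 20 residues +
    padding token).
    """

    def __init__(
        self,
        vocab_size: int = 21,
        embed_dim: int = 32,
        max_len: int = 1000,
        config: TextCNNConfig | None = None,
        dtype=np.float32,
    ):
        self.config = config or TextCNNConfig(input_dim=max_len)
        self.dtype = np.dtype(dtype)
        cfg = self.config
        if max_len < max(cfg.kernel_sizes):
            raise ValueError("max_len must be >= the largest kernel size")
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.max_len = max_len
        rng = np.random.default_rng(cfg.seed)
        F = cfg.filters_per_kernel
        self.params = {
            "Emb": rng.normal(0, 0.1, size=(vocab_size, embed_dim)).astype(self.dtype)
        }
        for s in cfg.kernel_sizes:
            fan_in = s * embed_dim
            self.params[f"W_conv{s}"] = rng.normal(
                0, np.sqrt(2.0 / fan_in), size=(fan_in, F)).astype(self.dtype)
            self.params[f"b_conv{s}"] = np.zeros(F, dtype=self.dtype)
        fused = len(cfg.kernel_sizes) * F
        self.params["W1"] = rng.normal(
            0, np.sqrt(2.0 / fused), size=(fused, cfg.dense_units)).astype(self.dtype)
        self.params["b1"] = np.zeros(cfg.dense_units, dtype=self.dtype)
        self.params["W2"] = rng.normal(
            0, np.sqrt(2.0 / cfg.dense_units),
            size=(cfg.dense_units, 1)).astype(self.dtype)
        self.params["b2"] = np.zeros(1, dtype=self.dtype)
        self._init_adam()

    def _check_input(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.max_len:
            raise DimensionMismatchError(
                f"expected integer sequences of length {self.max_len}, got "
                f"{X.shape}"
            )
        return X.astype(np.int64)

    def _forward(self, X: np.ndarray, train: bool = False, rng=None):
        cfg = self.config
        B = X.shape[0]
        F = cfg.filters_per_kernel
        D = self.embed_dim
        E = self.params["Emb"][X]  # (B, L, D)
        tokens = np.empty((B, len(cfg.kernel_sizes), F), dtype=self.dtype)
        branch_cache = []
        for bi, s in enumerate(cfg.kernel_sizes):
            win = sliding_window_view(E, s, axis=1)  # (B, Lw, D, s)
            # (B, s*D, Lw) with kernel rows ordered (offset j, channel d)
            wt = np.ascontiguousarray(win.transpose(0, 3, 2, 1)).reshape(
                B, s * D, -1)
            Z = self.params[f"W_conv{s}"].T @ wt + self.params[f"b_conv{s}"][:, None]
            R = np.maximum(Z, 0)
            tokens[:, bi, :] = R.max(axis=2)
            arg = R.argmax(axis=2) if train else None
            branch_cache.append((wt, Z, arg))
        p, head_cache = self._head_forward(tokens, train, rng)
        return p, (X, branch_cache, head_cache)

    def _backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        X, branch_cache, head_cache = cache
        B = X.shape[0]
        D = self.embed_dim
        grads: dict[str, np.ndarray] = {}
        dT = self._head_backward(head_cache, dlogits, grads)
        dEmb = np.zeros_like(self.params["Emb"])
        for bi, s in enumerate(self.config.kernel_sizes):
            wt, Z, arg = branch_cache[bi]
            dR = np.zeros_like(Z)
            np.put_along_axis(dR, arg[:, :, None], dT[:, bi, :][:, :, None], axis=2)
            dZ = dR * (Z > 0)
            grads[f"W_conv{s}"] = (dZ @ wt.transpose(0, 2, 1)).sum(axis=0).T
            grads[f"b_conv{s}"] = dZ.sum(axis=(0, 2))
            dwt = np.matmul(self.params[f"W_conv{s}"], dZ)  # (B, s*D, Lw)
            dwt = dwt.reshape(B, s, D, -1)
            Lw = dwt.shape[-1]
            dE = np.zeros((B, self.max_len, D), dtype=self.dtype)
            for j in range(s):
                dE[:, j : j + Lw, :] += dwt[:, j, :, :].transpose(0, 2, 1)
            np.add.at(dEmb, X, dE)
        dEmb[0] = 0  # padding token stays fixed
        grads["Emb"] = dEmb
        return grads


def build_improved_textcnn(config: TextCNNConfig | None = None) -> ImprovedTextCNN:
    """Construct the embedding-free model from a config."""
    return ImprovedTextCNN(config)


def build_original_textcnn(
    vocab_size: int = 21,
    embed_dim: int = 32,
    max_len: int = 1000,
    config: TextCNNConfig | None = None,
) -> OriginalTextCNN:
    """Construct the embedding-based baseline model."""
    return OriginalTextCNN(vocab_size, embed_dim, max_len, config)


def load_model(out_dir: str | Path):
    """Load a saved model (weights.npz + config.json)."""
    out_dir = Path(out_dir)
    cfg = json.loads((out_dir / "config.json").read_text())
    cls_name = cfg.pop("model_class")
    vocab = cfg.pop("vocab_size", None)
    embed = cfg.pop("embed_dim", None)
    max_len = cfg.pop("max_len", None)
    cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
    config = TextCNNConfig(**cfg)
    if cls_name == "ImprovedTextCNN":
        model: _AdamNet = ImprovedTextCNN(config)
    else:
        model = OriginalTextCNN(vocab, embed, max_len, config)
    with np.load(out_dir / "weights.npz") as data:
        model.params = {k: data[k].astype(model.dtype) for k in data.files}
    model._init_adam()
    return model
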