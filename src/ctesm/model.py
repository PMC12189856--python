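"""The convolutional transformer enhanced sequential model (CTESM).

The classifier maps one channels x features EEG instance to class
probabilities through three stages:

1. **CNN block** — two 1-D convolution + ReLU stages along the electrode
   axis (the features act as input channels), max pooling, then batch
   normalization. The pooled electrode axis becomes the sequence axis T and
   the filter axis the model dimension D, i.e. the feature maps are
   reshaped into sequence format (T, D).
2. **Transformer block** — multi-head scaled dot-product self-attention
   with residual connection and (non-affine) layer normalization, then a
   two-layer position-wise feed-forward network (ReLU affine D→ff_dim,
   affine ff_dim→D) with a second residual + normalization. Dropout after
   the block is the model's explicit regularizer.
3. **LSTM head** — an LSTM consumes the T-step sequence; its final hidden
   state passes through a dense layer with softmax.

Training uses Adam on categorical cross-entropy, 50 epochs and batch size
32 by default. Input features are standardized per feature column with
statistics fit on the training partition only. Two ablations mirror the
architecture study: ``use_lstm=False`` replaces the LSTM with mean pooling
over the sequence (the pooled vector feeds the dense head directly), and
``use_dropout=False`` switches off the dropout regularizer (batch
normalization stays, being part of the CNN block proper).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .augment import AugmentedDataset
from .features import FeatureInstance
from . import nn

__all__ = [
    "CTESM",
    "ModelConfig",
    "TrainingProtocol",
    "instances_to_arrays",
    "split_instances",
]

CLASS_TO_INDEX = {"HC": 0, "PD": 1}
INDEX_TO_CLASS = {v: k for k, v in CLASS_TO_INDEX.items()}


@dataclass(frozen=True)
class ModelConfig:
    conv_filters: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    n_heads: int = 4
    d_k: int = 16
    ff_dim: int = 64
    lstm_units: int = 64
    dropout_rate: float = 0.3
    n_classes: int = 2
    use_lstm: bool = True
    use_dropout: bool = True
    seed: int = 0

    def validate(self) -> None:
        if any(f < 1 for f in self.conv_filters) or len(self.conv_filters) != 2:
            raise ValueError("conv_filters must be two positive integers")
        for name in ("kernel_size", "pool_size", "n_heads", "d_k", "ff_dim", "lstm_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.conv_filters[1] % self.n_heads != 0:
            raise ValueError("model dimension (conv_filters[1]) must be divisible by n_heads")


@dataclass(frozen=True)
class TrainingProtocol:
    """The published training protocol: Adam on categorical cross-entropy."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1


def instances_to_arrays(
    instances: Sequence[FeatureInstance] | AugmentedDataset,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack FeatureInstances into (X: n x C x F, y: int labels)."""
    if isinstance(instances, AugmentedDataset):
        instances = instances.instances
    if not instances:
        raise ValueError("no instances")
    X = np.stack([inst.matrix for inst in instances])
    y = np.array([CLASS_TO_INDEX[inst.label] for inst in instances])
    return X, y


def split_instances(
    instances: Sequence[FeatureInstance],
    test_fraction: float = 0.2,
    by: str = "frame",
    seed: int = 0,
) -> tuple[list[FeatureInstance], list[FeatureInstance]]:
    """Train/test split of feature instances.

    ``by="frame"`` shuffles instances stratified by label (the published
    protocol's 80/20 split). ``by="subject"`` holds out whole subjects per
    class — the leakage-safe alternative, since frames of one subject are
    strongly dependent.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[FeatureInstance] = []
    test: list[FeatureInstance] = []
    if by == "frame":
        for label in sorted({inst.label for inst in instances}):
            group = [inst for inst in instances if inst.label == label]
            order = rng.permutation(len(group))
            n_test = max(1, int(round(test_fraction * len(group))))
            test_idx = set(order[:n_test].tolist())
            for i, inst in enumerate(group):
                (test if i in test_idx else train).append(inst)
    elif by == "subject":
        for label in sorted({inst.label for inst in instances}):
            subjects = sorted({i.subject_id for i in instances if i.label == label})
            order = rng.permutation(len(subjects))
            n_test = max(1, int(round(test_fraction * len(subjects))))
            held = {subjects[i] for i in order[:n_test]}
            for inst in instances:
                if inst.label != label:
                    continue
                (test if inst.subject_id in held else train).append(inst)
    else:
        raise ValueError("by must be 'frame' or 'subject'")
    return train, test


class CTESM:
    """CNN → multi-head attention → LSTM → softmax classifier."""

    def __init__(self, n_channels: int, n_features: int, config: ModelConfig | None = None):
        self.cfg = config or ModelConfig()
        self.cfg.validate()
        self.n_channels = n_channels
        self.n_features = n_features
        cfg = self.cfg
        d_model = cfg.conv_filters[1]
        seq_after_convs = n_channels - 2 * (cfg.kernel_size - 1)
        self.seq_len = seq_after_convs // cfg.pool_size
        if self.seq_len < 1:
            raise ValueError("n_channels too small for the configured CNN block")
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.conv1 = nn.Conv1d(n_features, cfg.conv_filters[0], cfg.kernel_size, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv1d(cfg.conv_filters[0], d_model, cfg.kernel_size, rng)
        self.relu2 = nn.ReLU()
        self.pool = nn.MaxPool1d(cfg.pool_size)
        self.bnorm = nn.BatchNorm(d_model)
        self.mha = nn.MultiHeadAttention(d_model, cfg.n_heads, cfg.d_k, rng)
        self.ln1 = nn.LayerNorm()
        self.ff1 = nn.Dense(d_model, cfg.ff_dim, rng)
        self.ff_relu = nn.ReLU()
        self.ff2 = nn.Dense(cfg.ff_dim, d_model, rng)
        self.ln2 = nn.LayerNorm()
        self.dropout = nn.Dropout(cfg.dropout_rate if cfg.use_dropout else 0.0, rng)
        head_in = cfg.lstm_units if cfg.use_lstm else d_model
        self.lstm = nn.LSTM(d_model, cfg.lstm_units, rng) if cfg.use_lstm else None
        self.out = nn.Dense(head_in, cfg.n_classes, rng)
        self._rng = rng
        # feature standardization statistics, fit on the training partition
        self._mu = np.zeros(n_features)
        self._sd = np.ones(n_features)

    # -- stages (exposed for inspection and unit identities) ---------------

    def params(self) -> list[nn.Param]:
        layers = [self.conv1, self.conv2, self.bnorm, self.mha, self.ff1, self.ff2, self.out]
        if self.lstm is not None:
            layers.insert(6, self.lstm)
        return [p for layer in layers for p in layer.params()]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mu) / self._sd

    def cnn_block(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """(B, C, F) instances → (B, T, D) sequence along the electrode axis."""
        if X.ndim != 3 or X.shape[1:] != (self.n_channels, self.n_features):
            raise ValueError(
                f"expected batch of shape (B, {self.n_channels}, {self.n_features}),"
                f" got {X.shape}"
            )
        h = self.relu1.forward(self.conv1.forward(X, training), training)
        h = self.relu2.forward(self.conv2.forward(h, training), training)
        h = self.pool.forward(h, training)
        return self.bnorm.forward(h, training)

    def transformer_block(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """LN(attn(x) + x) then LN(FFN(·) + ·), dropout after the block."""
        x1 = self.ln1.forward(self.mha.forward(x, training) + x, training)
        ff = self.ff2.forward(self.ff_relu.forward(self.ff1.forward(x1, training), training), training)
        x2 = self.ln2.forward(ff + x1, training)
        return self.dropout.forward(x2, training)

    def lstm_head(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Sequence → class probabilities (softmax over the dense output)."""
        if self.lstm is not None:
            h = self.lstm.forward(x, training)
        else:
            h = x.mean(axis=1)
            self._pool_T = x.shape[1]
        logits = self.out.forward(h, training)
        return nn.softmax(logits, axis=-1)

    def _forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        seq = self.cnn_block(self._standardize(X), training)
        seq = self.transformer_block(seq, training)
        return self.lstm_head(seq, training)

    def _backward(self, dlogits: np.ndarray) -> None:
        dh = self.out.backward(dlogits)
        if self.lstm is not None:
            dseq = self.lstm.backward(dh)
        else:
            dseq = np.repeat(dh[:, None, :], self._pool_T, axis=1) / self._pool_T
        dseq = self.dropout.backward(dseq)
        dx2 = self.ln2.backward(dseq)
        dff = self.ff1.backward(self.ff_relu.backward(self.ff2.backward(dx2)))
        dx1 = dx2 + dff
        dattn_in = self.ln1.backward(dx1)
        dx = dattn_in + self.mha.backward(dattn_in)
        dx = self.bnorm.backward(dx)
        dx = self.pool.backward(dx)
        dx = self.conv2.backward(self.relu2.backward(dx))
        self.conv1.backward(self.relu1.backward(dx))

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        protocol: TrainingProtocol | None = None,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> dict[str, list[float]]:
        """Train with Adam on categorical cross-entropy; returns the history.

        If no validation set is given, ``validation_fraction`` of the
        training data is carved off (stratified shuffle under the model
        seed) to record per-epoch validation accuracy and loss.
        """
        protocol = protocol or TrainingProtocol()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if X_val is None and protocol.validation_fraction > 0:
            idx = self._rng.permutation(len(X))
            n_val = max(1, int(round(protocol.validation_fraction * len(X))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            if len(np.unique(y[tr_idx])) < 2:
                raise ValueError("training partition lost a class in the validation split")
            X, X_val, y, y_val = X[tr_idx], X[val_idx], y[tr_idx], y[val_idx]
        self._mu = X.reshape(-1, self.n_features).mean(axis=0)
        sd = X.reshape(-1, self.n_features).std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        onehot = np.eye(self.cfg.n_classes)[y]
        optimizer = nn.Adam(self.params(), lr=protocol.learning_rate)
        history: dict[str, list[float]] = {
            "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
        }
        n = len(X)
        for _epoch in range(protocol.epochs):
            order = self._rng.permutation(n)
            epoch_loss, epoch_correct = 0.0, 0
            for start in range(0, n, protocol.batch_size):
                batch = order[start : start + protocol.batch_size]
                xb, yb = X[batch], onehot[batch]
                probs = self._forward(xb, training=True)
                eps = 1e-12
                epoch_loss -= float((yb * np.log(probs + eps)).sum())
                epoch_correct += int((probs.argmax(1) == y[batch]).sum())
                optimizer.zero_grad()
                self._backward((probs - yb) / len(batch))
                optimizer.step()
            history["loss"].append(epoch_loss / n)
            history["accuracy"].append(epoch_correct / n)
            if X_val is not None:
                val_probs = self.predict_proba(X_val)
                val_onehot = np.eye(self.cfg.n_classes)[y_val]
                history["val_loss"].append(
                    float(-(val_onehot * np.log(val_probs + 1e-12)).sum() / len(X_val))
                )
                history["val_accuracy"].append(
                    float((val_probs.argmax(1) == y_val).mean())
                )
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for start in range(0, len(X), 256):
            out.append(self._forward(X[start : start + 256], training=False))
        return np.concatenate(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Self-describing checkpoint: config JSON + weights in one archive."""
        path = Path(path)
        payload = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        payload["bn_running_mean"] = self.bnorm.running_mean
        payload["bn_running_var"] = self.bnorm.running_var
        payload["scaler_mu"] = self._mu
        payload["scaler_sd"] = self._sd
        meta = {
            "config": asdict(self.cfg),
            "n_channels": self.n_channels,
            "n_features": self.n_features,
        }
        np.savez(path, meta=json.dumps(meta), **payload)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "CTESM":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            cfg_dict = meta["config"]
            cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
            model = cls(meta["n_channels"], meta["n_features"], ModelConfig(**cfg_dict))
            for i, p in enumerate(model.params()):
                p.value[:] = archive[f"param_{i}"]
            model.bnorm.running_mean = archive["bn_running_mean"]
            model.bnorm.running_var = archive["bn_running_var"]
            model._mu = archive["scaler_mu"]
            model._sd = archive["scaler_sd"]
        return model
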