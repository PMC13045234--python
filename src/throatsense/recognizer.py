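"""Dual-head hybrid recognizer: CNN trunk, bidirectional LSTM, one
multi-head self-attention encoder block, and parallel softmax heads for
6-class emotion and 5-class sentence recognition.

The CNN treats the 40 feature rows as the frequency-like axis and the
128 frames as time; after two conv/pool stages the 32 remaining time
steps feed the recurrent and attention stages.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .features import N_FRAMES, N_ROWS
from .synthgen import EMOTIONS

__all__ = [
    "ModelConfig",
    "DualPrediction",
    "FeatureDataset",
    "TrainedModel",
    "EmotionTextNet",
    "build_model",
    "train",
    "predict",
    "predict_labels",
]

N_EMOTIONS = 6
N_TEXTS = 5


@dataclass(frozen=True)
class ModelConfig:
    conv_channels: tuple = (32, 64)
    kernel_size: int = 3
    lstm_layers: int = 2
    lstm_units: int = 128
    lstm_dropout: float = 0.3
    attention_heads: int = 8
    attention_width: int = 128
    ff_width: int = 256
    fc_units: int = 128
    fc_dropout: float = 0.5
    n_emotions: int = N_EMOTIONS
    n_texts: int = N_TEXTS
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 200
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.n_emotions, self.n_texts) != (N_EMOTIONS, N_TEXTS):
            raise ValueError(f"output heads must be ({N_EMOTIONS}, {N_TEXTS})")
        if self.attention_width % self.attention_heads:
            raise ValueError("attention width must be divisible by head count")


@dataclass
class DualPrediction:
    emotion_probs: np.ndarray  # (6,)
    text_probs: np.ndarray  # (5,)

    def __post_init__(self) -> None:
        self.emotion_probs = np.asarray(self.emotion_probs, dtype=np.float64)
        self.text_probs = np.asarray(self.text_probs, dtype=np.float64)
        for name, v, n in (("emotion", self.emotion_probs, N_EMOTIONS),
                           ("text", self.text_probs, N_TEXTS)):
            if v.shape != (n,):
                raise ValueError(f"{name}_probs must have shape ({n},), got {v.shape}")
            if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name}_probs must be a probability vector")

    @property
    def emotion(self) -> str:
        return EMOTIONS[int(np.argmax(self.emotion_probs))]

    @property
    def sentence_id(self) -> int:
        return int(np.argmax(self.text_probs))


@dataclass
class FeatureDataset:
    """Stacked feature matrices with both label sets and provenance ids."""

    features: np.ndarray  # (N, 40, 128)
    emotion_labels: np.ndarray  # (N,) ints 0..5, alphabetical emotion order
    text_labels: np.ndarray  # (N,) ints 0..4
    subject_ids: np.ndarray  # (N,)
    recording_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 3 or self.features.shape[1:] != (N_ROWS, N_FRAMES):
            raise ValueError(
                f"features must be (N, {N_ROWS}, {N_FRAMES}), got {self.features.shape}"
            )
        self.emotion_labels = np.asarray(self.emotion_labels, dtype=np.int64)
        self.text_labels = np.asarray(self.text_labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        n = len(self.features)
        if not (len(self.emotion_labels) == len(self.text_labels) == len(self.subject_ids) == n):
            raise ValueError("label arrays must match feature count")

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, idx) -> "FeatureDataset":
        idx = np.asarray(idx)
        return FeatureDataset(
            features=self.features[idx],
            emotion_labels=self.emotion_labels[idx],
            text_labels=self.text_labels[idx],
            subject_ids=self.subject_ids[idx],
            recording_ids=[self.recording_ids[i] for i in idx] if self.recording_ids else [],
        )


class EmotionTextNet(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.conv_channels
        self.conv1 = self.add_module(nn.Conv2d(1, c1, rng, config.kernel_size))
        self.bn1 = self.add_module(nn.BatchNorm2d(c1))
        self.conv2 = self.add_module(nn.Conv2d(c1, c2, rng, config.kernel_size))
        self.bn2 = self.add_module(nn.BatchNorm2d(c2))
        self.pool = self.add_module(nn.MaxPool2d())
        feat_dim = c2 * (N_ROWS // 4)  # 64 channels x 10 rows after two pools
        self.lstm = self.add_module(
            nn.LSTM(feat_dim, config.lstm_units, config.lstm_layers, rng,
                    bidirectional=True, dropout=config.lstm_dropout)
        )
        self.proj = self.add_module(nn.Linear(2 * config.lstm_units, config.attention_width, rng))
        self.encoder = self.add_module(
            nn.TransformerEncoderBlock(config.attention_width, config.attention_heads,
                                       config.ff_width, rng)
        )
        self.fc = self.add_module(nn.Linear(config.attention_width, config.fc_units, rng))
        self.fc_dropout = self.add_module(nn.Dropout(config.fc_dropout))
        self.head_emotion = self.add_module(nn.Linear(config.fc_units, config.n_emotions, rng))
        self.head_text = self.add_module(nn.Linear(config.fc_units, config.n_texts, rng))
        # zero-initialized heads start at uniform predictions, which lets the
        # trunk receive well-scaled gradients from the first step
        self.head_emotion.weight.data[...] = 0.0
        self.head_text.weight.data[...] = 0.0

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != (N_ROWS, N_FRAMES):
            raise ValueError(
                f"expected input of shape (batch, {N_ROWS}, {N_FRAMES}), got {x.shape}"
            )
        t = nn.Tensor(x[:, None, :, :])  # (B, 1, 40, 128)
        t = self.pool(self.bn1(self.conv1(t)).relu())
        t = self.pool(self.bn2(self.conv2(t)).relu())
        b = t.shape[0]
        # (B, C, F, T) -> (B, T, C*F): time-major sequence for the LSTM
        t = t.transpose((0, 3, 1, 2)).reshape(b, t.shape[3], -1)
        t = self.lstm(t, rng)
        t = self.encoder(self.proj(t))
        t = t.mean(axis=1)  # global average pooling over time
        t = self.fc_dropout(self.fc(t).relu(), rng)
        return self.head_emotion(t), self.head_text(t)


def build_model(config: ModelConfig = ModelConfig()) -> EmotionTextNet:
    """Untrained network mapping one (40, 128) matrix to a DualPrediction."""
    return EmotionTextNet(config)


@dataclass
class TrainedModel:
    model: EmotionTextNet
    config: ModelConfig
    training_log: list  # per-epoch dicts
    rng_seed: int
    feat_mean: np.ndarray  # (40, 1) per-row standardization
    feat_std: np.ndarray

    def save(self, path) -> None:
        arrays = {f"arr_{i}": a for i, a in enumerate(self.model.state_arrays())}
        np.savez(
            path,
            feat_mean=self.feat_mean,
            feat_std=self.feat_std,
            config_json=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            log_json=np.frombuffer(
                json.dumps(self.training_log).encode(), dtype=np.uint8
            ),
            rng_seed=np.asarray(self.rng_seed),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["config_json"]).decode()))
            log = json.loads(bytes(z["log_json"]).decode())
            model = build_model(cfg)
            n = len(model.state_arrays())
            model.load_arrays([z[f"arr_{i}"] for i in range(n)])
            return cls(
                model=model, config=cfg, training_log=log,
                rng_seed=int(z["rng_seed"]), feat_mean=z["feat_mean"],
                feat_std=z["feat_std"],
            )


def _standardize(x: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return ((x - mean) / std).astype(np.float32)


def _accuracy(logits, labels) -> float:
    return float(np.mean(logits.data.argmax(axis=1) == labels))


def _epoch_eval(model: EmotionTextNet, x, ye, yt, batch_size: int):
    model.eval()
    losses, hits_e, hits_t, n = 0.0, 0, 0, 0
    for i in range(0, len(x), batch_size):
        xb, yeb, ytb = x[i : i + batch_size], ye[i : i + batch_size], yt[i : i + batch_size]
        le, lt = model.forward(xb)
        loss = nn.cross_entropy(le, yeb) + nn.cross_entropy(lt, ytb)
        losses += float(loss.data) * len(xb)
        hits_e += int(np.sum(le.data.argmax(axis=1) == yeb))
        hits_t += int(np.sum(lt.data.argmax(axis=1) == ytb))
        n += len(xb)
    return losses / n, hits_e / n, hits_t / n


def train(
    model: EmotionTextNet,
    train_set: FeatureDataset,
    val_set: FeatureDataset,
    config: ModelConfig | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Minimize the summed cross-entropies of both heads with Adam.

    Stops when validation loss fails to improve for
    ``early_stopping_patience`` consecutive epochs and restores the
    best-validation weights.
    """
    config = config or model.config
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if train_set.recording_ids and val_set.recording_ids:
        overlap = set(train_set.recording_ids) & set(val_set.recording_ids)
        if overlap:
            raise ValueError(f"train/val overlap on {len(overlap)} recordings")

    rng = np.random.default_rng(config.seed)
    mean = train_set.features.mean(axis=(0, 2), keepdims=True)[0]
    std = train_set.features.std(axis=(0, 2), keepdims=True)[0] + 1e-6
    xtr = _standardize(train_set.features, mean, std)
    xva = _standardize(val_set.features, mean, std)
    ye_tr, yt_tr = train_set.emotion_labels, train_set.text_labels
    ye_va, yt_va = val_set.emotion_labels, val_set.text_labels

    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    best_loss = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    best_epoch = 0
    stall = 0
    log = []
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(xtr))
        tr_loss, n_seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            le, lt = model.forward(xtr[idx], rng)
            loss = nn.cross_entropy(le, ye_tr[idx]) + nn.cross_entropy(lt, yt_tr[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}: "
                    f"{float(loss.data)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            tr_loss += float(loss.data) * len(idx)
            n_seen += len(idx)
        val_loss, val_acc_e, val_acc_t = _epoch_eval(
            model, xva, ye_va, yt_va, config.batch_size
        )
        entry = dict(
            epoch=epoch, train_loss=tr_loss / n_seen, val_loss=val_loss,
            val_acc_emotion=val_acc_e, val_acc_text=val_acc_t,
        )
        log.append(entry)
        if verbose:
            print(
                f"epoch {epoch:3d} train {entry['train_loss']:.4f} "
                f"val {val_loss:.4f} acc_e {val_acc_e:.3f} acc_t {val_acc_t:.3f}"
            )
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = [a.copy() for a in model.state_arrays()]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.early_stopping_patience:
                break
    model.load_arrays(best_state)
    model.eval()
    log.append(dict(epoch=best_epoch, restored_best=True, val_loss=best_loss))
    return TrainedModel(
        model=model, config=config, training_log=log, rng_seed=config.seed,
        feat_mean=mean, feat_std=std,
    )


def predict(trained: TrainedModel, features: np.ndarray) -> list:
    """Deterministic inference; returns one DualPrediction per input row."""
    x = np.asarray(features, dtype=np.float32)
    single = x.ndim == 2
    if single:
        x = x[None]
    x = _standardize(x, trained.feat_mean, trained.feat_std)
    trained.model.eval()
    out = []
    for i in range(0, len(x), trained.config.batch_size):
        le, lt = trained.model.forward(x[i : i + trained.config.batch_size])
        pe = _softmax_np(le.data)
        pt = _softmax_np(lt.data)
        out.extend(DualPrediction(pe[j], pt[j]) for j in range(len(pe)))
    return out


def predict_labels(trained: TrainedModel, features: np.ndarray):
    """(emotion_idx, text_idx) arrays for a feature batch."""
    preds = predict(trained, features)
    e = np.array([int(np.argmax(p.emotion_probs)) for p in preds])
    t = np.array([int(np.argmax(p.text_probs)) for p in preds])
    return e, t


def _softmax_np(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
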