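"""View-classification CNN: folds, training protocol and ensembling.

Two input strategies are supported for classifying a clip into one of the
five standard views:

``averaged``
    the network sees the pixel-wise average of the clip's 10
    cycle-normalized frames (one sample per clip);

``per_frame``
    the network is trained on the 10 individual frames (each inheriting
    the clip's view label) and a clip is classified by averaging the 10
    per-frame softmax probability vectors.

Model selection follows the early-stopping-by-checkpoint protocol: train
a fixed number of epochs with Adam on cross-entropy and keep the
parameters from the epoch with minimum validation loss.  k-fold
cross-validation is patient-level (all clips of a patient share a fold)
so near-duplicate frames never straddle the train/test boundary.  At
prediction time the k per-fold weight sets form an ensemble: their
probability vectors are averaged and the argmax (ties broken by the
canonical view order) is the predicted view.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import VIEW_ORDER, FrameSet, ViewLabel
from . import nn

__all__ = [
    "ModelConfig", "ViewModel", "WeightSet", "Sample",
    "make_folds", "build_model", "train",
    "predict_avgimage", "predict_frames",
    "combine_probabilities", "ensemble_predict", "ensemble_proba_many",
    "train_crossval", "save_weight_sets", "load_weight_sets",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training protocol of the view classifier.

    Defaults follow the study protocol: five conv blocks with 64-128
    channels, 50 epochs of Adam (default parameters) on cross-entropy,
    120 x 120 grayscale input.  Desk-scale experiments shrink channels
    and epochs through this config.
    """

    n_conv_layers: int = 5
    channels: tuple[int, ...] = (64, 80, 96, 112, 128)
    input_mode: str = "per_frame"  # or "averaged"
    n_classes: int = 5
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    dense_units: int = 64
    input_size: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 5:
            raise ValueError("the view classifier is a 5-class model")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if len(self.channels) != self.n_conv_layers:
            raise ValueError("need one channel count per conv layer")
        if self.input_mode not in ("averaged", "per_frame"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if any(not (64 <= c <= 128) for c in self.channels):
            warnings.warn(
                "channel counts outside the tuned 64-128 range", stacklevel=2)


class ViewModel:
    """A (possibly untrained) view-classification CNN."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list[nn.Layer] = []
        in_ch, size = 1, config.input_size
        for ch in config.channels:
            layers += [nn.Conv2D(in_ch, ch, rng), nn.ReLU(), nn.MaxPool2()]
            in_ch, size = ch, size // 2
        if size < 1:
            raise ValueError("too many conv blocks for the input size")
        layers += [nn.Flatten(),
                   nn.Dense(in_ch * size * size, config.dense_units, rng),
                   nn.ReLU(),
                   nn.Dense(config.dense_units, config.n_classes, rng)]
        self.net = nn.Sequential(layers)

    def _as_batch(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        s = self.config.input_size
        if x.shape[1:] != (s, s):
            raise ValueError(f"expected {s}x{s} input, got {x.shape[1:]}")
        return x[:, :, :, None]  # channels-last

    def forward_logits(self, images: np.ndarray) -> np.ndarray:
        """Logits for a batch of [0,1]-scaled H x W images."""
        return self.net.forward(self._as_batch(images))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward_logits(images))


@dataclass
class WeightSet:
    """Trained parameters of one fold's model at minimum validation loss."""

    state: list[np.ndarray]
    fold: int
    val_loss: float
    config: ModelConfig
    history: list[tuple[float, float]] = field(default_factory=list)

    def model(self) -> ViewModel:
        m = ViewModel(self.config)
        m.net.set_state(self.state)
        return m


@dataclass
class Sample:
    """One clip ready for the classifier."""

    patient_id: str
    frameset: FrameSet
    label: ViewLabel


def make_folds(patient_ids: list[str], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Random patient-level k-fold partition, reproducible from ``seed``.

    Fold sizes differ by at most one patient; with 340 patients and k=5
    every fold holds 68 patients (68 x 5 views x 10 frames = 3,400 frame
    images).
    """
    ids = list(dict.fromkeys(patient_ids))  # unique, order-preserving
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(ids):
        raise ValueError(f"cannot split {len(ids)} patients into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[j]: i % k for i, j in enumerate(order)}


def build_model(config: ModelConfig) -> ViewModel:
    """Fresh model with seed-deterministic initialization."""
    return ViewModel(config)


def _to_xy(samples: list[Sample], mode: str) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in samples:
        if mode == "averaged":
            xs.append(s.frameset.averaged)
            ys.append(s.label.index)
        else:
            for f in s.frameset.frames:
                xs.append(f)
                ys.append(s.label.index)
    x = np.stack(xs).astype(np.float32) / 255.0
    return x, np.array(ys, dtype=np.int64)


def _epoch_loss(model: ViewModel, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total, n = 0.0, len(y)
    for i in range(0, n, batch):
        logits = model.forward_logits(x[i:i + batch])
        loss, _ = nn.cross_entropy(logits, y[i:i + batch])
        total += loss * len(y[i:i + batch])
    return total / n


def train(model: ViewModel, train_set: list[Sample], val_set: list[Sample],
          config: ModelConfig, fold: int = 0, *,
          allow_overlap: bool = False) -> WeightSet:
    """Train with Adam on cross-entropy; keep the min-validation-loss epoch.

    ``train_set`` and ``val_set`` must be patient-disjoint (asserted
    unless ``allow_overlap`` is set for deliberate train-as-val runs).
    Sample order is reshuffled every epoch from the config seed.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    tr_pat = {s.patient_id for s in train_set}
    va_pat = {s.patient_id for s in val_set}
    if (tr_pat & va_pat) and not allow_overlap:
        raise ValueError(f"patient leakage between train and val: {tr_pat & va_pat}")

    xtr, ytr = _to_xy(train_set, config.input_mode)
    xva, yva = _to_xy(val_set, config.input_mode)
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.net.params, lr=config.lr)
    best_state, best_val = model.net.get_state(), np.inf
    history = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(ytr))
        ep_loss, nb = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward_logits(xtr[idx])
            loss, grad = nn.cross_entropy(logits, ytr[idx])
            model.net.backward(grad)
            opt.step(model.net.grads)
            ep_loss += loss
            nb += 1
        val_loss = _epoch_loss(model, xva, yva, config.batch_size)
        history.append((ep_loss / max(nb, 1), val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.net.get_state()
    model.net.set_state(best_state)
    return WeightSet(state=best_state, fold=fold, val_loss=float(best_val),
                     config=config, history=history)


def predict_avgimage(weights: WeightSet, fs: FrameSet) -> np.ndarray:
    """Softmax probabilities from the clip's averaged image."""
    model = weights.model()
    x = fs.averaged.astype(np.float32) / 255.0
    return model.predict_proba(x)[0]


def predict_frames(weights: WeightSet, fs: FrameSet) -> np.ndarray:
    """Arithmetic mean of the per-frame softmax probability vectors."""
    model = weights.model()
    x = fs.frames.astype(np.float32) / 255.0
    return model.predict_proba(x).mean(axis=0)


def combine_probabilities(probs: list[np.ndarray]) -> tuple[np.ndarray, ViewLabel]:
    """Mean of probability vectors and its argmax view.

    ``np.argmax`` returns the first maximum, which is exactly the
    tie-break over the canonical view ordering.
    """
    if not probs:
        raise ValueError("need at least one probability vector")
    mean = np.stack(probs).mean(axis=0)
    return mean, ViewLabel.from_index(int(np.argmax(mean)))


def ensemble_predict(weight_sets: list[WeightSet], fs: FrameSet,
                     mode: str = "per_frame") -> tuple[np.ndarray, ViewLabel]:
    """Average the per-weight-set probabilities; argmax with canonical ties."""
    if not weight_sets:
        raise ValueError("need at least one weight set")
    fn = predict_avgimage if mode == "averaged" else predict_frames
    return combine_probabilities([fn(w, fs) for w in weight_sets])


def ensemble_proba_many(weight_sets: list[WeightSet], framesets: list[FrameSet],
                        mode: str = "per_frame", batch: int = 64) -> np.ndarray:
    """Batched ensemble probabilities for many clips: (n_clips, 5)."""
    if not weight_sets:
        raise ValueError("need at least one weight set")
    n = len(framesets)
    if mode == "averaged":
        x = np.stack([fs.averaged for fs in framesets]).astype(np.float32) / 255.0
    else:
        x = np.concatenate([fs.frames for fs in framesets]).astype(np.float32) / 255.0
    out = np.zeros((n, 5), dtype=np.float64)
    for ws in weight_sets:
        model = ws.model()
        probs = np.concatenate([model.predict_proba(x[i:i + batch])
                                for i in range(0, len(x), batch)])
        if mode == "per_frame":
            k = len(x) // n
            probs = probs.reshape(n, k, 5).mean(axis=1)
        out += probs
    return out / len(weight_sets)


def save_weight_sets(weight_sets: list[WeightSet], path: str | Path) -> Path:
    """Serialize trained weight sets: one ``fold<k>.npz`` per fold plus a
    JSON manifest (config, fold indices, min validation losses)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"weight_sets": []}
    for ws in weight_sets:
        fname = f"fold{ws.fold}.npz"
        np.savez(path / fname, **{f"p{i}": p for i, p in enumerate(ws.state)})
        manifest["weight_sets"].append({
            "file": fname,
            "fold": ws.fold,
            "val_loss": ws.val_loss,
            "config": {**ws.config.__dict__,
                       "channels": list(ws.config.channels)},
        })
    (path / "weights.json").write_text(json.dumps(manifest, indent=1))
    return path


def load_weight_sets(path: str | Path) -> list[WeightSet]:
    """Load weight sets written by :func:`save_weight_sets`."""
    path = Path(path)
    manifest = json.loads((path / "weights.json").read_text())
    out = []
    for entry in manifest["weight_sets"]:
        cfg_dict = dict(entry["config"])
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # stored config may be desk-scale
            config = ModelConfig(**cfg_dict)
        with np.load(path / entry["file"]) as npz:
            state = [npz[f"p{i}"] for i in range(len(npz.files))]
        out.append(WeightSet(state=state, fold=entry["fold"],
                             val_loss=entry["val_loss"], config=config))
    return out


def train_crossval(samples: list[Sample], folds: dict[str, int],
                   config: ModelConfig, k: int = 5) -> list[WeightSet]:
    """One weight set per fold.

    For fold ``f``, the fold itself is held out entirely; of the
    remaining folds, ``(f+1) mod k`` provides the validation set for the
    min-loss checkpoint and the rest are the training set.
    """
    weight_sets = []
    for f in range(k):
        if k >= 3:
            val_fold = (f + 1) % k
            tr = [s for s in samples if folds[s.patient_id] not in (f, val_fold)]
            va = [s for s in samples if folds[s.patient_id] == val_fold]
        else:  # k == 2: split the other fold's patients in half for validation
            others = sorted({s.patient_id for s in samples
                             if folds[s.patient_id] != f})
            va_pat = set(others[len(others) // 2:])
            tr = [s for s in samples if folds[s.patient_id] != f
                  and s.patient_id not in va_pat]
            va = [s for s in samples if s.patient_id in va_pat]
        cfg = ModelConfig(**{**config.__dict__, "seed": config.seed + f})
        model = build_model(cfg)
        weight_sets.append(train(model, tr, va, cfg, fold=f))
    return weight_sets
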