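"""Multiscale convolutional readout over echo state representations.

The five per-part ESRs feed three convolution blocks: the central trunk
is a single-channel block, while left+right arm and left+right leg form
dual-channel blocks whose filters span both ESRs and capture bilateral
correlation.  Each block applies full-height filters of several time
scales k (default 2, 3, 4) in valid mode along time, ReLU, and
max-over-time pooling, so every filter contributes one scalar no matter
where in the sequence its motif occurs.  The pooled scalars are
concatenated and mapped by a single fully connected layer to softmax
class probabilities.  Training minimises cross-entropy with Adam; all
randomness (weight initialization, shuffling) is seeded.

Implemented directly on numpy: forward, backprop and the Adam update are
explicit, which keeps the training loop deterministic and dependency-free.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: conv blocks: name -> the parts whose ESRs it consumes
BLOCKS: Dict[str, Tuple[str, ...]] = {
    "CT": ("CT",),
    "ARMS": ("LA", "RA"),
    "LEGS": ("LL", "RL"),
}


@dataclass(frozen=True)
class ModelConfig:
    """Readout architecture.

    ``scales`` are the filter time-lengths k; each (block, scale) pair
    gets ``filters_per_scale`` filters, so the pooled feature vector has
    ``3 * len(scales) * filters_per_scale`` entries.
    """

    reservoir_size: int
    num_classes: int
    scales: Tuple[int, ...] = (2, 3, 4)
    filters_per_scale: int = 16

    def __post_init__(self) -> None:
        if self.filters_per_scale < 1:
            raise ValueError("filters_per_scale must be >= 1")
        if any(k < 1 for k in self.scales):
            raise ValueError("scales must be positive")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def feature_dim(self) -> int:
        return len(BLOCKS) * len(self.scales) * self.filters_per_scale


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class PredictionResult:
    probabilities: np.ndarray
    predicted: int


@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray  # rows = true class

    def as_dict(self) -> Dict:
        return {"accuracy": self.accuracy, "confusion": self.confusion.tolist()}


@dataclass
class EsrDataset:
    """Stacked per-block ESR tensors ready for the readout.

    ``blocks[name]`` has shape (B, T, channels*N): single-channel blocks
    keep the raw ESR; dual-channel blocks hstack left and right ESRs.
    """

    blocks: Dict[str, np.ndarray]
    labels: np.ndarray  # B integer class ids
    classes: List[str]

    def __len__(self) -> int:
        return int(self.labels.shape[0])


def stack_esr_samples(
    samples: Sequence[Dict[str, np.ndarray]],
    labels: Sequence[str],
    classes: Optional[Sequence[str]] = None,
) -> EsrDataset:
    """Assemble per-sample {part: T x N ESR} dicts into block tensors."""
    if classes is None:
        classes = sorted(set(labels))
    class_to_id = {c: i for i, c in enumerate(classes)}
    blocks: Dict[str, np.ndarray] = {}
    for name, parts in BLOCKS.items():
        blocks[name] = np.stack(
            [np.hstack([np.asarray(s[p], dtype=float) for p in parts]) for s in samples]
        )
    y = np.array([class_to_id[l] for l in labels], dtype=np.int64)
    return EsrDataset(blocks=blocks, labels=y, classes=list(classes))


# ---------------------------------------------------------------------------
# elementary operators (reference forms of the model's building blocks)
# ---------------------------------------------------------------------------

def conv_single(esr: np.ndarray, filt: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Valid correlation of one full-height k x N filter along time + ReLU."""
    esr = np.atleast_2d(np.asarray(esr, dtype=float))
    filt = np.atleast_2d(np.asarray(filt, dtype=float))
    T, N = esr.shape
    k = filt.shape[0]
    if filt.shape[1] != N:
        raise ValueError("filter width must equal the state dimension")
    if k > T:
        raise ValueError(f"filter length k={k} exceeds T={T}")
    windows = np.lib.stride_tricks.sliding_window_view(esr, (k, N)).reshape(T - k + 1, k * N)
    return np.maximum(windows @ filt.reshape(-1) + bias, 0.0)


def conv_dual(
    esr_left: np.ndarray,
    esr_right: np.ndarray,
    filt: np.ndarray,
    bias: float = 0.0,
) -> np.ndarray:
    """Dual-channel convolution: one k x N x 2 filter spans both ESRs."""
    esr_left = np.atleast_2d(np.asarray(esr_left, dtype=float))
    esr_right = np.atleast_2d(np.asarray(esr_right, dtype=float))
    if esr_left.shape != esr_right.shape:
        raise ValueError("left and right ESRs must have identical shape")
    filt = np.asarray(filt, dtype=float)
    if filt.ndim != 3 or filt.shape[2] != 2:
        raise ValueError("dual filter must be k x N x 2")
    stacked = np.hstack([esr_left, esr_right])  # T x 2N
    flat = np.hstack([filt[:, :, 0], filt[:, :, 1]])  # k x 2N
    return conv_single(stacked, flat, bias)


def max_over_time(feature_map: np.ndarray) -> float:
    """Pool a temporal feature map to its single largest activation."""
    feature_map = np.asarray(feature_map, dtype=float)
    if feature_map.size == 0:
        raise ValueError("empty feature map")
    return float(feature_map.max())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------

class ConvEsnReadout:
    """Trainable multiscale convolutional classifier over block ESRs."""

    def __init__(
        self,
        config: ModelConfig,
        seed: int = 0,
        block_widths: Optional[Dict[str, int]] = None,
    ):
        """``block_widths`` overrides the per-block input width (columns of
        the stacked ESR) when channel reservoirs differ in size; by
        default every part contributes ``config.reservoir_size`` states."""
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        N = config.reservoir_size
        F = config.filters_per_scale
        self.block_widths = dict(block_widths) if block_widths else {
            name: len(parts) * N for name, parts in BLOCKS.items()
        }
        self.params: Dict[str, np.ndarray] = {}
        for name, parts in BLOCKS.items():
            width = self.block_widths[name]
            for k in config.scales:
                fan_in = k * width
                limit = np.sqrt(6.0 / (fan_in + F))
                self.params[f"W_{name}_{k}"] = rng.uniform(-limit, limit, size=(F, fan_in))
                self.params[f"b_{name}_{k}"] = np.zeros(F)
        D = config.feature_dim
        S = config.num_classes
        limit = np.sqrt(6.0 / (D + S))
        self.params["W_fc"] = rng.uniform(-limit, limit, size=(S, D))
        self.params["b_fc"] = np.zeros(S)
        # Adam state
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.epochs_trained = 0

    # -- forward -----------------------------------------------------------

    def _windows(self, x: np.ndarray, k: int) -> np.ndarray:
        """(B, T, W) -> (B, T-k+1, k*W) sliding windows along time."""
        B, T, W = x.shape
        if k > T:
            raise ValueError(f"scale k={k} exceeds sequence length T={T}")
        v = np.lib.stride_tricks.sliding_window_view(x, (1, k, W))
        return v.reshape(B, T - k + 1, k * W)

    def _forward(self, blocks: Dict[str, np.ndarray]):
        feats: List[np.ndarray] = []
        cache: List[Tuple] = []
        for name in BLOCKS:
            x = blocks[name]
            for k in self.config.scales:
                V = self._windows(x, k)
                A = V @ self.params[f"W_{name}_{k}"].T + self.params[f"b_{name}_{k}"]
                M = np.maximum(A, 0.0)
                amax = M.argmax(axis=1)  # (B, F)
                pooled = np.take_along_axis(M, amax[:, None, :], axis=1)[:, 0, :]
                feats.append(pooled)
                cache.append((name, k, V, amax, pooled))
        feat = np.concatenate(feats, axis=1)
        logits = feat @ self.params["W_fc"].T + self.params["b_fc"]
        return logits, feat, cache

    def forward(self, channel_esrs: Dict[str, np.ndarray]) -> PredictionResult:
        """Classify one sample given its five per-part ESRs."""
        blocks = {
            name: np.hstack([np.asarray(channel_esrs[p], dtype=float) for p in parts])[None]
            for name, parts in BLOCKS.items()
        }
        logits, _, _ = self._forward(blocks)
        probs = softmax(logits)[0]
        return PredictionResult(probabilities=probs, predicted=int(probs.argmax()))

    def predict_proba(self, dataset: EsrDataset) -> np.ndarray:
        logits, _, _ = self._forward(dataset.blocks)
        return softmax(logits)

    # -- training ----------------------------------------------------------

    def _loss_and_grads(self, blocks: Dict[str, np.ndarray], y: np.ndarray):
        logits, feat, cache = self._forward(blocks)
        B = y.shape[0]
        probs = softmax(logits)
        loss = float(-np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean())
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: Dict[str, np.ndarray] = {
            "W_fc": dlogits.T @ feat,
            "b_fc": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ self.params["W_fc"]
        F = self.config.filters_per_scale
        for i, (name, k, V, amax, pooled) in enumerate(cache):
            dp = dfeat[:, i * F : (i + 1) * F]
            dpre = dp * (pooled > 0.0)  # ReLU gate at the pooled maximum
            gathered = np.take_along_axis(V, amax[:, :, None], axis=1)  # (B, F, k*W)
            grads[f"W_{name}_{k}"] = np.einsum("bf,bfj->fj", dpre, gathered)
            grads[f"b_{name}_{k}"] = dpre.sum(axis=0)
        return loss, grads

    def _adam_update(self, grads: Dict[str, np.ndarray], lr: float,
                     beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for key, g in grads.items():
            self._m[key] = beta1 * self._m[key] + (1 - beta1) * g
            self._v[key] = beta2 * self._v[key] + (1 - beta2) * g * g
            mhat = self._m[key] / (1 - beta1**t)
            vhat = self._v[key] / (1 - beta2**t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        train: EsrDataset,
        val: Optional[EsrDataset] = None,
        tc: TrainConfig = TrainConfig(),
    ) -> Dict[str, List[float]]:
        """Train with Adam + cross-entropy; resumable (Adam state kept).

        Returns per-epoch ``train_loss`` and (when a validation set is
        given) ``val_accuracy``.
        """
        present = set(np.unique(train.labels).tolist())
        if present != set(range(self.config.num_classes)):
            missing = sorted(set(range(self.config.num_classes)) - present)
            raise ValueError(f"classes absent from training set: {missing}")
        rng = np.random.default_rng(tc.seed + 7919 * self.epochs_trained)
        history: Dict[str, List[float]] = {"train_loss": [], "val_accuracy": []}
        B = len(train)
        for _ in range(tc.epochs):
            order = rng.permutation(B)
            losses = []
            for start in range(0, B, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                batch = {name: arr[idx] for name, arr in train.blocks.items()}
                loss, grads = self._loss_and_grads(batch, train.labels[idx])
                if tc.learning_rate > 0:
                    self._adam_update(grads, tc.learning_rate)
                losses.append(loss)
            history["train_loss"].append(float(np.mean(losses)))
            if val is not None:
                history["val_accuracy"].append(self.evaluate(val).accuracy)
            self.epochs_trained += 1
        return history

    def evaluate(self, dataset: EsrDataset) -> EvalReport:
        """Accuracy = correct/total, plus the S x S confusion matrix."""
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        probs = self.predict_proba(dataset)
        pred = probs.argmax(axis=1)
        S = self.config.num_classes
        confusion = np.zeros((S, S), dtype=np.int64)
        np.add.at(confusion, (dataset.labels, pred), 1)
        accuracy = float(np.trace(confusion)) / float(confusion.sum())
        return EvalReport(accuracy=accuracy, confusion=confusion)

    def clone(self) -> "ConvEsnReadout":
        """Deep copy (weights + optimizer state); used by PBT exploitation."""
        return copy.deepcopy(self)


def train(
    model: ConvEsnReadout,
    train_ds: EsrDataset,
    val_ds: Optional[EsrDataset],
    tc: TrainConfig,
) -> Tuple[ConvEsnReadout, Dict[str, List[float]]]:
    """Functional wrapper over :meth:`ConvEsnReadout.fit`."""
    history = model.fit(train_ds, val_ds, tc)
    return model, history


def evaluate(model: ConvEsnReadout, dataset: EsrDataset) -> EvalReport:
    return model.evaluate(dataset)
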