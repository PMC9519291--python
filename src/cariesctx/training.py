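"""End-to-end optimization with validation-best model selection.

Training follows the reference protocol: Adam, mini-batch 32, learning rate
1e-3, shuffled epochs, and after every epoch the selection metric is
computed on the validation partition; the returned model carries the
weights of the best validation epoch. Neighbor images for each training
example are resolved strictly within the example's own radiograph, so a
radiograph-level split guarantees no image ever crosses partitions.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .data import DatasetSplit, ToothRecord
from .evaluation import roc_auc
from .model import ContextAwareModel, ModelConfig
from .preprocess import contrast_enhance, resize_for_model
from .topology import context_positions

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "Example",
    "prepare_tensors",
    "build_batches",
    "build_examples",
    "train",
    "TrainResult",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    seed: int = 0
    selection_metric: str = "accuracy"
    patience: int = 20

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.selection_metric not in ("accuracy", "f1", "auc"):
            raise ValueError("selection_metric must be accuracy, f1 or auc")


@dataclass(frozen=True)
class Example:
    """One training/evaluation unit: a present labelled tooth plus context."""

    current: int  # index into the tensor table
    neighbors: tuple[int, ...]
    label: int
    position: str
    radiograph_id: str


def prepare_tensors(
    records: Sequence[ToothRecord],
    side: int,
    enhance: bool = True,
    contrast_factor: float = 1.5,
) -> dict[int, np.ndarray]:
    """Preprocess every present tooth once: enhance, resize, add channel axis."""
    tensors: dict[int, np.ndarray] = {}
    for i, rec in enumerate(records):
        if not rec.present:
            continue
        img = np.asarray(rec.image, dtype=np.float64)
        if enhance:
            img = contrast_enhance(img, factor=contrast_factor)
        tensors[i] = resize_for_model(img, side).astype(np.float32)
    return tensors


def build_examples(
    records: Sequence[ToothRecord],
    k: int,
    radiograph_ids: set[str] | frozenset[str] | None = None,
) -> list[Example]:
    """Resolve each labelled present tooth's neighbor indices within its mouth.

    Neighbors are looked up by FDI position via the k-neighbor topology;
    absent neighbors (or a non-primary position, which has no topology) are
    simply omitted. ``radiograph_ids`` restricts to one split partition.
    """
    index: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(records):
        if rec.present:
            index[(rec.radiograph_id, rec.position)] = i
    out: list[Example] = []
    for i, rec in enumerate(records):
        if not rec.present or rec.label is None:
            continue
        if radiograph_ids is not None and rec.radiograph_id not in radiograph_ids:
            continue
        nbs = tuple(
            index[(rec.radiograph_id, str(q))]
            for q in context_positions(rec.position, k)
            if (rec.radiograph_id, str(q)) in index
        )
        out.append(Example(i, nbs, int(rec.label), rec.position, rec.radiograph_id))
    return out


def build_batches(
    examples: Sequence[Example],
    tensors: dict[int, np.ndarray],
    batch_size: int,
    order: np.ndarray | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (x_cur, x_nb, seg, labels) mini-batches."""
    idx = np.arange(len(examples)) if order is None else order
    for start in range(0, len(idx), batch_size):
        chunk = [examples[j] for j in idx[start : start + batch_size]]
        x_cur = np.stack([tensors[ex.current] for ex in chunk])
        nb_imgs, seg = [], []
        for b, ex in enumerate(chunk):
            for n in ex.neighbors:
                nb_imgs.append(tensors[n])
                seg.append(b)
        x_nb = np.stack(nb_imgs) if nb_imgs else None
        labels = np.array([ex.label for ex in chunk], dtype=np.intp)
        yield x_cur, x_nb, (np.array(seg, dtype=np.intp) if seg else None), labels


def predict_examples(
    model: ContextAwareModel,
    examples: Sequence[Example],
    tensors: dict[int, np.ndarray],
    batch_size: int = 64,
) -> np.ndarray:
    """Caries probability for each example (eval mode)."""
    probs = [
        model.predict_proba(x_cur, x_nb, seg)[:, 1]
        for x_cur, x_nb, seg, _ in build_batches(examples, tensors, batch_size)
    ]
    return np.concatenate(probs) if probs else np.zeros(0)


def _selection_score(metric: str, labels: np.ndarray, scores: np.ndarray) -> float:
    preds = (scores >= 0.5).astype(int)
    if metric == "accuracy":
        return float(np.mean(preds == labels))
    if metric == "f1":
        tp = int(np.sum((preds == 1) & (labels == 1)))
        fp = int(np.sum((preds == 1) & (labels == 0)))
        fn = int(np.sum((preds == 0) & (labels == 1)))
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    _, auc = roc_auc(labels, scores)
    return float(auc)


@dataclass
class TrainResult:
    model: ContextAwareModel
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = float("nan")

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def train(
    records: Sequence[ToothRecord],
    split: DatasetSplit,
    model_config: ModelConfig,
    train_config: TrainConfig,
    tensors: dict[int, np.ndarray] | None = None,
    enhance: bool = True,
) -> TrainResult:
    """Train on the split's train partition, select the best validation epoch.

    ``tensors`` may carry precomputed preprocessed images (so baseline and
    context variants can share one preprocessing pass); otherwise they are
    computed here.
    """
    if tensors is None:
        tensors = prepare_tensors(records, model_config.input_side, enhance=enhance)
    k = model_config.k_neighbors
    train_ex = build_examples(records, k, split.train)
    val_ex = build_examples(records, k, split.validation)
    if not train_ex:
        raise ValueError("train partition has no labelled teeth")
    if not val_ex:
        raise ValueError("validation partition has no labelled teeth")
    val_labels = np.array([ex.label for ex in val_ex], dtype=np.intp)

    model = ContextAwareModel(model_config)
    opt = model.make_optimizer(lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)

    result = TrainResult(model=model)
    best_state: dict[str, np.ndarray] | None = None
    since_best = 0
    for epoch in range(train_config.max_epochs):
        order = rng.permutation(len(train_ex))
        losses = []
        for x_cur, x_nb, seg, labels in build_batches(
            train_ex, tensors, train_config.batch_size, order
        ):
            model.forward_batch(x_cur, x_nb, seg, train=True)
            losses.append(model.loss_and_backward(labels))
            opt.step(model.grads())
        scores = predict_examples(model, val_ex, tensors)
        metric = _selection_score(train_config.selection_metric, val_labels, scores)
        result.history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                f"val_{train_config.selection_metric}": metric,
            }
        )
        logger.info(
            "epoch %d: loss %.4f, val %s %.4f",
            epoch,
            result.history[-1]["train_loss"],
            train_config.selection_metric,
            metric,
        )
        if best_state is None or metric > result.best_metric:
            result.best_metric = metric
            result.best_epoch = epoch
            best_state = copy.deepcopy(model.state())
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_config.patience:
                logger.info("early stop at epoch %d", epoch)
                break
    model.load_state(best_state)
    return result
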