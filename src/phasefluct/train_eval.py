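"""Repeated-shuffle training protocol and five-metric evaluation.

The protocol mirrors a repeated random-subsampling validation: ``n_shuffles``
independent 60/20/20 train/validation/test splits, cross-entropy training
with Adam, selection of the epoch with the highest validation accuracy, and
per-shuffle test metrics (accuracy, sensitivity, specificity, precision,
AUC; positive class = metastatic) aggregated as mean and sample std across
shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .models import (FusionModel, FusionModelSpec, adapt_input_channels,
                     build_model, make_two_channel, prepare_input)

__all__ = [
    "ShufflePlan",
    "TrainConfig",
    "TrainingDivergedError",
    "CellRecord",
    "make_shuffles",
    "prepare_dataset",
    "train_one_shuffle",
    "metrics_from_scores",
    "evaluate",
    "aggregate",
    "run_protocol",
]

LABELS = {"primary": 0, "metastatic": 1}
METRICS = ("accuracy", "sensitivity", "specificity", "precision", "auc")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class CellRecord:
    """One cell's classifier inputs: raw modality images plus its label."""

    cell_id: str
    label: str
    morphology: np.ndarray
    fluct_map: np.ndarray

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label '{self.label}'")

    @property
    def y(self) -> int:
        return LABELS[self.label]


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published protocol."""

    batch_size: int = 8
    learning_rate: float = 2e-6
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


@dataclass
class ShufflePlan:
    """Per-shuffle disjoint train/val/test id assignments."""

    n_shuffles: int
    fractions: tuple[float, float, float]
    master_seed: int
    assignments: list[dict[str, list]] = field(default_factory=list)

    def partition(self, i: int) -> dict[str, list]:
        return self.assignments[i]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_shuffles(cell_ids, n_shuffles: int = 20,
                  fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  master_seed: int = 0, stratify: bool = False,
                  labels=None) -> ShufflePlan:
    """Create ``n_shuffles`` random train/val/test partitions of the ids.

    Split sizes are round-half-up on the train and validation fractions with
    the remainder as test.  Deterministic given ``master_seed``.  With
    ``stratify=True`` the split is performed within each class (``labels``
    required).
    """
    cell_ids = list(cell_ids)
    n = len(cell_ids)
    if n < 10:
        raise ValueError("need at least 10 cells for a 60/20/20 split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if stratify and labels is None:
        raise ValueError("stratify=True requires labels")
    rng = np.random.default_rng(master_seed)

    def split(ids):
        ids = list(ids)
        k = len(ids)
        n_train = _round_half_up(fractions[0] * k)
        n_val = _round_half_up(fractions[1] * k)
        perm = rng.permutation(k)
        ids = [ids[j] for j in perm]
        return ids[:n_train], ids[n_train:n_train + n_val], ids[n_train + n_val:]

    assignments = []
    for _ in range(n_shuffles):
        if stratify:
            tr, va, te = [], [], []
            by_class: dict = {}
            for cid, lab in zip(cell_ids, labels):
                by_class.setdefault(lab, []).append(cid)
            for ids in by_class.values():
                t, v, s = split(ids)
                tr += t; va += v; te += s
        else:
            tr, va, te = split(cell_ids)
        if not (tr and va and te):
            raise ValueError("dataset too small for nonempty partitions")
        assignments.append({"train": tr, "val": va, "test": te})
    return ShufflePlan(n_shuffles, tuple(fractions), master_seed, assignments)


def prepare_dataset(records, spec: FusionModelSpec) -> dict[str, dict]:
    """Precompute normalized, resized, channel-adapted inputs per cell.

    Morphology maps are min-max normalized per image (phase offsets are not
    informative); fluctuation maps are put on the fixed log-power scale of
    :func:`phasefluct.fluctuation.log_scale_map`, since their absolute level
    carries the class contrast.
    """
    from skimage import transform as _transform

    from .fluctuation import log_scale_map

    size = spec.input_size
    out = {}
    for rec in records:
        morph = prepare_input(rec.morphology, size)
        fluct = log_scale_map(rec.fluct_map)
        if fluct.shape != (size, size):
            fluct = _transform.resize(
                fluct, (size, size), order=1, preserve_range=True,
                anti_aliasing=size < min(fluct.shape), mode="reflect"
            ).astype(np.float32)
        fluct = fluct.astype(np.float32)
        entry = {"label": rec.y}
        if "morphology" in spec.inputs:
            entry["morphology"] = adapt_input_channels(morph[None])
        if "fluctuations" in spec.inputs:
            entry["fluctuations"] = adapt_input_channels(fluct[None])
        if "two_channel" in spec.inputs:
            entry["two_channel"] = adapt_input_channels(make_two_channel(morph, fluct))
        out[rec.cell_id] = entry
    return out


def _stack_batch(data: dict, ids, modalities) -> tuple[dict[str, np.ndarray], np.ndarray]:
    inputs = {m: np.stack([data[i][m] for i in ids]) for m in modalities}
    labels = np.array([data[i]["label"] for i in ids], dtype=int)
    return inputs, labels


def _forward_scores(model: FusionModel, data: dict, ids,
                    batch: int = 64) -> np.ndarray:
    """Positive-class probabilities in the order of ``ids`` (eval mode)."""
    probs = []
    for i in range(0, len(ids), batch):
        inputs, _ = _stack_batch(data, ids[i:i + batch], model.spec.inputs)
        probs.append(model.predict_proba(inputs)[:, 1])
    return np.concatenate(probs)


def train_one_shuffle(spec: FusionModelSpec, data: dict, partition: dict,
                      config: TrainConfig):
    """Train one model on one shuffle; return it at its best-validation epoch.

    Returns ``(model, curves)`` where ``curves`` is a per-epoch DataFrame of
    train/validation loss and accuracy with a ``selected`` flag on the chosen
    epoch (highest validation accuracy; ties broken by lower validation loss,
    then by the earlier epoch).
    """
    from . import nn

    for part in ("train", "val", "test"):
        if not partition.get(part):
            raise ValueError(f"empty partition '{part}'")
    model = build_model(spec, seed=config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    train_ids = list(partition["train"])
    val_ids = list(partition["val"])

    rows = []
    best = None  # (acc, -loss, -epoch) maximized
    best_state = None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_ids))
        losses, hits, seen = [], 0, 0
        for i in range(0, len(order), config.batch_size):
            ids = [train_ids[j] for j in order[i:i + config.batch_size]]
            inputs, labels = _stack_batch(data, ids, spec.inputs)
            logits = model.forward(inputs, train=True)
            loss, dlogits, probs = nn.softmax_cross_entropy(logits, labels)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(ids))
            hits += int((probs.argmax(axis=1) == labels).sum())
            seen += len(ids)
        train_loss = float(np.sum(losses) / seen)
        train_acc = hits / seen

        val_inputs, val_labels = _stack_batch(data, val_ids, spec.inputs)
        val_logits = model.forward(val_inputs, train=False)
        val_loss, _, val_probs = nn.softmax_cross_entropy(val_logits, val_labels)
        val_acc = float((val_probs.argmax(axis=1) == val_labels).mean())

        rows.append(dict(epoch=epoch, train_loss=train_loss, train_acc=train_acc,
                         val_loss=val_loss, val_acc=val_acc))
        key = (val_acc, -val_loss, -epoch)
        if best is None or key > best:
            best = key
            best_state = model.snapshot()

    model.load_snapshot(best_state)
    curves = pd.DataFrame(rows)
    curves["selected"] = curves["epoch"] == -best[2]
    return model, curves


def metrics_from_scores(labels, scores) -> dict[str, float]:
    """Five metrics from positive-class scores (positive = metastatic).

    Predictions are score >= 0.5 (argmax for a 2-class softmax); AUC is the
    rank-based area under the ROC.  Both classes must be present; precision
    with no positive predictions is NaN (flagged undefined).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("test set must contain both classes (AUC undefined)")
    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return {
        "accuracy": (tp + tn) / labels.size,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "precision": tp / (tp + fp) if (tp + fp) > 0 else float("nan"),
        "auc": float(roc_auc_score(labels, scores)),
    }


def evaluate(model: FusionModel, data: dict, test_ids) -> dict[str, float]:
    """Five-metric test-set evaluation of a trained model.

    See :func:`metrics_from_scores` for the metric definitions.
    """
    test_ids = list(test_ids)
    labels = np.array([data[i]["label"] for i in test_ids], dtype=int)
    scores = _forward_scores(model, data, test_ids)
    return metrics_from_scores(labels, scores)


def aggregate(reports) -> pd.DataFrame:
    """Mean and sample std (ddof=1) per metric across shuffle reports."""
    df = pd.DataFrame(list(reports))
    if len(df) < 2:
        raise ValueError("need at least 2 shuffle reports to aggregate")
    return pd.DataFrame({"mean": df[list(METRICS)].mean(),
                         "std": df[list(METRICS)].std(ddof=1)})


def run_protocol(records, spec: FusionModelSpec, config: TrainConfig,
                 n_shuffles: int = 20, master_seed: int = 0,
                 plan: ShufflePlan | None = None, stratify: bool = False):
    """Full repeated-shuffle protocol for one architecture.

    Returns ``(per_shuffle, aggregate_table, curves)``; ``per_shuffle`` has
    one metric row per shuffle, ``curves`` the per-epoch training traces.
    """
    data = prepare_dataset(records, spec)
    ids = [r.cell_id for r in records]
    if plan is None:
        plan = make_shuffles(ids, n_shuffles=n_shuffles, master_seed=master_seed,
                             stratify=stratify,
                             labels=[r.label for r in records] if stratify else None)
    rows, all_curves = [], []
    for i in range(plan.n_shuffles):
        cfg = TrainConfig(batch_size=config.batch_size,
                          learning_rate=config.learning_rate,
                          epochs=config.epochs,
                          seed=config.seed + 1000 * i)
        model, curves = train_one_shuffle(spec, data, plan.partition(i), cfg)
        metrics = evaluate(model, data, plan.partition(i)["test"])
        rows.append({"shuffle": i, **metrics})
        curves.insert(0, "shuffle", i)
        all_curves.append(curves)
    per_shuffle = pd.DataFrame(rows)
    return per_shuffle, aggregate(rows), pd.concat(all_curves, ignore_index=True)
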