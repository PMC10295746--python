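"""Five-fold cross-validated training of the classifier.

Training follows the protocol: Adam at an initial learning rate of 0.01
on categorical cross-entropy with one-hot 2-class targets; when the
validation accuracy fails to improve for two consecutive epochs the
learning rate is halved, floored at 1e-5; the weights of the epoch with
the highest validation accuracy are checkpointed and used for the fold's
validation predictions. Folds are stratified by class: within each class
the members are shuffled under the seed and dealt round-robin, so fold
sizes differ by at most one per class. Augmentation is applied to the
training portion of each fold only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import metrics as _metrics
from .architecture import ModelConfig, build_network, enhanced_mobilenet_spec
from .augment import AugmentConfig, augment_image
from .dataio import AK, DatasetIndex, RunReport, load_image
from .nn import Adam
from .preprocess import PreprocessConfig, preprocess_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol parameters.

    The learning-rate schedule monitors validation accuracy: strict
    improvement over the best value so far resets the stagnation counter;
    once the counter reaches ``lr_patience_epochs`` the rate is multiplied
    by ``lr_factor`` (clamped at ``lr_min``) and the counter resets.
    ``oversample_minority`` > 1 repeats minority-class training examples
    by that factor each epoch (off by default).
    """

    lr_initial: float = 0.01
    lr_factor: float = 0.5
    lr_patience_epochs: int = 2
    lr_min: float = 1e-5
    epochs: int = 30
    batch_size: int = 32
    k_folds: int = 5
    seed: int = 0
    stratified: bool = True
    oversample_minority: float = 1.0
    monitor: str = "val_accuracy"  # fixed; documented for auditability

    def __post_init__(self):
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_min >= self.lr_initial:
            raise ValueError("lr_min must be below lr_initial")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.oversample_minority < 1.0:
            raise ValueError("oversample_minority must be >= 1")


@dataclass(frozen=True)
class FoldAssignment:
    """Validation index lists per fold: disjoint, jointly exhaustive."""

    folds: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        flat = [i for fold in self.folds for i in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("fold validation sets must be disjoint")

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_indices(self, fold_id: int) -> tuple[int, ...]:
        return tuple(
            i for j, fold in enumerate(self.folds) if j != fold_id for i in fold
        )


@dataclass
class LRState:
    """Mutable state of the plateau schedule."""

    current_lr: float
    epochs_since_best: int = 0
    best_acc: float = -np.inf


@dataclass
class FoldResult:
    fold_id: int
    history: list[dict]
    best_epoch: int
    record_ids: list[str]
    y_true: np.ndarray
    p_ak: np.ndarray
    best_weights: Optional[dict] = None


def make_folds(labels_or_index, k: int, seed: int, stratified: bool = True) -> FoldAssignment:
    """Partition records into k validation folds.

    Stratified mode shuffles each class separately under the seed and
    deals members round-robin; the dealing offset rotates between classes
    so overall fold sizes also differ by at most one.
    """
    if isinstance(labels_or_index, DatasetIndex):
        labels = labels_or_index.labels
    else:
        labels = np.asarray(labels_or_index, dtype=int)
    n = len(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]

    if not stratified:
        perm = rng.permutation(n)
        for pos, idx in enumerate(perm):
            folds[pos % k].append(int(idx))
    else:
        offset = 0
        for cls in sorted(set(labels.tolist())):
            members = np.flatnonzero(labels == cls)
            if len(members) < k:
                raise ValueError(
                    f"class {cls} has {len(members)} members; needs at least k={k}"
                )
            perm = rng.permutation(members)
            for pos, idx in enumerate(perm):
                folds[(pos + offset) % k].append(int(idx))
            offset = (offset + len(members)) % k
    return FoldAssignment(folds=tuple(tuple(sorted(f)) for f in folds))


def lr_schedule_step(val_acc_history: Sequence[float], state: LRState,
                     cfg: TrainConfig = TrainConfig()) -> LRState:
    """Advance the plateau schedule by one epoch (latest accuracy last).

    Improvement means strictly exceeding the best accuracy so far; ties
    count as stagnation. The returned state is a new object.
    """
    latest = float(val_acc_history[-1])
    lr = state.current_lr
    if latest > state.best_acc:
        return LRState(current_lr=lr, epochs_since_best=0, best_acc=latest)
    counter = state.epochs_since_best + 1
    if counter >= cfg.lr_patience_epochs:
        return LRState(current_lr=max(lr * cfg.lr_factor, cfg.lr_min),
                       epochs_since_best=0, best_acc=state.best_acc)
    return LRState(current_lr=lr, epochs_since_best=counter, best_acc=state.best_acc)


def _one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def train_fold(
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    aug_cfg: AugmentConfig,
    seed: int,
    fold_id: int = 0,
    record_ids: Optional[Sequence[str]] = None,
    keep_weights: bool = False,
) -> FoldResult:
    """Train on one fold and return history plus best-checkpoint predictions.

    ``train_set``/``val_set`` are (images, integer labels) with images as
    preprocessed [0, 1] tensors of shape (n, H, W, 3).
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training set must contain both classes")

    ss = np.random.SeedSequence(seed)
    net_seed, aug_seed, shuffle_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    spec = enhanced_mobilenet_spec(model_cfg)
    network = build_network(spec, seed=net_seed)
    optimizer = Adam(lr=train_cfg.lr_initial)
    aug_rng = np.random.default_rng(aug_seed)
    shuffle_rng = np.random.default_rng(shuffle_seed)

    base_indices = np.arange(len(x_train))
    if train_cfg.oversample_minority > 1.0:
        counts = np.bincount(y_train, minlength=2)
        minority = int(np.argmin(counts))
        extra_reps = int(round(train_cfg.oversample_minority)) - 1
        extra = np.flatnonzero(y_train == minority)
        base_indices = np.concatenate([base_indices] + [extra] * extra_reps)

    state = LRState(current_lr=train_cfg.lr_initial)
    best_val_acc = -np.inf
    best_epoch = -1
    best_weights = network.get_weights()
    history: list[dict] = []
    val_acc_history: list[float] = []

    for epoch in range(train_cfg.epochs):
        optimizer.lr = state.current_lr
        order = shuffle_rng.permutation(base_indices)
        losses, accs = [], []
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            batch = np.stack([augment_image(x_train[i], aug_cfg, aug_rng) for i in idx])
            loss, acc = network.train_batch(batch, _one_hot(y_train[idx]), optimizer)
            losses.append(loss)
            accs.append(acc)

        # precise-BN: re-estimate population statistics with the weights
        # this epoch produced before judging them on the validation fold
        network.calibrate_bn(x_train)
        proba = network.predict_proba(x_val, batch_size=train_cfg.batch_size)
        p_ak = proba[:, 1]
        val_loss = _metrics.cross_entropy(y_val, p_ak)
        val_acc = float(np.mean((p_ak >= 0.5).astype(int) == y_val))
        history.append({
            "epoch": epoch,
            "lr": state.current_lr,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": float(np.mean(accs)),
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
        logger.info(
            "fold %d epoch %d lr=%.2g train_loss=%.4f train_acc=%.4f "
            "val_loss=%.4f val_acc=%.4f",
            fold_id, epoch, state.current_lr, history[-1]["train_loss"],
            history[-1]["train_accuracy"], val_loss, val_acc,
        )
        if val_acc > best_val_acc:  # first epoch wins on ties
            best_val_acc = val_acc
            best_epoch = epoch
            best_weights = network.get_weights()
        val_acc_history.append(val_acc)
        state = lr_schedule_step(val_acc_history, state, train_cfg)

    network.set_weights(best_weights)
    proba = network.predict_proba(x_val, batch_size=train_cfg.batch_size)
    ids = list(record_ids) if record_ids is not None else [str(i) for i in range(len(y_val))]
    return FoldResult(
        fold_id=fold_id,
        history=history,
        best_epoch=best_epoch,
        record_ids=ids,
        y_true=np.asarray(y_val),
        p_ak=proba[:, 1],
        best_weights=best_weights if keep_weights else None,
    )


def load_tensors(index: DatasetIndex, pre_cfg: PreprocessConfig) -> np.ndarray:
    """Load and preprocess every image of an index into one float array."""
    return np.stack(
        [preprocess_image(load_image(r), pre_cfg) for r in index.records]
    ).astype(np.float32)


METRIC_NAMES = ("accuracy", "loss", "auc", "sensitivity", "specificity", "mcc")


def run_cv(
    index: DatasetIndex,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    aug_cfg: AugmentConfig = AugmentConfig(),
    tensors: Optional[np.ndarray] = None,
) -> RunReport:
    """k-fold cross-validation over a dataset index.

    Every record is validated exactly once; per-fold metrics are computed
    on the best-checkpoint validation predictions and aggregated as mean
    ± 95% CI. Fully reproducible from ``train_cfg.seed``.

    ``tensors`` may carry pre-computed preprocessed images (in record
    order) to avoid repeated disk reads.
    """
    labels = index.labels
    if tensors is None:
        tensors = load_tensors(index, pre_cfg)
    tensors = np.asarray(tensors, dtype=np.float64)

    ss = np.random.SeedSequence(train_cfg.seed)
    fold_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    fold_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(train_cfg.k_folds)
    ]
    assignment = make_folds(labels, train_cfg.k_folds, fold_seed,
                            stratified=train_cfg.stratified)

    fold_rows: list[dict] = []
    roc_points: dict[str, list[list[float]]] = {}
    predictions: list[dict] = []
    for fold_id, val_idx in enumerate(assignment.folds):
        val_idx = np.array(val_idx, dtype=int)
        train_idx = np.array(assignment.train_indices(fold_id), dtype=int)
        result = train_fold(
            (tensors[train_idx], labels[train_idx]),
            (tensors[val_idx], labels[val_idx]),
            model_cfg, train_cfg, aug_cfg,
            seed=fold_seeds[fold_id],
            fold_id=fold_id,
            record_ids=[index.records[i].image_id for i in val_idx],
        )
        row = {"fold": fold_id, "best_epoch": result.best_epoch}
        row.update(_metrics.evaluate_predictions(result.y_true, result.p_ak))
        fold_rows.append(row)
        pts, _ = _metrics.roc_auc(result.y_true, result.p_ak)
        roc_points[str(fold_id)] = pts.tolist()
        predictions.extend(
            {"record_id": rid, "fold": fold_id, "y": int(y), "p_ak": float(p)}
            for rid, y, p in zip(result.record_ids, result.y_true, result.p_ak)
        )
        logger.info("fold %d metrics: %s", fold_id,
                    {k: round(v, 4) for k, v in row.items() if k not in ("fold",)})

    summaries = {}
    for name in METRIC_NAMES:
        summary = _metrics.aggregate_folds([r[name] for r in fold_rows], name=name)
        summaries[name] = {
            "values": list(summary.values),
            "mean": summary.mean,
            "ci_half_width": summary.ci_half_width,
        }

    # canonicalize to JSON-native types so a report round-trips exactly
    config = json.loads(json.dumps({
        "preprocess": asdict(pre_cfg),
        "model": asdict(model_cfg),
        "train": asdict(train_cfg),
        "augment": asdict(aug_cfg),
    }, default=str))
    return RunReport(
        k=train_cfg.k_folds,
        fold_metrics=fold_rows,
        summaries=summaries,
        roc_points=roc_points,
        predictions=predictions,
        config=config,
        seeds={"train_seed": train_cfg.seed, "fold_seed": fold_seed,
               "fold_seeds": fold_seeds},
    )
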