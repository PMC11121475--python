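"""Training loop: Adam, cross-entropy, seeded shuffling, metric logging.

Default hyperparameters follow the study protocol: Adam at learning rate
0.005, batch size 170, 250 epochs with no early stopping, cross-entropy
loss.  An epoch is floor(n_train / batch_size) parameter updates — the
final partial batch is dropped, which is what makes 8372 training images
at batch 170 come out to 49 iterations per epoch.  Validation metrics are
recorded every epoch; both the across-epoch average and the final-epoch
values are reported.

Inputs are standardized with a single scalar mean and standard deviation
fitted on the training set only.  Raw magnitude spectra span several
orders of magnitude between the DC bin and the texture bins; one global
affine rescale brings them into the optimizer's working range while
preserving the relative dominance of the low-frequency bins, which is
where the injury signal lives.  (Per-pixel whitening would equalize every
bin's variance and bury that signal under the noise floor.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ArchitectureSpec
from .nn import Adam, Network, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "LeakageError",
    "TrainingDivergedError",
    "iterations_per_epoch",
    "train_model",
    "dataset_to_arrays",
]

LABEL_TO_INDEX = {"sprain": 0, "fracture": 1}  # fracture is the positive class


class LeakageError(RuntimeError):
    """Train and validation sets share a participant."""


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during optimization."""


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.005
    batch_size: int = 170
    max_epochs: int = 250
    loss: str = "cross_entropy"
    seed: int = 0
    standardize_inputs: bool = True

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainingLog:
    """Per-iteration training metrics and per-epoch validation metrics."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    iteration_epoch: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.train_loss)

    @property
    def final_val_accuracy(self) -> float:
        return self.val_accuracy[-1] if self.val_accuracy else float("nan")

    @property
    def mean_val_accuracy(self) -> float:
        """Across-epoch average of the validation accuracy."""
        return float(np.mean(self.val_accuracy)) if self.val_accuracy else float("nan")


def iterations_per_epoch(n_train_images: int, batch_size: int) -> int:
    """floor(n / batch); the final partial batch is dropped."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if n_train_images < 1:
        raise ValueError("n_train_images must be >= 1")
    return n_train_images // batch_size


def dataset_to_arrays(dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a spectrum-stage cohort into (images, labels, participant_ids)."""
    images, labels, pids = [], [], []
    for p in dataset:
        for item in p.items:
            images.append(item.magnitude)
            labels.append(LABEL_TO_INDEX[p.label])
            pids.append(p.participant_id)
    if not images:
        return np.zeros((0, 100, 100)), np.zeros(0, dtype=int), np.asarray(pids)
    return np.stack(images), np.asarray(labels, dtype=int), np.asarray(pids)


def _batch_eval(net: Network, images: np.ndarray, labels: np.ndarray,
                batch_size: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(images), batch_size):
        xb, yb = images[i : i + batch_size], labels[i : i + batch_size]
        logits = net.forward(xb, training=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(images)), correct / len(images)


def train_model(
    arch_or_net: ArchitectureSpec | Network,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray | None,
    val_labels: np.ndarray | None,
    config: TrainConfig,
    train_participants=None,
    val_participants=None,
) -> tuple[Network, TrainingLog]:
    """Run max_epochs x iterations_per_epoch seeded Adam updates.

    If participant id arrays are supplied for both subsets, any overlap
    refuses to train (participant-level leakage would invalidate every
    validation metric).  A non-finite loss aborts with a diagnostic.
    """
    if train_participants is not None and val_participants is not None:
        shared = set(np.asarray(train_participants)) & set(np.asarray(val_participants))
        if shared:
            raise LeakageError(
                f"participants present in both train and validation: {sorted(shared)}")

    net = arch_or_net if isinstance(arch_or_net, Network) else Network(arch_or_net, seed=config.seed)
    if config.standardize_inputs:
        net.set_input_standardization(train_images.mean(), train_images.std())

    n_iter = iterations_per_epoch(len(train_images), config.batch_size)
    if n_iter == 0:
        raise ValueError("batch_size exceeds the training-set size")
    optimizer = Adam(net.params(), learning_rate=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x5D]))
    log = TrainingLog()

    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(train_images))
        for it in range(n_iter):
            idx = order[it * config.batch_size : (it + 1) * config.batch_size]
            xb, yb = train_images[idx], train_labels[idx]
            logits = net.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}, iteration {it + 1}")
            net.backward(dlogits)
            optimizer.step()
            log.train_loss.append(loss)
            log.train_accuracy.append(float((logits.argmax(axis=1) == yb).mean()))
            log.iteration_epoch.append(epoch + 1)
        if val_images is not None and len(val_images):
            vloss, vacc = _batch_eval(net, val_images, val_labels)
            log.val_loss.append(vloss)
            log.val_accuracy.append(vacc)
    return net, log
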