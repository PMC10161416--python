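"""Stochastic augmentation scheduling and the pretrain/fine-tune protocol.

During pretraining every mini-batch sequence independently receives a
random subset of augmentations.  The number applied is either fixed
(``hard`` mode: always ``max_augs``) or uniform on ``{1, ..., max_augs}``
(``soft`` mode); the subset is drawn without replacement from the
configured augmentation set, and applied in a fixed priority order:

    inversion, deletion, translocation, insertion,
    reverse_complement, mutation, noise

Whenever insertion is in the set, sequences that did not draw an insertion
are 3'-padded with random DNA of length ``insert_max`` so the model always
sees a constant input length — at validation and test time the same 3'
padding (and no other augmentation) is applied via
:func:`pad_for_inference`.

Fine-tuning then continues training on unperturbed data at a reduced
learning rate to unlearn augmentation biases unsupported by the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import augment as A
from .nn import Adam, Network
from .nn.losses import loss_for_task
from .seqdata import LabeledDataset, random_one_hot

#: fixed application order for multi-augmentation compositions
PRIORITY = (
    "inversion",
    "deletion",
    "translocation",
    "insertion",
    "reverse_complement",
    "mutation",
    "noise",
)

ALL_AUGMENTATIONS = frozenset(PRIORITY)


@dataclass(frozen=True)
class CurriculumConfig:
    """Which augmentations to sample from, and how many per sequence."""

    aug_set: frozenset = frozenset(PRIORITY)
    settings: A.AugmentationSettings = field(default_factory=A.AugmentationSettings)
    max_augs: int = 1
    mode: str = "hard"  # "hard" | "soft"

    def __post_init__(self) -> None:
        object.__setattr__(self, "aug_set", frozenset(self.aug_set))
        unknown = self.aug_set - ALL_AUGMENTATIONS
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")
        if self.aug_set and self.max_augs > len(self.aug_set):
            raise ValueError(
                f"max_augs={self.max_augs} exceeds augmentation set size {len(self.aug_set)}"
            )
        if self.aug_set and self.max_augs < 1:
            raise ValueError("max_augs must be >= 1 when augmenting")
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"mode must be 'hard' or 'soft', got {self.mode!r}")

    @property
    def pads_inference(self) -> bool:
        return "insertion" in self.aug_set

    @property
    def length_increase(self) -> int:
        return self.settings.insert_max if self.pads_inference else 0


@dataclass
class OptimConfig:
    """Optimizer and schedule settings for one training stage."""

    stage: str = "pretrain"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-6
    max_epochs: int = 100
    early_stop_patience: int = 10
    lr_decay_factor: float = 0.1
    lr_decay_patience: int = 5
    batch_size: int = 128
    seed: int = 0

    @classmethod
    def pretrain_defaults(cls, **kwargs) -> "OptimConfig":
        return cls(stage="pretrain", **kwargs)

    @classmethod
    def finetune_defaults(cls, **kwargs) -> "OptimConfig":
        defaults = dict(
            stage="finetune",
            learning_rate=1e-4,
            max_epochs=5,
            early_stop_patience=5,
        )
        defaults.update(kwargs)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Scheduling
# ---------------------------------------------------------------------------

def sample_augmentation_subset(
    config: CurriculumConfig, rng: np.random.Generator
) -> list[str]:
    """Draw the priority-ordered augmentation subset for one sequence."""
    names = sorted(config.aug_set)
    if not names:
        return []
    if config.mode == "hard":
        k = config.max_augs
    else:
        k = int(rng.integers(1, config.max_augs + 1))
    chosen = rng.choice(len(names), size=k, replace=False)
    drawn = {names[i] for i in chosen}
    return [name for name in PRIORITY if name in drawn]


def _apply_augmentation(
    name: str, x: np.ndarray, s: A.AugmentationSettings, rng: np.random.Generator
) -> np.ndarray:
    if name == "inversion":
        return A.invert(x, s.invert_min, s.invert_max, rng)
    if name == "deletion":
        return A.delete(x, s.delete_min, s.delete_max, rng)
    if name == "translocation":
        return A.translocate(x, s.shift_min, s.shift_max, rng)
    if name == "insertion":
        return A.insert(x, s.insert_min, s.insert_max, rng)
    if name == "reverse_complement":
        return A.reverse_complement(x, s.rc_prob, rng)
    if name == "mutation":
        return A.mutate(x, s.mutate_frac, rng)
    if name == "noise":
        return A.add_noise(x, s.noise_mean, s.noise_std, rng)
    raise ValueError(f"unknown augmentation {name!r}")


def augment_sequence(
    x: np.ndarray, config: CurriculumConfig, rng: np.random.Generator
) -> np.ndarray:
    """Augment one sequence with an independently sampled ordered subset.

    If insertion belongs to the configured set but was not drawn for this
    sequence, the output is 3'-padded with random DNA of length
    ``insert_max`` so every sequence in a batch has the same length.
    """
    names = sample_augmentation_subset(config, rng)
    out = x
    for name in names:
        out = _apply_augmentation(name, out, config.settings, rng)
    if config.pads_inference and "insertion" not in names:
        pad = random_one_hot(rng, config.settings.insert_max)
        out = np.concatenate([out, pad.astype(out.dtype)], axis=0)
    return out


def augment_batch(
    x: np.ndarray, config: CurriculumConfig, rng: np.random.Generator
) -> np.ndarray:
    """Independently augment every sequence of a ``(B, L, 4)`` batch.

    Labels are untouched by construction — augmented sequences keep the
    wild-type labels.  Each record draws from its own spawned RNG stream,
    so results do not depend on batch-internal evaluation order.
    """
    x = np.asarray(x)
    if x.ndim != 3 or x.shape[2] != 4:
        raise ValueError(f"expected a (B, L, 4) batch, got shape {x.shape}")
    if not config.aug_set:
        return x.copy()
    streams = rng.spawn(x.shape[0])
    out = [augment_sequence(x[i], config, streams[i]) for i in range(x.shape[0])]
    return np.stack(out)


def pad_for_inference(
    x: np.ndarray, insert_max: int, rng: np.random.Generator
) -> np.ndarray:
    """3'-pad sequences with random DNA of length ``insert_max``.

    Applied at validation/test time for models trained with the insertion
    augmentation; no other augmentation is used at evaluation.  Accepts a
    single ``(L, 4)`` sequence or a ``(B, L, 4)`` batch; the original rows
    are preserved as a prefix.
    """
    x = np.asarray(x)
    if insert_max == 0:
        return x.copy()
    if x.ndim == 2:
        pad = random_one_hot(rng, insert_max)
        return np.concatenate([x, pad.astype(x.dtype)], axis=0)
    pad = random_one_hot(rng, x.shape[0] * insert_max).reshape(x.shape[0], insert_max, 4)
    return np.concatenate([x, pad.astype(x.dtype)], axis=1)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _PatienceCounter:
    """Tracks epochs since the last strict improvement in validation loss."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.count = 0

    def update(self, loss: float) -> bool:
        """Record an epoch loss; return True when patience is exhausted."""
        if loss < self.best:
            self.best = loss
            self.count = 0
            return False
        self.count += 1
        return self.count >= self.patience


def _expected_input_length(dataset: LabeledDataset, pad: int) -> int:
    return dataset.length + pad


def _validate_shapes(model: Network, dataset: LabeledDataset, pad: int) -> None:
    expected = _expected_input_length(dataset, pad)
    probe = np.zeros((1, expected, 4))
    try:
        out = model.forward(probe)
    except ValueError as exc:
        raise ValueError(
            f"model incompatible with padded input length {expected}: {exc}"
        ) from None
    if out.shape[1] != dataset.n_tasks:
        raise ValueError(
            f"model produces {out.shape[1]} outputs but dataset has {dataset.n_tasks} tasks"
        )


def _evaluate_loss(model, x, y, loss_fn, batch_size=256) -> float:
    total, count = 0.0, 0
    for i in range(0, len(x), batch_size):
        pred = model.forward(x[i : i + batch_size])
        loss, _ = loss_fn(pred, y[i : i + batch_size])
        total += loss * len(pred)
        count += len(pred)
    return total / max(count, 1)


def _train(
    model: Network,
    dataset: LabeledDataset,
    curriculum: CurriculumConfig | None,
    optim: OptimConfig,
) -> tuple[Network, pd.DataFrame]:
    pad = curriculum.length_increase if curriculum is not None else 0
    _validate_shapes(model, dataset, pad)
    loss_fn = loss_for_task(dataset.task_kind)
    x_train, y_train = dataset.split("train")
    x_valid, y_valid = dataset.split("valid")

    root = np.random.SeedSequence(optim.seed)
    pad_rng = np.random.default_rng(root.spawn(1)[0])
    if pad:
        x_valid = pad_for_inference(x_valid, pad, pad_rng)
    opt = Adam(model.params, lr=optim.learning_rate, weight_decay=optim.weight_decay)
    early = _PatienceCounter(optim.early_stop_patience)
    decay = _PatienceCounter(optim.lr_decay_patience)

    best_state = model.get_state()
    best_loss = np.inf
    rows: list[dict] = []
    n = len(x_train)
    for epoch in range(optim.max_epochs):
        epoch_ss = np.random.SeedSequence(entropy=(optim.seed, epoch))
        shuffle_rng = np.random.default_rng(epoch_ss.spawn(1)[0])
        order = shuffle_rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for bi, start in enumerate(range(0, n, optim.batch_size)):
            idx = order[start : start + optim.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            if curriculum is not None and curriculum.aug_set:
                batch_rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=(optim.seed, epoch, bi))
                )
                xb = augment_batch(xb, curriculum, batch_rng)
            elif pad:
                xb = pad_for_inference(xb, pad, pad_rng)
            pred = model.forward(xb, train=True)
            loss, grad = loss_fn(pred, yb)
            model.backward(grad)
            opt.step(model.grads)
            epoch_loss += loss * len(idx)
            seen += len(idx)
        train_loss = epoch_loss / max(seen, 1)
        valid_loss = _evaluate_loss(model, x_valid, y_valid, loss_fn)
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "valid_loss": valid_loss, "lr": opt.lr}
        )
        if valid_loss < best_loss:
            best_loss = valid_loss
            best_state = model.get_state()
        if decay.update(valid_loss):
            opt.lr *= optim.lr_decay_factor
            decay.count = 0
        if early.update(valid_loss):
            break
    model.set_state(best_state)
    return model, pd.DataFrame(rows, columns=["epoch", "train_loss", "valid_loss", "lr"])


def pretrain(
    model: Network,
    dataset: LabeledDataset,
    curriculum: CurriculumConfig,
    optim: OptimConfig | None = None,
) -> tuple[Network, pd.DataFrame]:
    """Train with online augmentations; return the min-validation-loss model.

    Augmentations are applied to training batches only; validation uses
    inference padding (when insertion is configured) and no augmentation.
    Early stopping and learning-rate decay run on independent patience
    counters over the epoch-mean validation loss.
    """
    if optim is None:
        optim = OptimConfig.pretrain_defaults()
    return _train(model, dataset, curriculum, optim)


def finetune(
    model: Network,
    dataset: LabeledDataset,
    optim: OptimConfig | None = None,
    padded: bool = False,
    insert_max: int = 0,
) -> tuple[Network, pd.DataFrame]:
    """Continue training on unperturbed data at a reduced learning rate.

    ``padded=True`` keeps the 3' inference padding for models whose input
    layer expects ``L + insert_max`` (trained with insertion augmentation).
    """
    if optim is None:
        optim = OptimConfig.finetune_defaults()
    curriculum = _PadOnly(insert_max) if padded else None
    return _train(model, dataset, curriculum, optim)


class _PadOnly:
    """Curriculum stand-in that applies only inference padding, no augmentation."""

    def __init__(self, pad: int):
        self.aug_set = frozenset()
        self.length_increase = pad


def evaluate(model: Network, dataset: LabeledDataset, split: str = "test",
             insert_max: int = 0, seed: int = 0) -> dict[str, float]:
    """Task-averaged evaluation metrics on one split.

    Binary tasks report AUROC and AUPR; regression tasks report Pearson r
    and mean squared error, averaged over tasks.
    """
    from scipy.stats import pearsonr
    from sklearn.metrics import average_precision_score, roc_auc_score

    x, y = dataset.split(split)
    if insert_max:
        x = pad_for_inference(x, insert_max, np.random.default_rng(seed))
    pred = model.predict(x)
    out: dict[str, float] = {}
    if dataset.task_kind == "binary":
        aurocs = [roc_auc_score(y[:, t], pred[:, t]) for t in range(y.shape[1])]
        auprs = [average_precision_score(y[:, t], pred[:, t]) for t in range(y.shape[1])]
        out["auroc"] = float(np.mean(aurocs))
        out["aupr"] = float(np.mean(auprs))
    else:
        rs = [pearsonr(y[:, t], pred[:, t]).statistic for t in range(y.shape[1])]
        out["pearson_r"] = float(np.mean(rs))
        out["mse"] = float(np.mean((pred - y) ** 2))
    return out
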