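"""Training loops for the universal and personalized saliency models.

Stage defaults follow the study design: the universal stage uses Adam
(learning rate 1e-5) with batch size 32; the personalized stage uses AdamW
(learning rate 1e-6, decoupled weight decay 0.05) with batch size 1 and
each image replicated eight times per epoch.  Both stages stop early when
the validation loss fails to improve for ``patience`` (default 5)
consecutive validation evaluations (one per epoch), and the returned
checkpoint holds the weights at the minimum validation loss.

Personalized training is initialized by transferring a trained universal
model's encoder and decoder weights (``transfer_init``); the user-encoding
mechanism keeps its fresh initialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .model import PsmModel, UsmModel
from .nn import Adam, AdamW

__all__ = [
    "TrainConfig",
    "EarlyStopState",
    "TrainResult",
    "mse_loss",
    "split_dataset",
    "early_stop_update",
    "transfer_init",
    "train_stage",
]


@dataclass
class TrainConfig:
    stage: str = "USM"  # "USM" | "PSM"
    optimizer: str = ""  # default by stage: USM -> adam, PSM -> adamw
    learning_rate: float = 0.0  # default by stage: 1e-5 / 1e-6
    weight_decay: float = 0.05  # PSM stage only
    batch_size: int = 0  # default by stage: 32 / 1
    patience: int = 5
    replicate_per_image: int = 8  # PSM stage: passes over each sample per epoch
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.stage not in ("USM", "PSM"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.patience < 1 or (self.batch_size and self.batch_size < 1):
            raise ValueError("patience and batch_size must be >= 1")
        if not self.optimizer:
            self.optimizer = "adam" if self.stage == "USM" else "adamw"
        if not self.learning_rate:
            self.learning_rate = 1e-5 if self.stage == "USM" else 1e-6
        if not self.batch_size:
            self.batch_size = 32 if self.stage == "USM" else 1


@dataclass
class EarlyStopState:
    best_val: float = np.inf
    epochs_since_improve: int = 0


@dataclass
class TrainResult:
    """Outcome of one training stage."""

    best_state: dict  # weights at minimum validation loss
    loss_curve: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_val: float
    epochs_run: int
    best_epoch: int

    def save_curve(self, path) -> None:
        self.loss_curve.to_csv(path, index=False)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error between a predicted map and a target array."""
    target = np.asarray(target, dtype=float)
    if tuple(pred.shape) != target.shape:
        raise ValueError(f"shape mismatch: {tuple(pred.shape)} vs {target.shape}")
    diff = pred - Tensor(target)
    return diff.square().mean()


def split_dataset(
    samples: Sequence,
    train_frac: float = 0.8,
    labels: Sequence[int] | None = None,
    subjects: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[list, list]:
    """Deterministic train/validation split with per-subject stratification.

    When ``subjects`` and binary ``labels`` are given, positives and
    negatives are split separately inside every subject, so the number of
    1-labelled samples each subject contributes to training is as uniform
    as rounding permits.  Without them the split is a plain shuffled cut.
    """
    n = len(samples)
    rng = np.random.default_rng(seed)
    if subjects is None or labels is None:
        idx = rng.permutation(n)
        k = int(round(n * train_frac))
        return [samples[i] for i in idx[:k]], [samples[i] for i in idx[k:]]

    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for subj in pd.unique(subjects):
        for lab in (1, 0):
            pool = np.flatnonzero((subjects == subj) & (labels == lab))
            pool = rng.permutation(pool)
            k = int(round(len(pool) * train_frac))
            train_idx.extend(pool[:k])
            val_idx.extend(pool[k:])
    return [samples[i] for i in train_idx], [samples[i] for i in val_idx]


def early_stop_update(
    state: EarlyStopState, val_loss: float, patience: int
) -> tuple[EarlyStopState, bool]:
    """Advance the early-stopping counter; improvement resets it."""
    if val_loss < state.best_val:
        return EarlyStopState(best_val=val_loss, epochs_since_improve=0), False
    count = state.epochs_since_improve + 1
    return (
        EarlyStopState(best_val=state.best_val, epochs_since_improve=count),
        count >= patience,
    )


def transfer_init(psm_model: PsmModel, usm_model: UsmModel) -> PsmModel:
    """Copy a trained universal model's encoder/decoder into a PSM model.

    The user-encoding mechanism keeps its fresh initialization, and nothing
    is frozen — the transferred weights continue to train.
    """
    src = usm_model.named_parameters()
    dst = psm_model.named_parameters()
    shared = [k for k in dst if k.startswith(("encoder.", "decoder."))]
    bad = [
        k for k in shared
        if k not in src or src[k].data.shape != dst[k].data.shape
    ]
    if bad:
        raise ValueError(f"encoder/decoder shape mismatch for layers: {bad}")
    for k in shared:
        dst[k].data = src[k].data.copy()
    return psm_model


def _forward(model, sample) -> Tensor:
    if isinstance(model, PsmModel):
        image, interest, target = sample
        pred = model.forward(image, interest)
    else:
        image, target = sample
        pred = model.forward(image)
    return mse_loss(pred, target)


def evaluate_loss(model, data: Sequence) -> float:
    """Mean per-sample MSE over a dataset (no gradients kept)."""
    losses = [float(_forward(model, s).data) for s in data]
    return float(np.mean(losses))


def train_stage(
    train_data: Sequence,
    val_data: Sequence,
    model,
    config: TrainConfig,
    callback: Callable[[int, float, float], None] | None = None,
) -> TrainResult:
    """Run one training stage with early stopping.

    ``train_data``/``val_data`` hold ``(image, target_map)`` samples for the
    universal stage or ``(image, interest_vector, target_map)`` for the
    personalized stage.  Gradients are averaged over each mini-batch by
    accumulation; validation runs once per epoch and the best-validation
    weights are kept.  A NaN loss aborts with a diagnostic.
    """
    if not len(train_data):
        raise ValueError("training data is empty")
    params = model.parameters()
    if config.optimizer == "adamw":
        opt = AdamW(params, config.learning_rate, weight_decay=config.weight_decay)
    elif config.optimizer == "adam":
        opt = Adam(params, config.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    rng = np.random.default_rng(config.seed)
    state = EarlyStopState()
    best_state = model.state_dict()
    best_epoch = 0
    rows = []
    replicate = config.replicate_per_image if config.stage == "PSM" else 1

    for epoch in range(1, config.max_epochs + 1):
        order = np.concatenate(
            [rng.permutation(len(train_data)) for _ in range(replicate)]
        )
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            model.zero_grad()
            batch_loss = 0.0
            for i in batch:
                loss = _forward(model, train_data[i]) * (1.0 / len(batch))
                loss.backward()
                batch_loss += float(loss.data) * len(batch)
            batch_loss /= len(batch)
            if np.isnan(batch_loss):
                raise FloatingPointError(
                    f"training diverged (NaN loss) at epoch {epoch}"
                )
            opt.step()
            epoch_losses.append(batch_loss)

        train_loss = float(np.mean(epoch_losses))
        val_loss = evaluate_loss(model, val_data) if len(val_data) else train_loss
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if callback is not None:
            callback(epoch, train_loss, val_loss)
        improved = val_loss < state.best_val
        state, stop = early_stop_update(state, val_loss, config.patience)
        if improved:
            best_state = model.state_dict()
            best_epoch = epoch
        if stop:
            break

    model.load_state_dict(best_state)
    return TrainResult(
        best_state=best_state,
        loss_curve=pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"]),
        best_val=state.best_val,
        epochs_run=len(rows),
        best_epoch=best_epoch,
    )
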