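"""Optimization loop: Nesterov-Adam on the soft Jaccard loss with a linearly
decaying learning rate and tournament selection over random initializations.

Eight networks (by default) are initialized with independent random
weights and trained in parallel schedule; at epochs 20/40/80 the half with
the worst validation score is dropped (8 -> 4 -> 2 -> 1).  The survivor
then trains until its validation loss stops improving (early stopping with
patience — "until convergence" given an explicit criterion).  The learning
rate decays linearly from 1e-2 to 1e-5 over the planned epochs and stays
at the floor afterwards.

Back-propagation minimizes the soft Jaccard loss (unweighted mean over
organ channels); validation ranking uses the Dice loss of the binarized
full-image prediction.  Each network draws its training patches from its
own seeded sampler stream, so runs are bit-reproducible from the
configuration seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import nn
from .core_io import ImageGrid, StructureSet
from .sampling import SamplerConfig, composite_sampler

__all__ = [
    "TrainConfig",
    "TrainState",
    "TrainingDiverged",
    "lr_at_epoch",
    "train_step",
    "fit",
    "tournament_select",
    "run_tournament_schedule",
    "tournament_train",
    "normalize_intensity",
    "recalibrate_batchnorm",
    "validation_dice_loss",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    lr_initial: float = 1e-2
    lr_final: float = 1e-5
    planned_epochs: int = 120
    tournament_schedule: tuple[tuple[int, int], ...] = ((20, 4), (40, 2), (80, 1))
    n_initializations: int = 8
    patch_size: tuple[int, int, int] = (32, 32, 16)
    batch_size: int = 2
    steps_per_epoch: int = 50
    patience: int = 10
    intensity_window: tuple[float, float] = (-1024.0, 1024.0)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    organs: tuple[str, ...] = ("left_breast", "right_breast", "heart")
    seed: int = 0

    def __post_init__(self):
        if not (self.lr_initial > self.lr_final > 0):
            raise ValueError("need lr_initial > lr_final > 0")
        if self.planned_epochs < 1 or self.n_initializations < 1:
            raise ValueError("planned_epochs and n_initializations must be >= 1")
        if self.tournament_schedule:
            epochs = [e for e, _ in self.tournament_schedule]
            survivors = [s for _, s in self.tournament_schedule]
            if epochs != sorted(set(epochs)):
                raise ValueError("tournament epochs must be strictly increasing")
            counts = [self.n_initializations] + survivors
            if any(b >= a for a, b in zip(counts, counts[1:])) or survivors[-1] != 1:
                raise ValueError(
                    "tournament survivors must be strictly decreasing and end at 1"
                )
        object.__setattr__(self, "sampler",
                           replace(self.sampler, patch_size=self.patch_size))


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Linear decay from ``lr_initial`` (epoch 0) to ``lr_final`` (epoch E-1)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    E = cfg.planned_epochs
    if E == 1:
        return cfg.lr_final
    frac = min(epoch, E - 1) / (E - 1)
    return cfg.lr_initial + (cfg.lr_final - cfg.lr_initial) * frac


def normalize_intensity(values: np.ndarray,
                        window: tuple[float, float] = (-1024.0, 1024.0)) -> np.ndarray:
    """Window and scale intensities to [0, 1] float32 network inputs."""
    lo, hi = window
    return ((np.clip(np.asarray(values, dtype=np.float32), lo, hi) - lo)
            / np.float32(hi - lo)).astype(np.float32)


def train_step(
    net: nn.Module,
    batch: tuple[np.ndarray, np.ndarray],
    optimizer: nn.NesterovAdam,
    lr: float,
) -> float:
    """One Nesterov-Adam update on the soft Jaccard loss; returns the loss."""
    x, y = batch
    optimizer.zero_grad()
    pred = net(nn.Tensor(x))
    loss = nn.soft_jaccard_loss(pred, y)
    if not np.isfinite(loss.data):
        raise TrainingDiverged(f"non-finite training loss {loss.data!r}")
    loss.backward()
    optimizer.step(lr)
    return float(loss.data)


def tournament_select(losses: Mapping[str, float], survivors: int) -> list[str]:
    """Keep the ``survivors`` entries with lowest loss (ties: smaller id)."""
    if survivors < 1 or survivors > len(losses):
        raise ValueError(f"cannot keep {survivors} of {len(losses)} networks")
    ranked = sorted(losses.items(), key=lambda kv: (kv[1], kv[0]))
    return [k for k, _ in ranked[:survivors]]


def run_tournament_schedule(
    traces: Mapping[str, Sequence[float]],
    schedule: Sequence[tuple[int, int]],
) -> dict[int, list[str]]:
    """Apply the drop schedule to per-network validation-loss traces.

    ``traces[net_id][e]`` is the validation loss after epoch ``e+1``.  At
    each scheduled epoch the current survivors are ranked by that epoch's
    loss and cut down; returns the surviving id list per scheduled epoch.
    """
    alive = sorted(traces)
    out: dict[int, list[str]] = {}
    for epoch, keep in schedule:
        losses = {k: traces[k][epoch - 1] for k in alive}
        alive = tournament_select(losses, keep)
        out[epoch] = list(alive)
    return out


@dataclass
class TrainState:
    epoch: int = 0
    history: dict[str, list[float]] = field(default_factory=dict)  # val-loss per net
    survivors: list[str] = field(default_factory=list)
    best_id: str | None = None
    best_loss: float = float("inf")
    best_checkpoint: dict[str, np.ndarray] | None = None


def validation_dice_loss(
    net: nn.Module,
    cases: Sequence[tuple[ImageGrid, StructureSet]],
    organs: Sequence[str],
    window: tuple[float, float],
) -> float:
    """Mean Dice loss of binarized full-image predictions over a cohort.

    Batch norm uses the statistics of the evaluated volume itself (dropout
    stays off), so mid-training validation is deterministic and unaffected
    by the patch-vs-volume statistics gap; the final model's running
    statistics are fixed separately by :func:`recalibrate_batchnorm`.
    An empty prediction for a nonempty reference scores the worst possible
    Dice loss of 1, so failing networks rank last rather than crash.
    """
    from .metrics import dice_coefficient

    net.train()
    dropouts = [m for m in net.modules() if isinstance(m, nn.Dropout)]
    bns = [m for m in net.modules() if isinstance(m, nn.BatchNorm3d)]
    saved = [(m.running_mean.copy(), m.running_var.copy()) for m in bns]
    for m in dropouts:
        object.__setattr__(m, "training", False)
    losses = []
    for image, structures in cases:
        x = normalize_intensity(image.values, window)[None, None]
        pred = net(nn.Tensor(x)).data[0]
        for c, organ in enumerate(organs):
            hard = (pred[c] >= 0.5).astype(np.uint8)
            d = dice_coefficient(hard, structures[organ].values)
            losses.append(1.0 if np.isnan(d) else 1.0 - d)
    for m, (rm, rv) in zip(bns, saved):
        m._buffers["running_mean"][:] = rm
        m._buffers["running_var"][:] = rv
    net.train()
    return float(np.mean(losses))


def recalibrate_batchnorm(
    net: nn.Module,
    volumes: Sequence[np.ndarray],
    window: tuple[float, float] = (-1024.0, 1024.0),
) -> None:
    """Re-estimate batch-norm running statistics on full volumes.

    Training on sampled patches biases the running mean/variance toward
    patch statistics, which differ from whole-volume statistics (patches
    over-represent organs, volumes are mostly air).  This runs forward
    passes in training mode with cumulative-average momentum so the
    running statistics become the exact average of the per-volume batch
    statistics, then returns the network in evaluation mode.
    """
    bns = [m for m in net.modules() if isinstance(m, nn.BatchNorm3d)]
    for m in bns:
        m._buffers["running_mean"][:] = 0.0
        m._buffers["running_var"][:] = 1.0
    net.train()
    for i, vol in enumerate(volumes):
        for m in bns:
            m.momentum = 1.0 / (i + 1)
        net(nn.Tensor(normalize_intensity(vol, window)[None, None]))
    for m in bns:
        m.momentum = 0.1
    net.eval()


def _epoch_of_training(
    net: nn.Module,
    optimizer: nn.NesterovAdam,
    stream_state: dict,
    cases: Sequence[tuple[ImageGrid, StructureSet]],
    cfg: TrainConfig,
    lr: float,
) -> float:
    """Run ``steps_per_epoch`` patch-batch updates; returns mean train loss."""
    rng: np.random.Generator = stream_state["rng"]
    samplers = stream_state["samplers"]
    losses = []
    for _ in range(cfg.steps_per_epoch):
        xs, ys = [], []
        for _ in range(cfg.batch_size):
            ci = int(rng.integers(0, len(cases)))
            patch, label = next(samplers[ci])
            xs.append(normalize_intensity(patch.values, cfg.intensity_window)[None])
            ys.append(label)
        batch = (np.stack(xs), np.stack(ys))
        losses.append(train_step(net, batch, optimizer, lr))
    return float(np.mean(losses))


def fit(
    net: nn.Module,
    cases: Sequence[tuple[ImageGrid, StructureSet]],
    cfg: TrainConfig,
    n_epochs: int,
    full_volume_final_epochs: int = 1,
) -> list[float]:
    """Train a single network; the final epochs use whole volumes.

    The patch-sampled epochs learn the organ appearance cheaply; the
    full-volume epochs at the tail align border behaviour and batch-norm
    statistics with full-image inference, and a final statistics
    recalibration pass fixes the running estimates.  Returns the per-epoch
    mean training losses and leaves the network in evaluation mode.
    """
    if not cases:
        raise ValueError("training cohort must be nonempty")
    optimizer = nn.NesterovAdam(net.parameters(), lr=cfg.lr_initial)
    srng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 17]))
    samplers = [
        composite_sampler(img, st, cfg.sampler, srng, organs=cfg.organs)
        for img, st in cases
    ]
    stacked = [st.stacked(list(cfg.organs)) for _, st in cases]
    net.train()
    losses = []
    for epoch in range(n_epochs):
        lr = lr_at_epoch(cfg, epoch)
        epoch_losses = []
        full = epoch >= n_epochs - full_volume_final_epochs
        for _ in range(cfg.steps_per_epoch):
            if full:
                ci = int(srng.integers(0, len(cases)))
                x = normalize_intensity(cases[ci][0].values, cfg.intensity_window)
                batch = (x[None, None], stacked[ci][None])
            else:
                xs, ys = [], []
                for _ in range(cfg.batch_size):
                    ci = int(srng.integers(0, len(cases)))
                    patch, label = next(samplers[ci])
                    xs.append(normalize_intensity(patch.values, cfg.intensity_window)[None])
                    ys.append(label)
                batch = (np.stack(xs), np.stack(ys))
            epoch_losses.append(train_step(net, batch, optimizer, lr))
        losses.append(float(np.mean(epoch_losses)))
    recalibrate_batchnorm(net, [img.values for img, _ in cases], cfg.intensity_window)
    return losses


def tournament_train(
    model_factory: Callable[[int], nn.Module],
    train_cases: Sequence[tuple[ImageGrid, StructureSet]],
    val_cases: Sequence[tuple[ImageGrid, StructureSet]],
    cfg: TrainConfig,
    log_path: str | Path | None = None,
) -> tuple[nn.Module, TrainState]:
    """Train ``n_initializations`` networks under the drop schedule.

    ``model_factory(seed)`` must return a freshly initialized network.
    Returns the best-checkpoint survivor and the final :class:`TrainState`.
    """
    if not train_cases or not val_cases:
        raise ValueError("training and validation cohorts must be nonempty")
    schedule = list(cfg.tournament_schedule)
    if schedule and schedule[0][1] > cfg.n_initializations:
        raise ValueError("schedule inconsistent with population size")

    root = np.random.SeedSequence([int(cfg.seed), 11])
    net_seeds = np.random.default_rng(root).integers(0, 2**31 - 1, cfg.n_initializations)
    nets: dict[str, nn.Module] = {}
    opts: dict[str, nn.NesterovAdam] = {}
    streams: dict[str, dict] = {}
    for i, s in enumerate(net_seeds):
        nid = f"net_{i}"
        net = model_factory(int(s))
        nets[nid] = net
        opts[nid] = nn.NesterovAdam(net.parameters(), lr=cfg.lr_initial)
        srng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 13, i]))
        samplers = [
            composite_sampler(img, st, cfg.sampler, srng, organs=cfg.organs)
            for img, st in train_cases
        ]
        streams[nid] = {"rng": srng, "samplers": samplers}

    state = TrainState(history={nid: [] for nid in nets}, survivors=sorted(nets))
    drop_at = dict(schedule)
    last_drop = max(drop_at) if drop_at else 0
    log_rows = []
    epochs_since_best = 0

    for epoch in range(1, cfg.planned_epochs + 1):
        lr = lr_at_epoch(cfg, epoch - 1)
        for nid in state.survivors:
            train_loss = _epoch_of_training(
                nets[nid], opts[nid], streams[nid], train_cases, cfg, lr
            )
            val_loss = validation_dice_loss(
                nets[nid], val_cases, cfg.organs, cfg.intensity_window
            )
            state.history[nid].append(val_loss)
            log_rows.append((epoch, nid, train_loss, val_loss, lr))
            if val_loss < state.best_loss:
                state.best_loss = val_loss
                state.best_id = nid
                state.best_checkpoint = {
                    k: v.copy() for k, v in nets[nid].state_dict().items()
                }
                epochs_since_best = 0
        state.epoch = epoch
        if epoch in drop_at:
            losses = {nid: state.history[nid][-1] for nid in state.survivors}
            state.survivors = tournament_select(losses, drop_at[epoch])
        if epoch > last_drop:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                break

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "network", "train_loss", "val_loss", "lr"])
            writer.writerows(log_rows)

    winner_id = state.best_id if state.best_id in state.survivors else state.survivors[0]
    winner = nets[winner_id]
    if state.best_checkpoint is not None and state.best_id == winner_id:
        winner.load_state_dict(state.best_checkpoint)
    recalibrate_batchnorm(
        winner, [img.values for img, _ in train_cases], cfg.intensity_window
    )
    return winner, state
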