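"""Two-phase training: teacher pretraining, then student distillation.

The teacher is optimized on (noisy, clean) patch pairs with the composite
objective minus the distillation term; it is then frozen and the student is
trained with the full PSNR-normalized objective, matching the teacher's
outputs (soft labels) in addition to the ground truth.  Both phases use
Adam (lr 5e-4, batch 32 by default), validate each epoch, reduce the
learning rate when validation PSNR plateaus, and checkpoint the best
validation-PSNR weights.  Everything is seeded and single-threaded, so a
given configuration reproduces bit-identical logs.

An ablation harness re-runs the student phase over a grid of loss
formulations × learning-rate policies, or over (distillation weight,
temperature) pairs, and reports test-partition PSNR/SSIM/RMSE per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Sequence

import numpy as np

from . import metrics
from .losses import LossBreakdown, LossWeights, teacher_loss, total_loss
from .models import (
    NetworkHandle, StudentSpec, TeacherSpec, build_student, build_teacher,
)
from .nn import Adam, Tensor, no_grad
from .simulation import DatasetSplit, PatchPair, replicate_channels


# ---------------------------------------------------------------------------
# Learning-rate plateau policy
# ---------------------------------------------------------------------------

@dataclass
class PlateauPolicy:
    """Reduce-on-plateau rule for the monitored validation metric."""

    monitor: str = "val_psnr"
    patience: int = 5
    factor: float = 0.5
    min_lr: float = 1e-6
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not (0 < self.factor < 1):
            raise ValueError("factor must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def plateau_step(history: Sequence[float], policy: PlateauPolicy,
                 current_lr: float) -> float:
    """One scheduler decision given the monitored history so far.

    If the best value seen before the last ``patience`` epochs has not been
    strictly improved upon (beyond ``tol``) within those epochs, the
    learning rate is multiplied by ``factor`` (floored at ``min_lr``).
    """
    if len(history) == 0:
        raise ValueError("history must be nonempty")
    if current_lr <= 0:
        raise ValueError("current_lr must be positive")
    if len(history) <= policy.patience:
        return current_lr
    recent = max(history[-policy.patience:])
    earlier = max(history[:-policy.patience])
    if recent <= earlier + policy.tol:
        return max(current_lr * policy.factor, policy.min_lr)
    return current_lr


class PlateauScheduler:
    """Stateful plateau scheduler: counts non-improving epochs, resets on
    reduction, so a flat history triggers exactly one cut per patience
    window."""

    def __init__(self, policy: PlateauPolicy, lr: float):
        self.policy = policy
        self.lr = lr
        self.best = -np.inf
        self.bad_epochs = 0

    def update(self, value: float) -> tuple[float, bool]:
        reduced = False
        if value > self.best + self.policy.tol:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.policy.patience:
                new_lr = max(self.lr * self.policy.factor, self.policy.min_lr)
                reduced = new_lr < self.lr
                self.lr = new_lr
                self.bad_epochs = 0
        return self.lr, reduced


# ---------------------------------------------------------------------------
# Configuration and logs
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimizer, schedule and loss settings for one training phase."""

    lr_init: float = 5e-4
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    loss: LossWeights = field(default_factory=LossWeights)
    plateau: PlateauPolicy = field(default_factory=PlateauPolicy)
    lr_policy: str = "plateau"            # "plateau" | "exponential"
    exp_decay: float = 0.96               # per 10 epochs, for the fixed schedule
    peak: float = 1.0
    max_steps: int | None = None
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.lr_policy not in ("plateau", "exponential"):
            raise ValueError("lr_policy must be 'plateau' or 'exponential'")


@dataclass
class TrainingLog:
    """Per-epoch records plus a wall of events (lr cuts, checkpoints)."""

    records: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)

    @property
    def train_losses(self) -> list[float]:
        return [r["train_loss"] for r in self.records]

    @property
    def val_psnrs(self) -> list[float]:
        return [r["val_psnr"] for r in self.records]


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def stack_pairs(pairs: Sequence[PatchPair], channels: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Stack patch pairs into channels-last (N, H, W, C) float32 arrays."""
    if not pairs:
        raise ValueError("empty patch-pair sequence")
    def to_hwc(img: np.ndarray) -> np.ndarray:
        img = replicate_channels(img, channels)
        return img[:, :, None] if img.ndim == 2 else img
    clean = np.stack([to_hwc(p.clean) for p in pairs]).astype(np.float32)
    noisy = np.stack([to_hwc(p.noisy) for p in pairs]).astype(np.float32)
    return clean, noisy


def _predict_batched(handle: NetworkHandle, x: np.ndarray,
                     batch_size: int) -> np.ndarray:
    """Inference over (N, C, H, W) input in batches."""
    outs = []
    handle.module.eval()
    with no_grad():
        for i in range(0, x.shape[0], batch_size):
            outs.append(handle.module(Tensor(x[i:i + batch_size])).data)
    return np.concatenate(outs, axis=0)


def _val_metrics(handle: NetworkHandle, clean: np.ndarray, noisy: np.ndarray,
                 batch_size: int, peak: float) -> dict:
    pred = _predict_batched(handle, noisy, batch_size)
    psnrs = [metrics.psnr(c, p, peak=peak) for c, p in zip(clean, pred)]
    ssims = [metrics.ssim(c, p) for c, p in zip(clean, pred)]
    rmses = [metrics.rmse(c, p) for c, p in zip(clean, pred)]
    return {"val_psnr": float(np.mean(psnrs)),
            "val_ssim": float(np.mean(ssims)),
            "val_rmse": float(np.mean(rmses))}


# ---------------------------------------------------------------------------
# Core loop
# ---------------------------------------------------------------------------

def _run_training(handle: NetworkHandle, data: DatasetSplit, cfg: TrainingConfig,
                  batch_loss: Callable[[Tensor, Tensor, np.ndarray], LossBreakdown]
                  ) -> TrainingLog:
    """Shared epoch loop: optimize, validate, schedule, checkpoint."""
    if not data.train or not data.val:
        raise ValueError("train and val partitions must be nonempty")
    channels = handle.spec.input_size[2]
    tr_clean, tr_noisy = stack_pairs(data.train, channels)
    va_clean, va_noisy = stack_pairs(data.val, channels)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(handle.module.parameters(), lr=cfg.lr_init,
               beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    sched = PlateauScheduler(cfg.plateau, cfg.lr_init)
    log = TrainingLog()
    best_psnr = -np.inf
    best_state: dict[str, np.ndarray] | None = None
    steps = 0
    n = tr_clean.shape[0]

    for epoch in range(1, cfg.epochs + 1):
        if cfg.lr_policy == "exponential":
            opt.lr = cfg.lr_init * cfg.exp_decay ** ((epoch - 1) // 10)
        order = rng.permutation(n)
        handle.module.train()
        epoch_terms: list[LossBreakdown] = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            x = Tensor(tr_noisy[idx])
            target = Tensor(tr_clean[idx])
            out = handle.module(x)
            bd = batch_loss(target, out, tr_noisy[idx])
            if bd.graph is not None:
                handle.module.zero_grad()
                bd.graph.backward()
                opt.step()
                bd.graph = None        # release the batch graph promptly
            epoch_terms.append(bd)
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break

        rec = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean([b.total for b in epoch_terms])),
            "train_mse": float(np.mean([b.mse_term for b in epoch_terms])),
            "train_kd": float(np.mean([b.kd_term for b in epoch_terms])),
            "train_ssim_term": float(np.mean([b.ssim_term for b in epoch_terms])),
            "train_l1": float(np.mean([b.l1_term for b in epoch_terms])),
        }
        rec.update(_val_metrics(handle, va_clean, va_noisy, cfg.batch_size, cfg.peak))
        log.records.append(rec)

        if rec["val_psnr"] > best_psnr:
            best_psnr = rec["val_psnr"]
            best_state = {k: v.copy() for k, v in handle.module.named_state().items()}
            log.events.append({"epoch": epoch, "event": "checkpoint",
                               "val_psnr": best_psnr})
        if cfg.lr_policy == "plateau":
            new_lr, reduced = sched.update(rec["val_psnr"])
            if reduced:
                log.events.append({"epoch": epoch, "event": "lr_reduced",
                                   "lr": new_lr})
            opt.lr = new_lr
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break

    if best_state is not None:
        handle.module.load_state(best_state)
    return log


def train_teacher(data: DatasetSplit, spec: TeacherSpec | None = None,
                  cfg: TrainingConfig | None = None
                  ) -> tuple[NetworkHandle, TrainingLog]:
    """Pretrain the teacher on (noisy, clean) pairs; returns best-val weights."""
    spec = spec or TeacherSpec()
    cfg = cfg or TrainingConfig()
    handle = build_teacher(spec, seed=cfg.seed)

    def batch_loss(target: Tensor, out: Tensor, _noisy: np.ndarray) -> LossBreakdown:
        return teacher_loss(target, out, cfg.loss, peak=cfg.peak)

    log = _run_training(handle, data, cfg, batch_loss)
    return handle, log


def distill_student(data: DatasetSplit, teacher: NetworkHandle | None,
                    spec: StudentSpec | None = None,
                    cfg: TrainingConfig | None = None
                    ) -> tuple[NetworkHandle, TrainingLog]:
    """Train the student with the full objective against a frozen teacher.

    With ``teacher=None`` (or ``cfg.loss.alpha == 0``) the distillation
    term vanishes and this is plain supervised training.
    """
    spec = spec or StudentSpec()
    cfg = cfg or TrainingConfig()
    if teacher is not None and teacher.spec.input_size != spec.input_size:
        raise ValueError(
            f"teacher input {teacher.spec.input_size} != student input {spec.input_size}")
    handle = build_student(spec, seed=cfg.seed)
    use_teacher = teacher is not None and cfg.loss.alpha > 0

    def batch_loss(target: Tensor, out: Tensor, noisy: np.ndarray) -> LossBreakdown:
        p_t = None
        if use_teacher:
            teacher.module.eval()
            with no_grad():
                p_t = Tensor(teacher.module(Tensor(noisy)).data)
        return total_loss(target, out, p_t, cfg.loss, peak=cfg.peak)

    log = _run_training(handle, data, cfg, batch_loss)
    return handle, log


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

LOSS_FORMULATIONS: list[tuple[str, dict]] = [
    ("KD+SSIM+L1", {"mse_weight": 0.0, "psnr_divisor": False}),
    ("MSE+SSIM+L1", {"alpha": 0.0, "psnr_divisor": False}),
    ("MSE+KD+L1", {"beta": 0.0, "psnr_divisor": False}),
    ("MSE+KD+SSIM", {"gamma_l1": 0.0, "psnr_divisor": False}),
    ("MSE+KD+SSIM+L1", {"psnr_divisor": False}),
    ("(MSE+KD+SSIM+L1)/PSNR", {"psnr_divisor": True}),
]

DISTILLATION_GRID: list[tuple[float, float]] = [
    (0.2, 0.8), (0.3, 0.8), (0.4, 0.8), (0.3, 0.7), (0.3, 0.9),
]


def run_ablation(data: DatasetSplit, grid: str,
                 cfg: TrainingConfig | None = None,
                 teacher: NetworkHandle | None = None,
                 teacher_spec: TeacherSpec | None = None,
                 student_spec: StudentSpec | None = None) -> dict:
    """Train one student per grid cell and report test-set metrics.

    ``grid='loss-formulations'``: six loss formulations × {plateau, fixed
    exponential schedule}.  ``grid='distillation'``: five (distillation
    weight, temperature) pairs.  All cells share the seed and the same
    pretrained teacher.
    """
    cfg = cfg or TrainingConfig()
    student_spec = student_spec or StudentSpec()
    if grid not in ("loss-formulations", "distillation"):
        raise ValueError(f"unknown ablation grid {grid!r}")
    if teacher is None:
        teacher, _ = train_teacher(data, teacher_spec, cfg)

    cells: list[dict] = []
    if grid == "loss-formulations":
        for name, overrides in LOSS_FORMULATIONS:
            for policy in ("plateau", "exponential"):
                cells.append({"loss_formulation": name, "lr_policy": policy,
                              "loss_overrides": overrides})
    else:
        for lam, temp in DISTILLATION_GRID:
            cells.append({"distillation_weight": lam, "temperature": temp,
                          "lr_policy": cfg.lr_policy,
                          "loss_overrides": {"alpha": lam, "temperature": temp}})

    channels = student_spec.input_size[2]
    te_clean, te_noisy = stack_pairs(data.test, channels)
    rows = []
    for cell in cells:
        loss = replace(cfg.loss, **cell["loss_overrides"])
        cell_cfg = replace(cfg, loss=loss, lr_policy=cell["lr_policy"])
        student, _ = distill_student(data, teacher, student_spec, cell_cfg)
        pred = _predict_batched(student, te_noisy, cfg.batch_size)
        row = {k: v for k, v in cell.items() if k != "loss_overrides"}
        row["psnr"] = float(np.mean([metrics.psnr(c, p, peak=cfg.peak)
                                     for c, p in zip(te_clean, pred)]))
        row["ssim"] = float(np.mean([metrics.ssim(c, p)
                                     for c, p in zip(te_clean, pred)]))
        row["rmse"] = float(np.mean([metrics.rmse(c, p)
                                     for c, p in zip(te_clean, pred)]))
        rows.append(row)
    return {"grid": grid, "rows": rows, "config": asdict(cfg),
            "n_test_patches": int(te_clean.shape[0])}


def desk_profile(seed: int = 0) -> dict:
    """The desk-scale experiment profile: one CPU, minutes not GPU-days.

    Single-channel phantoms, one noise level (variance 0.09), 360 training
    patches; a width-0.125 teacher and a short wide student (4 blocks of 16
    filters), both with the zero-initialized global residual head; Adam at
    5e-3 with batches of 16 (fewer, noisier steps trade off against the
    small corpus).  Everything derives from ``seed``.
    """
    return {
        "data": dict(n_images=13, seed=seed, noise_variances=[0.09],
                     split=(10 / 13, 2 / 13, 1 / 13), height=192, width=192),
        "teacher_spec": TeacherSpec(input_size=(64, 64, 1),
                                    width_multiplier=0.125, residual_output=True),
        "student_spec": StudentSpec(input_size=(64, 64, 1), n_blocks=4,
                                    filters=16, residual_output=True),
        "teacher_cfg": TrainingConfig(epochs=8, seed=seed, batch_size=16,
                                      lr_init=5e-3),
        "student_cfg": TrainingConfig(epochs=20, seed=seed, batch_size=16,
                                      lr_init=5e-3),
    }


def kfold_indices(n: int, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold split of ``range(n)`` into (train, held-out) index pairs."""
    if not (2 <= k <= n):
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    return [(np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
            for i in range(k)]


# ---------------------------------------------------------------------------
# Model / Results presentation layer
# ---------------------------------------------------------------------------

@dataclass
class FitResults:
    """Outcome of a training phase: the network, its log, and summaries."""

    handle: NetworkHandle
    log: TrainingLog
    config: TrainingConfig

    @property
    def best_val_psnr(self) -> float:
        return max(self.log.val_psnrs)

    def denoise(self, batch: np.ndarray) -> np.ndarray:
        return self.handle.forward(batch)

    def summary(self) -> str:
        spec = self.handle.spec
        lines = [
            f"{self.handle.kind.capitalize()} despeckling network",
            "=" * 40,
            f"parameters:     {self.handle.parameter_count:,}",
            f"input size:     {spec.input_size}",
            f"epochs run:     {len(self.log.records)}",
            f"final lr:       {self.log.records[-1]['lr']:.2e}",
            f"best val PSNR:  {self.best_val_psnr:.3f} dB",
            f"final val SSIM: {self.log.records[-1]['val_ssim']:.4f}",
            f"lr reductions:  {sum(1 for e in self.log.events if e['event'] == 'lr_reduced')}",
        ]
        return "\n".join(lines)


class TeacherDenoiser:
    """U-Net teacher fitted to (noisy, clean) patch pairs."""

    def __init__(self, data: DatasetSplit, spec: TeacherSpec | None = None,
                 config: TrainingConfig | None = None):
        self.data = data
        self.spec = spec or TeacherSpec()
        self.config = config or TrainingConfig()

    def fit(self) -> FitResults:
        handle, log = train_teacher(self.data, self.spec, self.config)
        return FitResults(handle, log, self.config)


class StudentDistiller:
    """Lightweight student distilled from a frozen pretrained teacher."""

    def __init__(self, data: DatasetSplit, teacher: NetworkHandle | None,
                 spec: StudentSpec | None = None,
                 config: TrainingConfig | None = None):
        self.data = data
        self.teacher = teacher
        self.spec = spec or StudentSpec()
        self.config = config or TrainingConfig()

    def fit(self) -> FitResults:
        handle, log = distill_student(self.data, self.teacher, self.spec, self.config)
        return FitResults(handle, log, self.config)
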