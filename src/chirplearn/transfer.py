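"""Transfer-learning strategies: deep/shallow finetuning and distillation.

The distillation objective is a weighted sum of a ground-truth term and a
distillation term, ``lam * L_g + (1 - lam) * L_kd``, with the temperature
dividing the *teacher* logits only. Defaults: lam = 0.5, temperature = 1.0;
cross-entropy + softmax + KL for single-label training, binary cross-entropy
+ sigmoid for multi-label. The teacher stays frozen throughout, and teacher
and student consume the identical augmented spectrogram batch at every step
(consistent teaching).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, NoisePool, augment_for_training
from .frontend import compute_mel
from .models import ClassifierModel, parameter_checksum, set_trainable_scope
from .nn import Adam, Tensor

__all__ = [
    "DistillationConfig", "TrainConfig", "TrainingLog",
    "ground_truth_loss", "distillation_loss", "total_distill_loss", "train",
]

LOG_FLOOR = 1e-10
STRATEGIES = ("deep_finetune", "shallow_finetune", "distill")


@dataclass(frozen=True)
class DistillationConfig:
    lam_weight: float = 0.5
    temperature: float = 1.0
    ground_truth_loss: str = "cross_entropy"
    distillation_loss: str = "kl_divergence"

    def __post_init__(self):
        if not 0.0 <= self.lam_weight <= 1.0:
            raise ValueError(f"lam_weight must lie in [0, 1], got {self.lam_weight}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ground_truth_loss not in ("cross_entropy", "binary_cross_entropy"):
            raise ValueError(f"unknown ground-truth loss {self.ground_truth_loss!r}")
        if self.distillation_loss not in ("kl_divergence", "binary_cross_entropy"):
            raise ValueError(f"unknown distillation loss {self.distillation_loss!r}")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_kind: str = "adam"
    seed: int = 0
    augmentation: AugmentationConfig | None = None
    multi_label: bool = False
    standardize: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer_kind != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer_kind!r}")


# ---------------------------------------------------------------------------
# losses — graph versions (used by the trainer) and scalar wrappers


def _as_batch(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    return arr[None] if arr.ndim == 1 else arr


def _ce_t(logits: Tensor, target: np.ndarray) -> Tensor:
    return -(Tensor(target) * logits.log_softmax(axis=-1)).sum(axis=-1).mean()


def _bce_t(logits: Tensor, target: np.ndarray) -> Tensor:
    p = logits.sigmoid()
    t = Tensor(target)
    terms = t * (p + LOG_FLOOR).log() + (1.0 - t) * (1.0 - p + LOG_FLOOR).log()
    return -(terms.mean())


def _ground_truth_loss_t(logits: Tensor, target: np.ndarray, kind: str) -> Tensor:
    target = np.asarray(target, dtype=np.float64)
    if np.any(target < 0) or np.any(target > 1):
        raise ValueError("targets must lie in [0, 1]")
    if kind == "cross_entropy":
        return _ce_t(logits, target)
    return _bce_t(logits, target)


def _distillation_loss_t(student_logits: Tensor, teacher_logits: np.ndarray,
                         cfg: DistillationConfig) -> Tensor:
    teacher_logits = np.asarray(teacher_logits, dtype=np.float64)
    if tuple(student_logits.shape) != teacher_logits.shape:
        raise ValueError(
            f"student/teacher logit shapes differ: {tuple(student_logits.shape)} "
            f"vs {teacher_logits.shape}")
    tempered = teacher_logits / cfg.temperature
    if cfg.distillation_loss == "kl_divergence":
        shifted = tempered - tempered.max(axis=-1, keepdims=True)
        p_t = np.exp(shifted)
        p_t /= p_t.sum(axis=-1, keepdims=True)
        log_p_t = np.log(p_t + LOG_FLOOR)
        kl_terms = Tensor(p_t) * (Tensor(log_p_t) - student_logits.log_softmax(axis=-1))
        return kl_terms.sum(axis=-1).mean()
    soft = 1.0 / (1.0 + np.exp(-tempered))
    return _bce_t(student_logits, soft)


def ground_truth_loss(logits, target, kind: str = "cross_entropy") -> float:
    """Scalar ground-truth loss (cross-entropy or BCE) on raw logits."""
    logits, target = _as_batch(logits), _as_batch(target)
    if logits.shape != target.shape:
        raise ValueError(f"logit/target shapes differ: {logits.shape} vs {target.shape}")
    return _ground_truth_loss_t(Tensor(logits), target, kind).item()


def distillation_loss(student_logits, teacher_logits,
                      cfg: DistillationConfig | None = None) -> float:
    """Scalar distillation loss; temperature divides the teacher logits only."""
    cfg = cfg or DistillationConfig()
    return _distillation_loss_t(Tensor(_as_batch(student_logits)),
                                _as_batch(teacher_logits), cfg).item()


def total_distill_loss(student_logits, teacher_logits, target,
                       cfg: DistillationConfig | None = None) -> float:
    """``lam * L_g + (1 - lam) * L_kd``; lam in {0, 1} reduces bit-exactly."""
    cfg = cfg or DistillationConfig()
    if cfg.lam_weight == 1.0:
        return ground_truth_loss(student_logits, target, cfg.ground_truth_loss)
    if cfg.lam_weight == 0.0:
        return distillation_loss(student_logits, teacher_logits, cfg)
    return (cfg.lam_weight
            * ground_truth_loss(student_logits, target, cfg.ground_truth_loss)
            + (1.0 - cfg.lam_weight)
            * distillation_loss(student_logits, teacher_logits, cfg))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingLog:
    strategy: str
    entries: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=1, default=str))

    @property
    def epoch_losses(self) -> list[float]:
        return [e["total_loss"] for e in self.entries]


def _prepare_input(clip, model: ClassifierModel, standardize: bool) -> np.ndarray:
    mel = compute_mel(clip, model.mel_config)
    return mel.standardized() if standardize else mel.values


def train(strategy: str, student: ClassifierModel,
          teacher: ClassifierModel | None,
          dataset: list[tuple],
          train_cfg: TrainConfig,
          distill_cfg: DistillationConfig | None = None,
          noise_pool: NoisePool | None = None) -> tuple[ClassifierModel, TrainingLog]:
    """Train ``student`` on ``dataset`` (list of (AudioClip, target) pairs).

    deep_finetune trains all parameters; shallow_finetune trains the head
    only; distill additionally matches a frozen teacher's soft outputs under
    consistent teaching. Returns the trained model and a per-epoch log.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    if not dataset:
        raise ValueError("dataset is empty")
    if strategy == "distill":
        if teacher is None:
            raise ValueError("distillation requires a teacher model")
        if teacher.vocab.classes != student.vocab.classes:
            raise ValueError("teacher/student class vocabularies differ")
        if teacher.frontend_preset != student.frontend_preset:
            raise ValueError(
                "consistent teaching requires teacher and student to share a "
                f"front-end preset ({teacher.frontend_preset!r} != "
                f"{student.frontend_preset!r})")
        distill_cfg = distill_cfg or DistillationConfig()
        set_trainable_scope(teacher, "frozen")
        set_trainable_scope(student, "all")
        gt_kind = distill_cfg.ground_truth_loss
    else:
        set_trainable_scope(student, "all" if strategy == "deep_finetune"
                            else "head_only")
        gt_kind = ("binary_cross_entropy" if train_cfg.multi_label
                   else "cross_entropy")

    aug_cfg = train_cfg.augmentation
    if aug_cfg is not None and aug_cfg.noise_prob > 0:
        if noise_pool is None or len(noise_pool) == 0:
            raise ValueError("augmentation requires a non-empty noise pool")

    rng = np.random.default_rng(train_cfg.seed)
    optimizer = Adam(student.parameters(), lr=train_cfg.learning_rate)
    log = TrainingLog(strategy=strategy)
    log.manifest = {
        "strategy": strategy,
        "train_config": asdict(train_cfg),
        "distill_config": asdict(distill_cfg) if distill_cfg else None,
        "student_kind": student.kind,
        "teacher_kind": teacher.kind if teacher else None,
        "n_examples": len(dataset),
        "classes": list(student.vocab.classes),
    }
    teacher_checksum_before = (parameter_checksum(teacher.parameters())
                               if teacher else None)

    n = len(dataset)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_total, epoch_gt, epoch_kd, n_batches = 0.0, 0.0, 0.0, 0
        for start in range(0, n, train_cfg.batch_size):
            batch_idx = order[start:start + train_cfg.batch_size]
            xs, ys = [], []
            for i in batch_idx:
                clip, target = dataset[i]
                if aug_cfg is not None:
                    def partner_source():
                        j = int(rng.integers(n))
                        return dataset[j][0], np.asarray(dataset[j][1], float)
                    clip, target = augment_for_training(
                        clip, target, partner_source, aug_cfg, rng,
                        noise_pool=noise_pool, multi_label=train_cfg.multi_label)
                xs.append(_prepare_input(clip, student, train_cfg.standardize))
                ys.append(np.asarray(target, dtype=np.float64))
            batch_x = np.stack(xs)
            batch_y = np.stack(ys)

            logits = student.forward_batch(batch_x)
            gt_loss = _ground_truth_loss_t(logits, batch_y, gt_kind)
            if strategy == "distill":
                # consistent teaching: the very same batch_x array
                teacher_logits = teacher.forward_batch(batch_x).data
                kd_loss = _distillation_loss_t(logits, teacher_logits, distill_cfg)
                lam = distill_cfg.lam_weight
                if lam == 1.0:
                    loss = gt_loss
                elif lam == 0.0:
                    loss = kd_loss
                else:
                    loss = gt_loss * lam + kd_loss * (1.0 - lam)
                epoch_kd += kd_loss.item()
            else:
                loss = gt_loss
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_total += loss.item()
            epoch_gt += gt_loss.item()
            n_batches += 1

        log.entries.append({
            "epoch": epoch,
            "total_loss": epoch_total / n_batches,
            "ground_truth_loss": epoch_gt / n_batches,
            "distillation_loss": (epoch_kd / n_batches
                                  if strategy == "distill" else np.nan),
            "backbone_checksum": parameter_checksum(student.backbone_parameters()),
            "head_checksum": parameter_checksum(student.head_parameters()),
        })

    if teacher is not None:
        after = parameter_checksum(teacher.parameters())
        if after != teacher_checksum_before:
            raise RuntimeError("teacher parameters changed during distillation")
    log.manifest["final_loss"] = log.entries[-1]["total_loss"]
    return student, log
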