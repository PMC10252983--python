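"""Training against texture-valued ground truth, prediction, IoU, ablation.

The network regresses the continuous 0-255 two-channel GT (wrinkle, pore)
with MSE loss — magnitude matters, so no output nonlinearity and no
cross-entropy. Continuous predictions are binarized per class before IoU:

    IoU(X, X_hat) = |X ∩ X_hat| / |X ∪ X_hat|

Aggregate IoU pools intersections and unions over the whole evaluation set;
per-image values are reported alongside. When both masks are empty IoU is
defined as 1 (0 when exactly one is empty).

``run_ablation`` trains the standard four-row configuration ladder —
vanilla U-Net, reduced U-Net, reduced + attentions, reduced + attentions +
zero-padding (proposed) — under one shared data/seed/epoch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn.optim import Adam
from .nn.tensor import Tensor, mse_loss
from .nn.unet import ModelConfig, SkinUNet, build_model, count_parameters
from .synthetic import SyntheticSample
from .texture import GroundTruthMap, make_ground_truth

__all__ = [
    "TrainConfig",
    "IoUReport",
    "DEFAULT_BINARIZE_THRESHOLDS",
    "sample_ground_truth",
    "train",
    "predict",
    "binarize",
    "iou",
    "evaluate",
    "false_positives_outside",
    "validation_loss",
    "run_ablation",
]

#: binarization cutoffs on the 0-255 prediction scale (wrinkle, pore)
DEFAULT_BINARIZE_THRESHOLDS = (64.0, 32.0)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 45
    batch_size: int = 4
    learning_rate: float = 1e-2
    lr_decay: str = "none"  # "cosine" (anneal to lr/10) or "none"
    grad_clip: float = 200.0  # global-norm spike clip; 0 disables
    optimizer: str = "adam"
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate < 0 or self.grad_clip < 0:
            raise ValueError("learning_rate and grad_clip must be >= 0")
        if self.lr_decay not in ("cosine", "none"):
            raise ValueError("lr_decay must be 'cosine' or 'none'")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "mse":
            raise ValueError("only mse loss is supported")


def sample_ground_truth(sample: SyntheticSample, **gt_kwargs) -> GroundTruthMap:
    """Texture-map GT from a synthetic sample's coarse annotations."""
    return make_ground_truth(
        sample.image,
        sample.coarse_wrinkle_annotation,
        sample.coarse_pore_annotation,
        **gt_kwargs,
    )


def _pad_chw(arr: np.ndarray, Z: int) -> np.ndarray:
    if Z == 0:
        return arr
    z = Z // 2
    return np.pad(arr, ((0, 0), (z, z), (z, z)))


def _as_batches(
    samples: Sequence[SyntheticSample],
    gts: Sequence[GroundTruthMap],
    Z: int,
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack(
        [_pad_chw(s.image.transpose(2, 0, 1).astype(np.float32), Z) for s in samples]
    )
    ys = np.stack([_pad_chw(g.stacked().astype(np.float32), Z) for g in gts])
    return xs, ys


def train(
    model: SkinUNet,
    samples: Sequence[SyntheticSample],
    config: TrainConfig,
    gts: Sequence[GroundTruthMap] | None = None,
) -> tuple[SkinUNet, list[float]]:
    """Minimize MSE between the 2-channel prediction and the texture GT.

    Deterministic for a fixed (model seed, config seed): initialization and
    the single sample permutation reused every epoch are both seeded, so
    repeated runs are bit-identical. Returns the model and the per-epoch
    mean training loss.
    """
    if len(samples) == 0:
        raise ValueError("training dataset is empty")
    if gts is None:
        gts = [sample_ground_truth(s) for s in samples]
    if len(gts) != len(samples):
        raise ValueError("samples and ground-truth maps differ in length")
    xs, ys = _as_batches(samples, gts, model.config.pad_Z)
    if xs.shape[2:] != ys.shape[2:]:
        raise ValueError("image / GT spatial shapes differ")
    history: list[float] = []
    if config.epochs == 0:
        return model, history
    # one fixed permutation reused every epoch keeps the lr=0 loss exactly
    # constant (batch-norm statistics see identical batches each epoch)
    order = np.random.default_rng(config.seed).permutation(len(samples))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    model.train()
    lr0 = config.learning_rate
    for epoch in range(config.epochs):
        if config.lr_decay == "cosine" and config.epochs > 1:
            # anneal to lr0/10; stabilizes the aggressive initial rate the
            # 0-255 regression scale requires
            frac = epoch / (config.epochs - 1)
            opt.lr = lr0 / 10.0 + 0.45 * lr0 * (1.0 + np.cos(np.pi * frac))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            out = model(Tensor(xs[idx]))
            loss = mse_loss(out, ys[idx])
            opt.zero_grad()
            loss.backward()
            if config.grad_clip > 0:
                _clip_global_norm(model.parameters(), config.grad_clip)
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    _recalibrate_batchnorm(model, xs, config.batch_size)
    return model, history


def _recalibrate_batchnorm(model: SkinUNet, xs: np.ndarray, batch_size: int) -> None:
    """Re-estimate batch-norm running statistics with the final weights.

    With short training budgets the exponential running averages lag the
    rapidly moving weights, so eval-mode predictions are mis-normalized
    relative to train-mode ones. One forward-only pass over the training
    set with cumulative (1/i) momentum replaces the lagged averages by the
    exact mean of the batch statistics under the final weights.
    """
    from .nn.modules import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    model.train()
    for i, start in enumerate(range(0, len(xs), batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        model(Tensor(xs[start : start + batch_size]))
    for bn in bns:
        bn.momentum = 0.1


def _clip_global_norm(params, max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def predict(model: SkinUNet, image: np.ndarray) -> np.ndarray:
    """Continuous 2-channel prediction (wrinkle, pore), cropped back to the
    input's H x W after removing the zero-padding border."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
    Z = model.config.pad_Z
    x = _pad_chw(image.transpose(2, 0, 1).astype(np.float32), Z)[None]
    model.eval()
    out = model(Tensor(x)).data[0]
    if Z:
        z = Z // 2
        out = out[:, z:-z, z:-z]
    return out


def binarize(value_map: np.ndarray, threshold: float) -> np.ndarray:
    return np.asarray(value_map) > threshold


def iou(truth: np.ndarray, pred: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 if both empty)."""
    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    union = np.count_nonzero(truth | pred)
    if union == 0:
        return 1.0
    return np.count_nonzero(truth & pred) / union


@dataclass(frozen=True)
class IoUReport:
    iou_wrinkle: float
    iou_pore: float
    per_image: list[tuple[float, float]] = field(default_factory=list)
    binarize_thresholds: tuple[float, float] = DEFAULT_BINARIZE_THRESHOLDS


def evaluate(
    model: SkinUNet,
    samples: Sequence[SyntheticSample],
    thresholds: tuple[float, float] = DEFAULT_BINARIZE_THRESHOLDS,
) -> IoUReport:
    """Pooled + per-image IoU of binarized predictions against the
    generator's exact fine masks."""
    inter = np.zeros(2)
    union = np.zeros(2)
    per_image = []
    for s in samples:
        pred = predict(model, s.image)
        truths = (s.fine_wrinkle_mask, s.fine_pore_mask)
        pair = []
        for ch, (truth, th) in enumerate(zip(truths, thresholds)):
            mask = binarize(pred[ch], th)
            inter[ch] += np.count_nonzero(truth & mask)
            union[ch] += np.count_nonzero(truth | mask)
            pair.append(iou(truth, mask))
        per_image.append(tuple(pair))
    pooled = [float(i / u) if u else 1.0 for i, u in zip(inter, union)]
    return IoUReport(
        iou_wrinkle=pooled[0],
        iou_pore=pooled[1],
        per_image=per_image,
        binarize_thresholds=thresholds,
    )


def false_positives_outside(
    model: SkinUNet,
    samples: Sequence[SyntheticSample],
    threshold: float = DEFAULT_BINARIZE_THRESHOLDS[1],
    channel: int = 1,
) -> int:
    """Total predicted pixels (given channel) outside that feature's zone —
    every such pixel is spurious, since true features live in-zone only."""
    zone_attr = "pore_zone" if channel == 1 else "wrinkle_zone"
    total = 0
    for s in samples:
        pred = binarize(predict(model, s.image)[channel], threshold)
        total += int(np.count_nonzero(pred & ~getattr(s.zones, zone_attr)))
    return total


def validation_loss(
    model: SkinUNet,
    samples: Sequence[SyntheticSample],
    gts: Sequence[GroundTruthMap] | None = None,
) -> float:
    """Mean MSE between predictions and texture GT over a validation set."""
    if gts is None:
        gts = [sample_ground_truth(s) for s in samples]
    losses = []
    for s, g in zip(samples, gts):
        pred = predict(model, s.image)
        losses.append(float(np.mean((pred - g.stacked().astype(np.float32)) ** 2)))
    return float(np.mean(losses))


def run_ablation(
    configs: Sequence[ModelConfig],
    train_samples: Sequence[SyntheticSample],
    val_samples: Sequence[SyntheticSample],
    train_config: TrainConfig,
    thresholds: tuple[float, float] = DEFAULT_BINARIZE_THRESHOLDS,
    keep_models: bool = False,
) -> list[dict]:
    """Train every config under the identical seed/budget and report the
    ablation table: parameter count, final training loss, validation loss,
    IoU per class, and pore false positives outside the pore zone."""
    if len(configs) == 0:
        raise ValueError("need at least one model config")
    train_gts = [sample_ground_truth(s) for s in train_samples]
    val_gts = [sample_ground_truth(s) for s in val_samples]
    rows = []
    for cfg in configs:
        model = build_model(cfg, seed=train_config.seed)
        model, history = train(model, train_samples, train_config, gts=train_gts)
        report = evaluate(model, val_samples, thresholds)
        rows.append(
            {
                "name": cfg.name or f"depth{cfg.depth}_base{cfg.base_channels}",
                "n_params": count_parameters(model),
                "final_loss": history[-1] if history else float("nan"),
                "val_loss": validation_loss(model, val_samples, gts=val_gts),
                "iou_wrinkle": report.iou_wrinkle,
                "iou_pore": report.iou_pore,
                "pore_fp_outside_zone": false_positives_outside(
                    model, val_samples, thresholds[1]
                ),
            }
        )
        if keep_models:
            rows[-1]["model"] = model
    return rows
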