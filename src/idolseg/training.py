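"""Generalized-model training: fit the FC-DenseNet on a cohort of CT/mask pairs.

Both time points of every training case enter the sample pool — a patient
contributes {CT_pre, Tumor_pre} and {CT_post, Tumor_post} as two independent
samples.  Optimization is Adam at batch size 1 with a polynomially decaying
learning rate lr(t) = lr0 * (1 - t/T)^p floored at ``min_lr``; augmentation
is random brightness scaling (applied to raw intensities, emulating scanner
gain variation) and uniform random cropping.  Input volumes are clipped to a
soft-tissue window and mapped linearly onto [-1, 1] before entering the
network, so the model never sees absolute CT units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fcd_net import LossConfig, NetConfig, SegmentationModel, build_network, loss_from_logits_tensor
from ._autograd import Adam
from .volumes import PatientCase, Volume

__all__ = ["TrainConfig", "fit_generalized", "predict", "normalize_intensities"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters of the generalized stage."""

    lr0: float = 1e-3
    poly_power: float = 0.9
    min_lr: float = 1e-8
    epochs: int = 100
    batch_size: int = 1
    brightness_range: Tuple[float, float] = (0.9, 1.1)
    crop_size: Optional[Tuple[int, int, int]] = None  # None: train on full volumes
    clip_window: Tuple[float, float] = (-100.0, 300.0)
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def lr_at(self, epoch: int, total: Optional[int] = None) -> float:
        """Polynomial decay lr(t) = lr0*(1 - t/T)^p, floored at min_lr."""
        T = total if total is not None else self.epochs
        frac = min(max(epoch / T, 0.0), 1.0)
        return max(self.lr0 * (1.0 - frac) ** self.poly_power, self.min_lr)


def normalize_intensities(
    data: np.ndarray, window: Tuple[float, float] = (-100.0, 300.0)
) -> np.ndarray:
    """Clip to a CT window and map it linearly onto [-1, 1].

    The mapping is fixed by the window alone — no per-volume statistics — so
    a training crop and the full inference volume land on exactly the same
    intensity scale (per-volume standardization would make the two differ
    whenever a crop's tissue composition differs from the whole volume's).
    """
    lo, hi = window
    x = np.clip(np.asarray(data, dtype=np.float32), lo, hi)
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    return (x - center) / half


def _augment(
    ct_raw: np.ndarray,
    mask: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.brightness_range
    scale = rng.uniform(lo, hi) if hi > lo else lo
    ct = ct_raw * scale
    if cfg.crop_size is not None:
        cx, cy, cz = cfg.crop_size
        X, Y, Z = ct.shape
        if cx > X or cy > Y or cz > Z:
            raise ValueError(f"crop_size {cfg.crop_size} exceeds volume shape {ct.shape}")
        ox = rng.integers(0, X - cx + 1)
        oy = rng.integers(0, Y - cy + 1)
        oz = rng.integers(0, Z - cz + 1)
        ct = ct[ox : ox + cx, oy : oy + cy, oz : oz + cz]
        mask = mask[ox : ox + cx, oy : oy + cy, oz : oz + cz]
    return normalize_intensities(ct, cfg.clip_window), mask


def run_training_loop(
    model: SegmentationModel,
    samples: Sequence[Tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    epochs: int,
    rng: np.random.Generator,
    augment: bool = True,
) -> List[dict]:
    """Adam/poly-lr loop over raw (ct, mask) samples; returns per-epoch log."""
    opt = Adam(model.parameters(), lr=cfg.lr0)
    log: List[dict] = []
    for epoch in range(epochs):
        lr = cfg.lr_at(epoch, epochs)
        opt.lr = lr
        order = rng.permutation(len(samples))
        losses = []
        for si in order:
            ct_raw, mask = samples[si]
            if augment:
                x, y = _augment(ct_raw, mask, cfg, rng)
            else:
                x, y = normalize_intensities(ct_raw, cfg.clip_window), mask
            logits = model.forward_logits(x, training=True, rng=rng)
            loss = loss_from_logits_tensor(logits, y, cfg.loss)
            lv = loss.item()
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss {lv} at epoch {epoch}, sample {si}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lv)
        log.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
    return log


def fit_generalized(
    train_cases: Sequence[PatientCase],
    cfg: TrainConfig | None = None,
    net_cfg: NetConfig | None = None,
) -> Tuple[SegmentationModel, List[dict]]:
    """Train the generalized FC-DenseNet on a cohort.

    Every case must carry ground truth at both time points; both pairs join
    the training pool.  Returns the trained model and the per-epoch loss log.
    Fully reproducible given ``cfg.seed``.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    net_cfg = net_cfg if net_cfg is not None else NetConfig()
    if len(train_cases) < 1:
        raise ValueError("need at least one training case")
    samples: List[Tuple[np.ndarray, np.ndarray]] = []
    for case in train_cases:
        if case.tumor_post is None:
            raise ValueError(f"case {case.case_id}: tumor_post required for training")
        samples.append(
            (np.asarray(case.ct_pre.data, np.float32), np.asarray(case.tumor_pre.data))
        )
        samples.append(
            (np.asarray(case.ct_post.data, np.float32), np.asarray(case.tumor_post.data))
        )
    model = build_network(net_cfg, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    log = run_training_loop(model, samples, cfg, cfg.epochs, rng, augment=True)
    return model, log


def predict(
    model: SegmentationModel,
    ct: Volume,
    clip_window: Tuple[float, float] = (-100.0, 300.0),
) -> Volume:
    """Foreground-probability volume for a CT; deterministic (no dropout).

    In-plane dims are edge-padded up to the network's divisor and the output
    cropped back, so any volume size is admissible.
    """
    x = normalize_intensities(np.asarray(ct.data, np.float32), clip_window)
    d = model.cfg.inplane_divisor
    X, Y, Z = x.shape
    px = (-X) % d
    py = (-Y) % d
    if px or py:
        x = np.pad(x, ((0, px), (0, py), (0, 0)), mode="edge")
    prob = model.predict_prob(x)[1]
    prob = prob[:X, :Y, :]
    return Volume(prob, spacing=ct.spacing, origin=ct.origin)
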