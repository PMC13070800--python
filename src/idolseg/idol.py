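"""Patient-specific adaptation by intentional overfitting.

The generalized model is deliberately overfitted to one patient's prior
pair {CT_pre, Tumor_pre}: the pair is repeated and perturbed (small affine
transforms, brightness scaling, additive noise) to form a patient-specific
training stream, and training continues for a fixed number of epochs with
the generalized stage's hyperparameters.  The final-epoch weights are used
as the personalized model — no early stopping or best-checkpoint selection —
which then segments the same patient's follow-up CT.  The generalized model
object is never modified; adaptation always returns a distinct copy.

The learning-rate schedule restarts for adaptation: t counts adaptation
epochs against the adaptation epoch total.  ("Identical hyperparameters" is
read as the same schedule formula, not a continued global step; pass
``restart_schedule=False`` for the continued-decay alternative.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from ._autograd import Adam
from .fcd_net import SegmentationModel, loss_from_logits_tensor
from .training import TrainConfig, normalize_intensities, predict
from .volumes import Mask, Volume, binarize

__all__ = ["IdolConfig", "adapt", "segment_post"]


@dataclass
class IdolConfig:
    """Adaptation hyperparameters.

    ``repetitions`` is the number of perturbed copies of the prior pair seen
    per adaptation epoch.  Geometric perturbations are in-plane rotation
    (degrees), in-plane/axial translation (voxels) and isotropic scaling;
    intensity perturbations are brightness scaling and additive Gaussian
    noise with sd expressed as a fraction of the processed CT window width.
    Optimizer, learning-rate schedule and loss are inherited from the
    generalized stage's :class:`~idolseg.training.TrainConfig`.
    """

    epochs: int = 350
    repetitions: int = 20
    perturb: bool = True
    rotation_deg: float = 10.0
    translate_inplane_vox: float = 5.0
    translate_axial_vox: float = 2.0
    scale_range: Tuple[float, float] = (0.9, 1.1)
    brightness_range: Tuple[float, float] = (0.9, 1.1)
    noise_sd_frac: float = 0.02
    restart_schedule: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def _perturb_pair(
    ct: np.ndarray,
    mask: np.ndarray,
    cfg: IdolConfig,
    rng: np.random.Generator,
    intensity_range: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """One random affine + intensity perturbation of the prior pair.

    ``intensity_range`` is the width of the processed CT window: noise is
    scaled to the intensities the network actually sees, not to the raw
    volume range (which is dominated by air at -1000 and would produce
    noise larger than the tissue contrasts themselves).
    """
    theta = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    scale = rng.uniform(*cfg.scale_range)
    tx = rng.uniform(-cfg.translate_inplane_vox, cfg.translate_inplane_vox)
    ty = rng.uniform(-cfg.translate_inplane_vox, cfg.translate_inplane_vox)
    tz = rng.uniform(-cfg.translate_axial_vox, cfg.translate_axial_vox)
    c, s = np.cos(theta), np.sin(theta)
    # in-plane rotation about z, isotropic scale; matrix maps output -> input
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]) / scale
    center = (np.asarray(ct.shape) - 1) / 2.0
    offset = center - rot @ (center + np.array([tx, ty, tz]))
    ct_bg = float(ct.min())
    ct_t = ndimage.affine_transform(
        ct, rot, offset=offset, order=1, mode="constant", cval=ct_bg
    )
    mask_t = ndimage.affine_transform(
        mask.astype(np.float32), rot, offset=offset, order=0, mode="constant", cval=0.0
    ).astype(np.uint8)
    bright = rng.uniform(*cfg.brightness_range)
    ct_t = ct_t * bright
    if cfg.noise_sd_frac > 0:
        ct_t = ct_t + rng.normal(0.0, cfg.noise_sd_frac * intensity_range, ct_t.shape)
    return ct_t.astype(np.float32), mask_t


def adapt(
    pretrained: SegmentationModel,
    ct_pre: Volume,
    tumor_pre: Mask,
    cfg: IdolConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> SegmentationModel:
    """Overfit a copy of the generalized model to one patient's prior pair.

    Returns the final-epoch personalized model; ``pretrained`` is untouched.
    With ``epochs=0`` the personalized model equals the generalized one.
    """
    cfg = cfg if cfg is not None else IdolConfig()
    train_cfg = train_cfg if train_cfg is not None else TrainConfig()
    if ct_pre.shape != tumor_pre.shape:
        raise ValueError(
            f"prior shapes differ: ct {ct_pre.shape} vs mask {tumor_pre.shape}"
        )
    model = pretrained.copy()
    if cfg.epochs == 0:
        return model
    rng = np.random.default_rng(cfg.seed)
    ct_raw = np.asarray(ct_pre.data, np.float32)
    mask = np.asarray(tumor_pre.data, np.uint8)
    total = cfg.epochs if cfg.restart_schedule else max(train_cfg.epochs, cfg.epochs)
    opt = Adam(model.parameters(), lr=train_cfg.lr0)
    for epoch in range(cfg.epochs):
        opt.lr = train_cfg.lr_at(epoch, total)
        for _ in range(cfg.repetitions):
            if cfg.perturb:
                window_width = train_cfg.clip_window[1] - train_cfg.clip_window[0]
                ct_t, m_t = _perturb_pair(ct_raw, mask, cfg, rng, window_width)
            else:
                ct_t, m_t = ct_raw, mask
            if train_cfg.crop_size is not None:  # inherited base augmentation
                cx, cy, cz = train_cfg.crop_size
                X, Y, Z = ct_t.shape
                ox = rng.integers(0, X - cx + 1)
                oy = rng.integers(0, Y - cy + 1)
                oz = rng.integers(0, Z - cz + 1)
                ct_t = ct_t[ox : ox + cx, oy : oy + cy, oz : oz + cz]
                m_t = m_t[ox : ox + cx, oy : oy + cy, oz : oz + cz]
            x = normalize_intensities(ct_t, train_cfg.clip_window)
            logits = model.forward_logits(x, training=True, rng=rng)
            loss = loss_from_logits_tensor(logits, m_t, train_cfg.loss)
            lv = loss.item()
            if not np.isfinite(lv):
                raise RuntimeError(f"non-finite adaptation loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def segment_post(
    personalized: SegmentationModel,
    ct_post: Volume,
    threshold: float = 0.5,
    clip_window: Tuple[float, float] = (-100.0, 300.0),
) -> Tuple[Mask, Volume]:
    """Segment the follow-up CT with the personalized model.

    Returns the binarized mask and the underlying probability volume.
    """
    prob = predict(personalized, ct_post, clip_window)
    return binarize(prob, threshold), prob
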