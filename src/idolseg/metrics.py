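"""Segmentation overlap and volume metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import Mask

__all__ = ["DscResult", "dice", "mask_volume_cc"]


@dataclass
class DscResult:
    """Dice similarity coefficient with its defining voxel counts.

    DSC = 2|A∩B| / (|A|+|B|).  Two empty masks are defined to agree
    perfectly (DSC 1.0); an empty prediction against a nonempty truth
    scores 0.0 — models that fail to produce any prediction must still be
    scoreable.
    """

    dsc: float
    intersection_voxels: int
    pred_voxels: int
    truth_voxels: int


def dice(pred: Mask, truth: Mask) -> DscResult:
    """Dice similarity coefficient between two binary masks."""
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask shapes differ: pred {pred.shape} vs truth {truth.shape}"
        )
    a = np.asarray(pred.data, dtype=bool)
    b = np.asarray(truth.data, dtype=bool)
    inter = int(np.logical_and(a, b).sum())
    na, nb = int(a.sum()), int(b.sum())
    dsc = 1.0 if (na + nb) == 0 else 2.0 * inter / (na + nb)
    return DscResult(dsc=dsc, intersection_voxels=inter, pred_voxels=na, truth_voxels=nb)


def mask_volume_cc(m: Mask) -> float:
    """Mask volume in cubic centimeters: voxel count x dx·dy·dz / 1000."""
    return m.voxel_count() * m.voxel_volume_mm3() / 1000.0
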