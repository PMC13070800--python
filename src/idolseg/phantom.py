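"""Synthetic paired pre/post liver-CT phantoms with ground-truth tumor masks.

The generator emulates portal-venous-phase liver CT of a treated
hepatocellular carcinoma: a hyperdense (contrast-enhanced) liver with
band-limited multiplicative texture standing in for cirrhotic parenchyma, a
heterogeneous hypodense tumor built as a union of ellipsoid lobes, and a
follow-up scan in which the tumor is rescaled by a configurable shrink
factor, the liver itself mildly contracts, and a peritumoral "edema" ring of
intermediate intensity appears around the post-treatment tumor.  The edema
ring is deliberately EXCLUDED from the ground-truth post mask: it plants the
over-segmentation hazard of treatment-related inflammatory change, so tests
can probe whether a segmentation model spills into it.

Everything is deterministic given the seed.  Intensities are CT-like class
means, not calibrated Hounsfield units; only the contrast ordering
(background << body < tumor < edema < liver) matters downstream because the
network z-scores its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .recist import classify, max_axial_diameter
from .volumes import Mask, PatientCase, Volume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_case",
    "generate_cohort",
]

#: Default class means in CT-like units.
DEFAULT_INTENSITIES: Dict[str, float] = {
    "background": -1000.0,
    "body": 40.0,
    "liver": 110.0,
    "tumor": 70.0,
    "edema": 85.0,
}


@dataclass
class PhantomConfig:
    """Geometry, intensity and response parameters of one phantom case.

    Spacing defaults keep the ~0.23 in-plane/axial anisotropy of clinical
    portal-venous liver CT while covering an adult-liver-sized field of view
    with a 64x64x24 grid.  ``shrink_factor`` scales the tumor between the
    time points; ``liver_scale_post`` models mild global post-treatment liver
    contraction about the liver center (tumor center moves with the liver).
    """

    shape: Tuple[int, int, int] = (64, 64, 24)
    spacing: Tuple[float, float, float] = (1.4, 1.4, 6.0)
    liver_semiaxes: Tuple[float, float, float] = (38.0, 32.0, 58.0)
    tumor_n_lobes: int = 2
    tumor_semiaxes_range: Tuple[float, float] = (9.0, 16.0)
    shrink_factor: float = 0.7
    edema_thickness: float = 1.5
    liver_scale_post: float = 0.95
    intensity_means: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    texture_amplitude: float = 8.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.shrink_factor <= 0:
            raise ValueError(f"shrink_factor must be > 0, got {self.shrink_factor}")
        if not 0 < self.liver_scale_post <= 1:
            raise ValueError(
                f"liver_scale_post must be in (0,1], got {self.liver_scale_post}"
            )
        if self.tumor_n_lobes < 1:
            raise ValueError("tumor_n_lobes must be >= 1")
        lo, hi = self.tumor_semiaxes_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad tumor_semiaxes_range {self.tumor_semiaxes_range}")
        missing = set(DEFAULT_INTENSITIES) - set(self.intensity_means)
        if missing:
            raise ValueError(f"intensity_means missing classes {sorted(missing)}")


@dataclass
class PhantomTruth:
    """Ground truth for parameter-recovery tests on one phantom case."""

    case_id: str
    pre_mask_diameter_mm: float
    post_mask_diameter_mm: float
    shrink_factor: float
    true_response_class: str
    min_inplane_extent_voxels: int


def _grid_mm(shape, spacing):
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grid, center, semiaxes) -> np.ndarray:
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grid, center, semiaxes))
    return q <= 1.0


def _fibonacci_directions(n: int = 256) -> np.ndarray:
    """Quasi-uniform unit directions for surface containment checks."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _lobe_inside_liver(center, semiaxes, liver_center, liver_semiaxes) -> bool:
    dirs = _fibonacci_directions()
    surf = np.asarray(center) + dirs * np.asarray(semiaxes)
    q = (((surf - np.asarray(liver_center)) / np.asarray(liver_semiaxes)) ** 2).sum(1)
    return bool((q <= 1.0).all())


def _smooth_noise(rng: np.random.Generator, shape, coarse: int = 4) -> np.ndarray:
    """Band-limited unit-variance field: coarse white noise upsampled smoothly."""
    cshape = [max(2, n // coarse) for n in shape]
    base = rng.standard_normal(cshape)
    zoom = [n / c for n, c in zip(shape, cshape)]
    tex = ndimage.zoom(base, zoom, order=3, mode="nearest", grid_mode=True)
    tex = tex[: shape[0], : shape[1], : shape[2]]
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _render(
    cfg: PhantomConfig,
    liver: np.ndarray,
    tumor: np.ndarray,
    edema: np.ndarray,
    body: np.ndarray,
    tex: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    im = cfg.intensity_means
    img = np.full(cfg.shape, im["background"], dtype=np.float64)
    img[body] = im["body"]
    img[liver] = im["liver"]
    img[edema] = im["edema"]
    img[tumor] = im["tumor"]
    parenchyma = liver & ~tumor & ~edema
    img[parenchyma] += cfg.texture_amplitude * tex[parenchyma]
    img[tumor] += 0.5 * cfg.texture_amplitude * tex[tumor]  # heterogeneous core
    img += rng.normal(0.0, cfg.noise_sd, cfg.shape)
    return img.astype(np.float32)


def _min_inplane_extent(mask: np.ndarray) -> int:
    """Smaller in-plane voxel extent of the mask's largest axial footprint."""
    best = 0
    for z in range(mask.shape[2]):
        xs, ys = np.nonzero(mask[:, :, z])
        if len(xs) == 0:
            continue
        ext = min(xs.max() - xs.min() + 1, ys.max() - ys.min() + 1)
        best = max(best, int(ext))
    return best


def generate_case(cfg: PhantomConfig, case_id: str = "case") -> Tuple[PatientCase, PhantomTruth]:
    """Render one pre/post phantom pair with exact ground-truth masks.

    The tumor geometry (lobe centers and semiaxes) is sampled once and reused
    for both time points, so the post mask is the exact voxelization of the
    pre shape rescaled by ``shrink_factor`` and repositioned with the liver.
    Raises a configuration error before rendering if the tumor does not fit
    inside the liver at either time point.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shape, spacing = cfg.shape, cfg.spacing

    liver_center = np.zeros(3)
    liver_ax = np.asarray(cfg.liver_semiaxes, dtype=float)

    # --- sample tumor geometry (mm, liver frame) -------------------------
    lo, hi = cfg.tumor_semiaxes_range
    main_ax = rng.uniform(lo, hi, size=3)
    t_center = liver_center + rng.uniform(-0.25, 0.25, size=3) * liver_ax
    lobes: List[Tuple[np.ndarray, np.ndarray]] = [(t_center, main_ax)]
    for _ in range(cfg.tumor_n_lobes - 1):
        off = rng.uniform(-0.6, 0.6, size=3) * main_ax
        ax = rng.uniform(0.45, 0.75, size=3) * main_ax
        lobes.append((t_center + off, ax))

    def post_lobe(center, ax):
        c = liver_center + cfg.liver_scale_post * (center - liver_center)
        return c, ax * cfg.shrink_factor

    # --- containment check before any rendering --------------------------
    for c, a in lobes:
        if not _lobe_inside_liver(c, a, liver_center, liver_ax):
            raise ValueError(
                f"{case_id}: tumor lobe at {np.round(c, 1)} with semiaxes "
                f"{np.round(a, 1)} mm does not fit inside the pre-treatment liver"
            )
    liver_ax_post = liver_ax * cfg.liver_scale_post
    for c, a in (post_lobe(*l) for l in lobes):
        if not _lobe_inside_liver(c, a, liver_center, liver_ax_post):
            raise ValueError(
                f"{case_id}: post-treatment tumor lobe does not fit inside the liver"
            )

    # --- voxelize ---------------------------------------------------------
    grid = _grid_mm(shape, spacing)
    body_ax = liver_ax * 1.45
    body = _ellipsoid(grid, liver_center, np.minimum(
        body_ax, [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]))
    liver_pre = _ellipsoid(grid, liver_center, liver_ax)
    liver_post = _ellipsoid(grid, liver_center, liver_ax_post)

    tumor_pre = np.zeros(shape, dtype=bool)
    for c, a in lobes:
        tumor_pre |= _ellipsoid(grid, c, a)
    tumor_post = np.zeros(shape, dtype=bool)
    for c, a in (post_lobe(*l) for l in lobes):
        tumor_post |= _ellipsoid(grid, c, a)

    if cfg.edema_thickness > 0 and tumor_post.any():
        dist = ndimage.distance_transform_edt(~tumor_post, sampling=spacing)
        edema = (dist <= cfg.edema_thickness) & liver_post & ~tumor_post
    else:
        edema = np.zeros(shape, dtype=bool)

    # --- render intensities ----------------------------------------------
    tex_pre = _smooth_noise(rng, shape)
    tex_post = _smooth_noise(rng, shape)
    img_pre = _render(cfg, liver_pre, tumor_pre, np.zeros(shape, bool), body, tex_pre, rng)
    img_post = _render(cfg, liver_post, tumor_post, edema, body, tex_post, rng)

    case = PatientCase(
        case_id=case_id,
        ct_pre=Volume(img_pre, spacing),
        tumor_pre=Mask(tumor_pre.astype(np.uint8), spacing),
        ct_post=Volume(img_post, spacing),
        tumor_post=Mask(tumor_post.astype(np.uint8), spacing),
    )

    d_pre, _, _ = max_axial_diameter(case.tumor_pre)
    d_post, _, _ = max_axial_diameter(case.tumor_post)
    s = cfg.shrink_factor
    true_cls = classify(100.0 * (s - 1.0), d_post=s * d_pre, d_pre=d_pre)
    truth = PhantomTruth(
        case_id=case_id,
        pre_mask_diameter_mm=d_pre,
        post_mask_diameter_mm=d_post,
        shrink_factor=s,
        true_response_class=true_cls,
        min_inplane_extent_voxels=_min_inplane_extent(tumor_pre),
    )
    return case, truth


def generate_cohort(
    n_train: int,
    n_val: int,
    base_cfg: PhantomConfig | None = None,
    shrink_range: Tuple[float, float] = (0.45, 1.05),
    seed: int = 0,
    liver_mean_sd: float = 8.0,
    tumor_contrast_range: Tuple[float, float] = (12.0, 55.0),
) -> Tuple[List[PatientCase], List[PatientCase], List[PhantomTruth]]:
    """Generate a train/validation phantom cohort.

    Per-case seeds and shrink factors derive deterministically from the
    cohort seed; shrink factors are uniform on ``shrink_range`` (the default
    spans roughly -55% to +5% diameter change, the band clinical responses
    after chemoradiotherapy fall into).

    Between-patient appearance varies in two ways that drive everything
    downstream: the liver enhancement level jitters case to case
    (``liver_mean_sd``), and the tumor's hypodense contrast against liver is
    drawn uniformly from ``tumor_contrast_range`` — from near-isodense,
    barely conspicuous lesions up to clearly hypodense ones.  Hepatocellular
    carcinomas on portal-venous CT genuinely span that conspicuity range,
    and it is exactly what limits a cohort-trained model on an unseen
    patient while leaving a patient-adapted model its advantage.  The edema
    intensity sits midway between each case's tumor and liver, slightly
    toward the tumor.
    """
    if n_train < 1 or n_val < 1:
        raise ValueError("n_train and n_val must be >= 1")
    base = base_cfg if base_cfg is not None else PhantomConfig()
    rng = np.random.default_rng(seed)
    cases: List[PatientCase] = []
    truths: List[PhantomTruth] = []
    n_total = n_train + n_val
    for i in range(n_total):
        s = float(rng.uniform(*shrink_range))
        case_seed = int(rng.integers(0, 2**31 - 1))
        means = dict(base.intensity_means)
        means["liver"] = means["liver"] + float(rng.normal(0, liver_mean_sd))
        means["tumor"] = means["liver"] - float(rng.uniform(*tumor_contrast_range))
        means["edema"] = 0.5 * (means["liver"] + means["tumor"]) - 5.0
        cfg = replace(
            base, shrink_factor=s, seed=case_seed, intensity_means=means
        )
        cid = f"train{i:02d}" if i < n_train else f"val{i - n_train:02d}"
        case, truth = generate_case(cfg, case_id=cid)
        cases.append(case)
        truths.append(truth)
    return cases[:n_train], cases[n_train:], truths
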