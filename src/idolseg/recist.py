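"""RECIST 1.1 diameter measurement from binary masks and response statistics.

The longest diameter of a lesion is measured on axial (x-y) slices only: for
each slice the largest connected in-plane component is taken and the maximum
pairwise distance between its voxel centers (scaled by the in-plane spacing
``dx, dy``) is computed; the lesion diameter is the maximum over slices.
Response classes follow RECIST 1.1 on the percent change of that diameter:
PR if the decrease is >= 30%, PD if the increase is >= 20% AND >= 5 mm
absolute, CR if the lesion disappears, SD otherwise (boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError

from .volumes import Mask

__all__ = [
    "DiameterRecord",
    "ConcordanceTable",
    "max_axial_diameter",
    "percent_change",
    "classify",
    "concordance",
    "paired_stats",
    "measure_case",
]

# 8-connectivity within a slice: diagonal voxels belong to the same lesion
# component (a lesion cut at a corner is still one lesion).
_STRUCT_2D = np.ones((3, 3), dtype=bool)


@dataclass
class DiameterRecord:
    """Per-case maximal axial diameters and the derived response class."""

    case_id: str
    d_pre_mm: float
    d_post_mm: float
    pct_change: Optional[float]
    response_class: Optional[str]


@dataclass
class ConcordanceTable:
    """2x2 manual-vs-predicted cross-tabulation over {PR, SD} with statistics.

    ``counts`` is ((PR&PR, PR&SD), (SD&PR, SD&SD)) with manual on rows.
    ``auc`` is the balanced accuracy (sensitivity + specificity)/2 of the
    binary predicted-PR classifier, the quantity a 2x2 table determines.
    """

    counts: Tuple[Tuple[int, int], Tuple[int, int]]
    sensitivity: Optional[float]
    specificity: Optional[float]
    auc: Optional[float]
    mcnemar_p: float
    n_concordant: int
    n_total: int


def _slice_max_distance(
    xs: np.ndarray, ys: np.ndarray, dx: float, dy: float
) -> Tuple[float, Tuple[Tuple[int, int], Tuple[int, int]]]:
    """Maximum pairwise distance between voxel centers of one 2D component.

    Returns (distance_mm, ((x1,y1),(x2,y2))) with the endpoint pair ordered
    and, among ties, lexicographically smallest.  The maximum distance over a
    finite point set is attained between convex-hull vertices, so for large
    components only hull vertices are enumerated; tiny or degenerate
    (collinear) components fall back to all pairs.
    """
    pts_mm = np.column_stack([xs * dx, ys * dy])
    idx = np.arange(len(xs))
    if len(xs) == 1:
        p = (int(xs[0]), int(ys[0]))
        return 0.0, (p, p)
    if len(xs) > 16:
        try:
            hull = ConvexHull(pts_mm)
            idx = idx[hull.vertices]
            pts_mm = pts_mm[hull.vertices]
        except QhullError:
            pass  # collinear set: brute-force the (small) hull-less set
    diff = pts_mm[:, None, :] - pts_mm[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    ii, jj = np.nonzero(d2 >= best - 1e-9)
    pairs = []
    for a, b in zip(ii, jj):
        if a >= b:
            continue
        pa = (int(xs[idx[a]]), int(ys[idx[a]]))
        pb = (int(xs[idx[b]]), int(ys[idx[b]]))
        pairs.append(tuple(sorted((pa, pb))))
    pair = min(pairs)
    a_mm = np.array([pair[0][0] * dx, pair[0][1] * dy])
    b_mm = np.array([pair[1][0] * dx, pair[1][1] * dy])
    return float(np.linalg.norm(a_mm - b_mm)), pair


def max_axial_diameter(
    m: Mask,
) -> Tuple[float, Optional[int], Optional[Tuple[Tuple[int, int], Tuple[int, int]]]]:
    """Longest in-plane diameter of a mask, RECIST-style.

    For each axial slice (fixed z) the largest 8-connected component is
    selected (ties by scan order) and its maximal center-to-center distance
    computed; the result is the maximum over slices.  Ties across slices go
    to the lower slice index, then the lexicographically smaller endpoint
    pair.  An empty mask measures 0 mm with no slice/endpoints.

    Returns ``(diameter_mm, slice_index, ((x1, y1), (x2, y2)))``.
    """
    dx, dy, _ = m.spacing
    data = np.asarray(m.data)
    best: Tuple[float, Optional[int], Optional[tuple]] = (0.0, None, None)
    for z in range(data.shape[2]):
        sl = data[:, :, z]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=_STRUCT_2D)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
            lab = int(np.argmax(sizes)) + 1  # argmax -> first max: scan-order tie-break
        else:
            lab = 1
        xs, ys = np.nonzero(labels == lab)
        d, pair = _slice_max_distance(xs, ys, dx, dy)
        if best[1] is None or d > best[0] + 1e-9:
            best = (d, z, pair)
        # equal diameter on a later slice: earlier slice wins on the tie
    return best


def percent_change(d_pre: float, d_post: float) -> float:
    """Percent diameter change 100*(d_post - d_pre)/d_pre."""
    if d_pre <= 0:
        raise ValueError(
            f"percent change undefined for d_pre={d_pre} "
            "(new-lesion semantics are out of scope)"
        )
    return 100.0 * (d_post - d_pre) / d_pre


def classify(
    pct: float, d_post: Optional[float] = None, d_pre: Optional[float] = None
) -> str:
    """RECIST 1.1 response class from a percent diameter change.

    CR if the lesion disappeared (d_post == 0); PR if pct <= -30; PD if
    pct >= +20 and the absolute increase is >= 5 mm (only checkable when both
    diameters are supplied; with percent alone, pct >= +20 classifies PD);
    SD otherwise.  Boundaries are inclusive.
    """
    if d_post is not None and d_post == 0:
        return "CR"
    if pct <= -30.0:
        return "PR"
    if pct >= 20.0:
        if d_pre is None or d_post is None:
            return "PD"
        if (d_post - d_pre) >= 5.0:
            return "PD"
    return "SD"


def _mcnemar_exact(b: int, c: int) -> float:
    """Exact (binomial) McNemar p on discordant counts, two-sided."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    p = 2.0 * sum(comb(n, i) for i in range(k + 1)) * 0.5**n
    return min(1.0, p)


def concordance(
    manual: Sequence[str], predicted: Sequence[str]
) -> ConcordanceTable:
    """Cross-tabulate manual vs predicted {PR, SD} calls and derive statistics.

    Sensitivity and specificity treat PR (response) as the positive class;
    the exact McNemar test uses the discordant cells.  Classes outside
    {PR, SD} are rejected (multi-class concordance is out of scope).
    """
    if len(manual) != len(predicted) or len(manual) == 0:
        raise ValueError("manual and predicted must be equal-length, nonempty")
    allowed = {"PR", "SD"}
    bad = (set(manual) | set(predicted)) - allowed
    if bad:
        raise ValueError(
            f"concordance is defined on {{PR, SD}} only; found {sorted(bad)} "
            "(multi-class mode is out of scope)"
        )
    a = sum(1 for m, p in zip(manual, predicted) if m == "PR" and p == "PR")
    b = sum(1 for m, p in zip(manual, predicted) if m == "PR" and p == "SD")
    c = sum(1 for m, p in zip(manual, predicted) if m == "SD" and p == "PR")
    d = sum(1 for m, p in zip(manual, predicted) if m == "SD" and p == "SD")
    sens = a / (a + b) if (a + b) > 0 else None
    spec = d / (c + d) if (c + d) > 0 else None
    auc = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    return ConcordanceTable(
        counts=((a, b), (c, d)),
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        mcnemar_p=_mcnemar_exact(b, c),
        n_concordant=a + d,
        n_total=a + b + c + d,
    )


def paired_stats(x: Sequence[float], y: Sequence[float]) -> dict:
    """Paired comparison of two mm series: t-test, Wilcoxon, Spearman.

    Returns mean difference (y - x), two-sided paired t, exact-where-feasible
    Wilcoxon signed-rank, and Spearman's rho with average ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("paired_stats needs two equal-length series of length >= 3")
    diff = y - x
    t_res = stats.ttest_rel(y, x)
    out = {
        "mean_diff": float(diff.mean()),
        "t": float(t_res.statistic),
        "df": int(len(x) - 1),
        "p_t": float(t_res.pvalue),
    }
    if np.all(diff == 0):
        out["wilcoxon_p"] = None  # signed-rank undefined with no nonzero pairs
    else:
        w = stats.wilcoxon(y, x, mode="auto")
        out["wilcoxon_p"] = float(w.pvalue)
    rho = stats.spearmanr(x, y)
    out["spearman_rho"] = float(rho.statistic)
    out["spearman_p"] = float(rho.pvalue)
    return out


def measure_case(case_id: str, pre: Mask, post: Mask) -> DiameterRecord:
    """Measure both time points of one case and classify the response."""
    d_pre, _, _ = max_axial_diameter(pre)
    d_post, _, _ = max_axial_diameter(post)
    if d_pre > 0:
        pct = percent_change(d_pre, d_post)
        cls = classify(pct, d_post=d_post, d_pre=d_pre)
    else:
        pct, cls = None, None
    return DiameterRecord(case_id, d_pre, d_post, pct, cls)
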