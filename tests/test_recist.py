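import numpy as np
import pytest
from scipy import ndimage, stats

from idolseg.recist import (
    classify,
    concordance,
    max_axial_diameter,
    measure_case,
    paired_stats,
    percent_change,
)
from idolseg.reproduce import load_fixtures
from idolseg.volumes import Mask


def brute_force_diameter(m: Mask) -> float:
    """Independent O(n^2) oracle: per slice, largest component, all pairs."""
    dx, dy, _ = m.spacing
    best = 0.0
    for z in range(m.data.shape[2]):
        sl = m.data[:, :, z]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=np.ones((3, 3)))
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        xs, ys = np.nonzero(labels == int(np.argmax(sizes)) + 1)
        pts = np.column_stack([xs * dx, ys * dy])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        best = max(best, float(np.sqrt(d2.max())))
    return best


def random_blob_mask(rng, shape=(24, 24, 4), spacing=(0.7, 0.7, 3.0)) -> Mask:
    m = np.zeros(shape, np.uint8)
    xs, ys, zs = np.meshgrid(*map(np.arange, shape), indexing="ij")
    for _ in range(rng.integers(1, 4)):
        c = rng.integers(3, np.array(shape[:2]) - 3, 2)
        cz = rng.integers(0, shape[2])
        r = rng.integers(1, 7, 2)
        blob = (((xs - c[0]) / r[0]) ** 2 + ((ys - c[1]) / r[1]) ** 2 <= 1) & (
            np.abs(zs - cz) <= 1
        )
        m |= blob.astype(np.uint8)
    return Mask(m, spacing)


class TestMaxAxialDiameter:
    def test_rectangle_corner_to_corner(self):
        """10x4 voxel rectangle at 0.7 mm: sqrt((9*.7)^2 + (3*.7)^2)."""
        m = np.zeros((16, 16, 3), np.uint8)
        m[2:12, 3:7, 1] = 1
        d, z, pair = max_axial_diameter(Mask(m, (0.7, 0.7, 3.0)))
        assert d == pytest.approx(np.hypot(9 * 0.7, 3 * 0.7), abs=1e-9)
        assert z == 1
        assert pair == ((2, 3), (11, 6))

    def test_voxelized_ellipse_near_analytic(self):
        """In-plane semi-axes 20 and 12 mm measure 40 mm within one voxel."""
        shape, sp = (80, 80, 5), (0.7, 0.7, 3.0)
        xs, ys, zs = np.meshgrid(*map(np.arange, shape), indexing="ij")
        x_mm = (xs - 39.5) * sp[0]
        y_mm = (ys - 39.5) * sp[1]
        ell = ((x_mm / 20.0) ** 2 + (y_mm / 12.0) ** 2 <= 1) & (zs == 2)
        d, _, _ = max_axial_diameter(Mask(ell.astype(np.uint8), sp))
        assert d == pytest.approx(40.0, abs=0.7)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = random_blob_mask(rng)
            d, _, _ = max_axial_diameter(m)
            assert d == pytest.approx(brute_force_diameter(m), abs=1e-9)

    def test_empty_mask_measures_zero(self):
        d, z, pair = max_axial_diameter(Mask(np.zeros((6, 6, 3), np.uint8)))
        assert (d, z, pair) == (0.0, None, None)

    def test_anisotropic_inplane_spacing_honored(self):
        m = np.zeros((10, 10, 1), np.uint8)
        m[1:9, 4, 0] = 1  # 8 voxels along x
        d, _, _ = max_axial_diameter(Mask(m, (0.5, 2.0, 3.0)))
        assert d == pytest.approx(7 * 0.5, abs=1e-12)

    def test_monotone_under_dilation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_blob_mask(rng)
            d0, _, _ = max_axial_diameter(m)
            grown = ndimage.binary_dilation(m.data, np.ones((3, 3, 1))).astype(np.uint8)
            d1, _, _ = max_axial_diameter(Mask(grown, m.spacing))
            assert d1 >= d0


class TestClassification:
    def test_percent_change_arithmetic(self):
        assert percent_change(100, 70) == pytest.approx(-30.0)
        assert percent_change(100, 100) == 0.0
        assert percent_change(151.8, 74.3) == pytest.approx(-51.05, abs=0.01)

    def test_percent_change_needs_baseline(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_change(0.0, 10.0)

    @pytest.mark.parametrize(
        "pct,expected",
        [(-52.6, "PR"), (-28.4, "SD"), (-30.0, "PR"), (6.3, "SD"), (-33.7, "PR")],
    )
    def test_response_thresholds(self, pct, expected):
        assert classify(pct) == expected

    def test_complete_response_and_progression(self):
        assert classify(-100.0, d_post=0.0, d_pre=30.0) == "CR"
        assert classify(25.0, d_post=50.0, d_pre=40.0) == "PD"
        # +25% but under the 5 mm absolute minimum stays SD
        assert classify(25.0, d_post=12.5, d_pre=10.0) == "SD"
        assert classify(20.0, d_post=30.0, d_pre=25.0) == "PD"  # inclusive

    def test_scale_invariance_of_pr_sd(self, rng):
        for _ in range(50):
            d_pre = rng.uniform(10, 150)
            d_post = rng.uniform(1, 1.19) * d_pre  # below the PD band
            c = rng.uniform(0.1, 10)
            pct = percent_change(d_pre, d_post)
            assert classify(pct) == classify(percent_change(c * d_pre, c * d_post))

    def test_printed_percent_columns_reproduce_printed_labels(self):
        fx = load_fixtures()
        manual = [classify(round(p, 1)) for p in fx.table4a.pct_manual]
        predicted = [classify(round(p, 1)) for p in fx.table4a.pct_predicted]
        assert manual == list(fx.table4a.class_manual)
        assert predicted == list(fx.table4a.class_predicted)


class TestConcordance:
    def _published_lists(self):
        fx = load_fixtures()
        return list(fx.table4a.class_manual), list(fx.table4a.class_predicted)

    def test_published_table_statistics(self):
        manual, predicted = self._published_lists()
        t = concordance(manual, predicted)
        assert t.counts == ((3, 1), (0, 10))
        assert t.sensitivity == pytest.approx(0.75)
        assert t.specificity == pytest.approx(1.00)
        assert t.auc == pytest.approx(0.875)
        assert t.n_concordant == 13
        assert t.mcnemar_p == pytest.approx(1.0)

    def test_exact_mcnemar_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 6, 4)
            if a + b == 0 or c + d == 0:
                continue
            manual = ["PR"] * (a + b) + ["SD"] * (c + d)
            pred = ["PR"] * a + ["SD"] * b + ["PR"] * c + ["SD"] * d
            t = concordance(manual, pred)
            ref = sm_mcnemar([[a, b], [c, d]], exact=True).pvalue
            assert t.mcnemar_p == pytest.approx(ref, abs=1e-12)

    def test_rejects_multiclass(self):
        with pytest.raises(ValueError, match="PR, SD"):
            concordance(["PR", "PD"], ["SD", "SD"])

    def test_undefined_rates_flagged_as_none(self):
        t = concordance(["SD", "SD"], ["SD", "PR"])
        assert t.sensitivity is None and t.auc is None
        assert t.specificity == pytest.approx(0.5)


class TestPairedStats:
    def test_published_diameter_columns(self):
        fx = load_fixtures()
        res = paired_stats(fx.table4a.d_post_manual_mm, fx.table4a.d_post_predicted_mm)
        assert res["mean_diff"] == pytest.approx(9.2, abs=0.05)
        assert res["p_t"] == pytest.approx(0.032, abs=0.0005)

    def test_identity_and_monotone(self):
        x = [1.0, 5.0, 9.0, 14.0]
        res = paired_stats(x, x)
        assert res["mean_diff"] == 0.0
        assert res["wilcoxon_p"] is None
        res2 = paired_stats(x, [2.0, 7.0, 20.0, 30.0])
        assert res2["spearman_rho"] == pytest.approx(1.0)

    def test_matches_scipy_reference(self, rng):
        x = rng.normal(50, 10, 12)
        y = x + rng.normal(2, 3, 12)
        res = paired_stats(x, y)
        assert res["p_t"] == pytest.approx(stats.ttest_rel(y, x).pvalue)
        assert res["wilcoxon_p"] == pytest.approx(stats.wilcoxon(y, x).pvalue)


class TestMeasureCase:
    def test_end_to_end_record(self):
        pre = np.zeros((30, 30, 3), np.uint8)
        pre[5:25, 14:17, 1] = 1  # 20 voxels -> 19*1 mm
        post = np.zeros_like(pre)
        post[9:21, 14:17, 1] = 1  # 12 voxels -> 11*1 mm
        rec = measure_case("c", Mask(pre, (1, 1, 3)), Mask(post, (1, 1, 3)))
        assert rec.d_pre_mm == pytest.approx(np.hypot(19, 2), abs=1e-9)
        assert rec.response_class in {"PR", "SD"}
        assert rec.pct_change == pytest.approx(
            100 * (rec.d_post_mm - rec.d_pre_mm) / rec.d_pre_mm
        )
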