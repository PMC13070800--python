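import numpy as np
import pytest
from dataclasses import replace

from idolseg.phantom import PhantomConfig, generate_case, generate_cohort
from idolseg.recist import max_axial_diameter


class TestGenerateCase:
    def test_deterministic_given_seed(self):
        cfg = PhantomConfig(seed=3)
        a, ta = generate_case(cfg, "c")
        b, tb = generate_case(cfg, "c")
        np.testing.assert_array_equal(a.ct_pre.data, b.ct_pre.data)
        np.testing.assert_array_equal(a.ct_post.data, b.ct_post.data)
        np.testing.assert_array_equal(a.tumor_post.data, b.tumor_post.data)
        assert ta == tb

    def test_identity_case_masks_equal(self):
        cfg = PhantomConfig(
            seed=5, shrink_factor=1.0, edema_thickness=0.0, liver_scale_post=1.0
        )
        case, truth = generate_case(cfg, "id")
        np.testing.assert_array_equal(case.tumor_pre.data, case.tumor_post.data)
        assert truth.true_response_class == "SD"

    def test_sphere_scaling_matches_analytic(self):
        """Radius-20 mm sphere shrunk by 0.6: post diameter 24 mm +- a voxel."""
        cfg = PhantomConfig(
            seed=1,
            shape=(96, 96, 24),
            spacing=(0.7, 0.7, 3.0),
            liver_semiaxes=(30.0, 30.0, 33.0),
            tumor_n_lobes=1,
            tumor_semiaxes_range=(20.0, 20.0),
            shrink_factor=0.6,
            edema_thickness=0.0,
            liver_scale_post=1.0,
        )
        case, truth = generate_case(cfg, "sphere")
        assert truth.pre_mask_diameter_mm == pytest.approx(40.0, abs=0.7)
        assert truth.post_mask_diameter_mm == pytest.approx(24.0, abs=0.7)

    def test_tumor_outside_liver_rejected_before_render(self):
        cfg = PhantomConfig(tumor_semiaxes_range=(60.0, 70.0), seed=0)
        with pytest.raises(ValueError, match="does not fit"):
            generate_case(cfg, "bad")

    def test_edema_ring_outside_truth_mask(self):
        case, _ = generate_case(PhantomConfig(seed=9, edema_thickness=5.0), "e")
        im = case.ct_post.data
        tumor = case.tumor_post.data.astype(bool)
        # edema-intensity voxels exist near but outside the ground-truth mask
        from scipy import ndimage

        ring = ndimage.binary_dilation(tumor, iterations=2) & ~tumor
        assert ring.any()
        ring_mean = im[ring].mean()
        assert im[tumor].mean() < ring_mean < 105.0

    def test_masks_are_exact_voxelizations(self):
        case, _ = generate_case(PhantomConfig(seed=2), "v")
        assert set(np.unique(case.tumor_pre.data)) <= {0, 1}
        assert case.tumor_pre.voxel_count() > 0
        assert case.tumor_post.voxel_count() > 0


class TestShrinkMonotonicity:
    def test_smaller_shrink_never_larger_post_diameter(self):
        base = PhantomConfig(seed=4)
        diams = []
        for s in (1.0, 0.85, 0.7, 0.55, 0.4):
            case, truth = generate_case(replace(base, shrink_factor=s), "m")
            diams.append(truth.post_mask_diameter_mm)
        assert all(a >= b for a, b in zip(diams, diams[1:]))


class TestGenerateCohort:
    def test_reproducible_and_complete(self):
        tr1, va1, t1 = generate_cohort(6, 3, seed=7)
        tr2, va2, t2 = generate_cohort(6, 3, seed=7)
        assert len(tr1) == 6 and len(va1) == 3 and len(t1) == 9
        for a, b in zip(tr1 + va1, tr2 + va2):
            np.testing.assert_array_equal(a.ct_pre.data, b.ct_pre.data)

    def test_degenerate_shrink_ranges_fix_response_class(self):
        _, _, truths_pr = generate_cohort(2, 2, shrink_range=(0.6, 0.6), seed=1)
        assert all(t.true_response_class == "PR" for t in truths_pr)
        _, _, truths_sd = generate_cohort(2, 2, shrink_range=(0.95, 1.0), seed=1)
        assert all(t.true_response_class == "SD" for t in truths_sd)

    def test_truth_diameter_consistent_with_shrink(self):
        _, _, truths = generate_cohort(4, 2, seed=13)
        for t in truths:
            expected = t.shrink_factor * t.pre_mask_diameter_mm
            # voxelization quantizes each measurement by about one voxel
            assert t.post_mask_diameter_mm == pytest.approx(expected, abs=2 * 1.4)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"shrink_factor": 0.0}, "shrink_factor"),
            ({"liver_scale_post": 1.5}, "liver_scale_post"),
            ({"tumor_n_lobes": 0}, "lobes"),
            ({"tumor_semiaxes_range": (5.0, 2.0)}, "range"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            generate_case(PhantomConfig(**kwargs), "x")
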