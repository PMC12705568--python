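"""Spatial normalization, tissue segmentation, GLM t-maps, GM masks."""

import numpy as np
import pytest
from scipy import ndimage, stats

from neurofuse import (
    BrainMask,
    PhantomSpec,
    TissueMaps,
    VolumeImage,
    generate_subject,
    glm_tmap,
    gm_mask,
    segment_tissues,
    skull_strip,
    spatial_normalize,
    zscore_normalize,
)
from neurofuse.image import DegenerateInputError, InvalidParameterError
from neurofuse.vbm import resample


@pytest.fixture(scope="module")
def template():
    spec = PhantomSpec(noise_sd=0.0)
    return generate_subject(spec, 0, 0, jitter=False).mri


class TestSpatialNormalize:
    def test_self_registration_is_identity(self, template):
        _, tr = spatial_normalize(template, template)
        assert np.all(np.abs(tr.translation) < 0.5)
        assert abs(tr.scale - 1.0) < 0.01

    def test_translation_recovery(self, template):
        subject = template.with_data(ndimage.shift(template.data, (3, -2), order=1))
        resampled, tr = spatial_normalize(subject, template)
        assert tr.translation == pytest.approx([-3.0, 2.0], abs=0.5)
        # after resampling the subject overlays the template
        corr = np.corrcoef(resampled.data.ravel(), template.data.ravel())[0, 1]
        assert corr > 0.99

    def test_scale_recovery(self, template):
        from neurofuse.vbm import AffineTransform, _params_to_affine

        center = (np.array(template.shape, float) - 1) / 2
        grow = _params_to_affine(np.array([0.0, 0.0, 0.0, np.log(1.1)]), 2, center)
        subject = resample(template, grow, template.shape)
        _, tr = spatial_normalize(subject, template)
        assert tr.scale == pytest.approx(1 / 1.1, rel=0.02)

    def test_empty_images_rejected(self, template):
        with pytest.raises(DegenerateInputError):
            spatial_normalize(VolumeImage(np.zeros((8, 8)) + 1e-30), template)


class TestSegmentTissues:
    def _three_gaussian_image(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, size=(n, n))
        means = np.array([-2.0, 0.0, 2.0])
        img = rng.normal(means[labels], 0.2)
        return VolumeImage(img), BrainMask(np.ones((n, n), np.uint8)), labels

    def test_well_separated_components_recovered(self):
        img, mask, labels = self._three_gaussian_image()
        tissues = segment_tissues(img, mask, seed=0)
        hard = np.argmax(np.stack([tissues.csf, tissues.gm, tissues.wm]), axis=0)
        assert (hard == labels).mean() >= 0.99  # CSF < GM < WM by intensity

    def test_posteriors_sum_to_one_in_mask(self):
        img, mask, _ = self._three_gaussian_image(seed=1, n=30)
        t = segment_tissues(img, mask, seed=0)
        total = t.gm + t.wm + t.csf
        assert np.allclose(total[mask.as_bool()], 1.0, atol=1e-6)

    def test_seeded_determinism_bitwise(self):
        img, mask, _ = self._three_gaussian_image(seed=2, n=40)
        t1 = segment_tissues(img, mask, seed=5)
        t2 = segment_tissues(img, mask, seed=5)
        for a, b in ((t1.gm, t2.gm), (t1.wm, t2.wm), (t1.csf, t2.csf)):
            assert np.array_equal(a, b)

    def test_insufficient_voxels_rejected(self):
        img = VolumeImage(np.random.default_rng(0).normal(size=(5, 5)))
        mask = BrainMask(np.zeros((5, 5), np.uint8))
        mask.data[0, :4] = 1
        with pytest.raises(DegenerateInputError):
            segment_tissues(img, mask, seed=0)


class TestGlmTmap:
    def test_identical_groups_give_zero(self):
        grids = [np.random.default_rng(i).normal(size=(6, 6)) for i in range(3)]
        sm = glm_tmap(grids, list(grids))
        assert np.all(sm.t_values == 0)
        assert sm.df == 4

    def test_hand_computed_voxel(self):
        a = [np.array([[1.0]]), np.array([[2.0]]), np.array([[3.0]])]
        b = [np.array([[4.0]]), np.array([[5.0]]), np.array([[6.0]])]
        sm = glm_tmap(a, b)
        assert sm.t_values[0, 0] == pytest.approx(-3.674, abs=1e-3)
        assert sm.df == 4

    def test_small_groups_rejected(self):
        g = [np.zeros((2, 2))]
        with pytest.raises(InvalidParameterError):
            glm_tmap(g, g * 3)

    def test_null_distribution_matches_t(self):
        rng = np.random.default_rng(0)
        a = [rng.normal(size=10_000) for _ in range(10)]
        b = [rng.normal(size=10_000) for _ in range(10)]
        sm = glm_tmap(a, b)
        ks = stats.kstest(sm.t_values, stats.t(df=sm.df).cdf).statistic
        assert ks < 0.02

    def test_zero_variance_voxels_get_zero(self):
        a = [np.array([1.0, 5.0]), np.array([1.0, 6.0]), np.array([1.0, 7.0])]
        b = [np.array([1.0, 1.0]), np.array([1.0, 2.0]), np.array([1.0, 3.0])]
        sm = glm_tmap(a, b)
        assert sm.t_values[0] == 0.0
        assert sm.t_values[1] != 0.0


class TestGmMask:
    def test_inclusive_threshold(self):
        gm = np.array([[0.4, 0.5, 0.6]])
        t = TissueMaps(gm=gm, wm=1 - gm, csf=np.zeros_like(gm))
        assert list(gm_mask(t, 0.5).data[0]) == [0, 1, 1]

    def test_all_high_probability(self):
        gm = np.full((3, 3), 0.9)
        t = TissueMaps(gm=gm, wm=np.full((3, 3), 0.1), csf=np.zeros((3, 3)))
        assert gm_mask(t, 0.5).n_voxels == 9

    def test_invalid_threshold(self):
        t = TissueMaps(gm=np.zeros((2, 2)), wm=np.zeros((2, 2)), csf=np.zeros((2, 2)))
        for thr in (0.0, 1.0, -0.5):
            with pytest.raises(InvalidParameterError):
                gm_mask(t, thr)

    def test_phantom_ring_dice(self):
        pair = generate_subject(PhantomSpec(), 0, 1)
        stripped, mask = skull_strip(pair.mri)
        z = zscore_normalize(stripped, mask)
        tissues = segment_tissues(z, mask, seed=0)
        gmask = gm_mask(tissues).as_bool()
        ring = pair.ground_truth["gm_ring_mask"]
        dice = 2 * (gmask & ring).sum() / (gmask.sum() + ring.sum())
        assert dice >= 0.9


class TestPlantedAtrophyContrast:
    def test_group_tmap_peaks_in_planted_region(self):
        hits = 0
        for seed in range(3):
            spec = PhantomSpec(seed=seed, n_per_class=10)
            gm_maps = {0: [], 3: []}
            region = None
            for cls in (0, 3):
                for k in range(10):
                    pair = generate_subject(spec, cls, k)
                    stripped, mask = skull_strip(pair.mri)
                    z = zscore_normalize(stripped, mask)
                    t = segment_tissues(z, mask, seed=spec.seed)
                    gm_maps[cls].append(t.gm)
                    if cls == 3:
                        region = pair.ground_truth["atrophy_mask"]
            sm = glm_tmap(gm_maps[0], gm_maps[3])
            dilated = np.asarray(region, bool)
            dilated = ndimage.binary_dilation(dilated, iterations=3)
            peak = np.unravel_index(np.argmax(np.abs(sm.t_values)), sm.t_values.shape)
            if dilated[peak]:
                hits += 1
            inside = np.abs(sm.t_values)[dilated].mean()
            outside = np.abs(sm.t_values)[~dilated].mean()
            assert inside > outside
        assert hits >= 2
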