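"""Unit and property tests for MTR maps, histogram summaries and volumetrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from msqmri import (
    VolumeImage,
    compute_mtr_map,
    compute_volumetrics,
    derive_normal_appearing_masks,
    extract_scan_traits,
    summarize_mtr_histogram,
)
from msqmri.cohort import CohortConfig, simulate_scan_images
from msqmri.errors import AlignmentError, FormatError
from msqmri.image_traits import LABEL_CSF, LABEL_GM, LABEL_WM, TRAIT_NAMES


def vol(arr, **kw):
    return VolumeImage(np.asarray(arr, dtype=float), **kw)


class TestComputeMtrMap:
    def test_direct_substitution(self):
        m0 = vol(np.full((8, 8, 8), 2.0))
        ms = vol(np.full((8, 8, 8), 1.0))
        assert np.allclose(compute_mtr_map(m0, ms).data, 50.0)

    def test_identical_images_give_zero(self):
        m0 = vol(np.random.default_rng(0).uniform(1, 5, (8, 8, 8)))
        assert np.allclose(compute_mtr_map(m0, m0).data, 0.0)

    def test_nonpositive_m0_is_missing_not_an_error(self):
        m0 = vol(np.full((8, 8, 8), 2.0))
        m0.data[0, 0, 0] = 0.0
        m0.data[0, 0, 1] = -1.0
        mtr = compute_mtr_map(m0, vol(np.ones((8, 8, 8)))).data
        assert np.isnan(mtr[0, 0, 0]) and np.isnan(mtr[0, 0, 1])
        assert np.isfinite(mtr[1:]).all()

    def test_space_mismatch_raises(self):
        m0 = vol(np.ones((8, 8, 8)), space_tag="a")
        ms = vol(np.ones((8, 8, 8)), space_tag="b")
        with pytest.raises(AlignmentError):
            compute_mtr_map(m0, ms)

    @given(alpha=st.floats(0.1, 10.0))
    def test_invariant_under_joint_rescaling(self, alpha):
        rng = np.random.default_rng(42)
        m0 = rng.uniform(1, 5, (6, 6, 6))
        ms = m0 * rng.uniform(0.5, 1.0, (6, 6, 6))
        base = compute_mtr_map(vol(m0), vol(ms)).data
        scaled = compute_mtr_map(vol(alpha * m0), vol(alpha * ms)).data
        assert np.allclose(base, scaled, rtol=1e-9)


class TestNormalAppearingMasks:
    def test_empty_lesion_mask_passes_tissue_through(self):
        rng = np.random.default_rng(1)
        hard = rng.integers(0, 4, (8, 8, 8))
        masks = derive_normal_appearing_masks(hard, np.zeros_like(hard, dtype=bool))
        assert np.array_equal(masks.nagm, hard == LABEL_GM)
        assert np.array_equal(masks.nawm, hard == LABEL_WM)

    def test_lesion_covering_all_wm_empties_nawm(self):
        rng = np.random.default_rng(2)
        hard = rng.integers(0, 4, (8, 8, 8))
        masks = derive_normal_appearing_masks(hard, hard == LABEL_WM)
        assert not masks.nawm.any()
        assert np.array_equal(masks.nagm, hard == LABEL_GM)

    def test_set_identities_by_voxelwise_enumeration(self):
        rng = np.random.default_rng(3)
        hard = rng.integers(0, 4, (16, 16, 16))
        lesion = rng.random((16, 16, 16)) < 0.2
        masks = derive_normal_appearing_masks(hard, lesion)
        for x in range(16):
            for y in range(16):
                for z in range(16):
                    assert masks.nagm[x, y, z] == (hard[x, y, z] == LABEL_GM and not lesion[x, y, z])
                    assert masks.nawm[x, y, z] == (hard[x, y, z] == LABEL_WM and not lesion[x, y, z])
        assert not (masks.nagm & lesion).any()
        assert not (masks.nawm & lesion).any()

    def test_unknown_labels_raise(self):
        hard = np.full((8, 8, 8), 7)
        with pytest.raises(FormatError):
            derive_normal_appearing_masks(hard, np.zeros((8, 8, 8), bool))

    def test_kappa1_must_be_inside_kappa0(self):
        hard = np.full((8, 8, 8), LABEL_WM)
        k0 = np.zeros((8, 8, 8), bool)
        k1 = np.zeros((8, 8, 8), bool)
        k1[0, 0, 0] = True
        with pytest.raises(FormatError):
            derive_normal_appearing_masks(hard, k0, k1)


class TestHistogramSummary:
    def test_constant_histogram(self):
        mtr = vol(np.full((8, 8, 8), 37.25))
        s = summarize_mtr_histogram(mtr, np.ones((8, 8, 8), bool))
        assert s.median == 37.25
        assert s.mean90 == 37.25
        assert s.peak_height == 100.0
        assert s.peak_location == 37.5  # center of the [37, 38) bin

    def test_five_values_against_sorted_oracle(self):
        vals = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        data = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        data.flat[:5] = vals
        mask.flat[:5] = True
        s = summarize_mtr_histogram(vol(data), mask, bin_width=10.0)
        assert s.median == 30.0
        # oracle: explicit percentiles + mean over the [P5, P95] subset
        p5, p95 = np.percentile(vals, [5, 95])
        expected_mean90 = np.mean(sorted(v for v in vals if p5 <= v <= p95))
        assert s.mean90 == pytest.approx(expected_mean90)
        assert expected_mean90 == 30.0  # {20, 30, 40}

    def test_large_normal_sample_against_sample_statistics(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(38, 2, 10**5)
        shape = (50, 50, 40)
        mtr = vol(draws.reshape(shape))
        s = summarize_mtr_histogram(mtr, np.ones(shape, bool), bin_width=1.0)
        assert s.peak_location in (37.5, 38.5)
        assert s.median == pytest.approx(np.percentile(draws, 50), abs=1e-12)
        assert abs(s.median - 38.0) < 0.05

    def test_out_of_range_voxels_excluded_and_denominator_adjusted(self):
        data = np.full((8, 8, 8), 40.0)
        data.flat[:100] = -5.0  # below valid range
        data.flat[100:110] = np.nan
        s = summarize_mtr_histogram(vol(data), np.ones((8, 8, 8), bool))
        assert s.n_voxels == 512 - 110
        assert s.peak_height == 100.0

    def test_empty_mask_flags_missing(self):
        s = summarize_mtr_histogram(vol(np.ones((8, 8, 8))), np.zeros((8, 8, 8), bool))
        assert s.is_missing and s.n_voxels == 0

    @given(shift=st.floats(-5, 5))
    def test_median_and_mean90_shift_equivariance(self, shift):
        rng = np.random.default_rng(6)
        data = rng.uniform(30, 50, (10, 10, 10))
        mask = rng.random((10, 10, 10)) < 0.7
        s0 = summarize_mtr_histogram(vol(data), mask)
        s1 = summarize_mtr_histogram(vol(data + shift), mask)
        assert s1.median == pytest.approx(s0.median + shift, abs=1e-9)
        assert s1.mean90 == pytest.approx(s0.mean90 + shift, abs=1e-9)

    def test_invariant_to_voxel_ordering(self):
        rng = np.random.default_rng(7)
        data = rng.uniform(20, 60, (10, 10, 10))
        mask = rng.random((10, 10, 10)) < 0.5
        s0 = summarize_mtr_histogram(vol(data), mask)
        perm = rng.permutation(data.size)
        s1 = summarize_mtr_histogram(
            vol(data.flat[perm].reshape(data.shape)),
            mask.flat[perm].reshape(mask.shape),
        )
        assert (s0.median, s0.peak_height, s0.peak_location, s0.mean90, s0.n_voxels) == (
            s1.median, s1.peak_height, s1.peak_location, s1.mean90, s1.n_voxels)


class TestVolumetrics:
    def test_pure_gm_block(self):
        shape = (10, 10, 10)
        soft = {"gm": np.ones(shape), "wm": np.zeros(shape), "csf": np.zeros(shape)}
        v = compute_volumetrics(soft, np.zeros(shape, bool), (1, 1, 1))
        assert v.gm_volume == pytest.approx(1.0)  # 1000 mm^3 = 1 ml
        assert v.total_brain_volume == pytest.approx(1.0)
        assert v.gm_pct == pytest.approx(100.0)

    def test_equal_thirds(self):
        shape = (6, 6, 6)
        soft = {c: np.full(shape, 1 / 3) for c in ("gm", "wm", "csf")}
        v = compute_volumetrics(soft, np.zeros(shape, bool), (1, 1, 1))
        assert v.gm_pct == pytest.approx(100 / 3)
        assert v.wm_pct == pytest.approx(100 / 3)

    def test_random_soft_seg_matches_brute_force_summation(self):
        rng = np.random.default_rng(8)
        shape = (16, 16, 16)
        raw = rng.dirichlet(np.ones(3), size=shape)
        soft = {"gm": raw[..., 0], "wm": raw[..., 1], "csf": raw[..., 2]}
        lesion = rng.random(shape) < 0.1
        voxel = (1.0, 1.2, 0.8)
        v = compute_volumetrics(soft, lesion, voxel)
        vox_ml = 1.0 * 1.2 * 0.8 / 1000.0
        # voxel-by-voxel oracle
        gm = sum(soft["gm"][i] for i in np.ndindex(shape)) * vox_ml
        assert v.gm_volume == pytest.approx(gm, rel=1e-12)
        assert v.lesion_volume == pytest.approx(lesion.sum() * vox_ml, rel=1e-12)
        assert v.total_brain_volume == pytest.approx(
            v.gm_volume + v.wm_volume + v.csf_volume, abs=1e-12)
        assert v.gm_pct + v.wm_pct + v.csf_pct == pytest.approx(100.0, abs=1e-9)

    def test_probability_outside_unit_interval_raises(self):
        shape = (6, 6, 6)
        soft = {"gm": np.full(shape, 1.2), "wm": np.zeros(shape), "csf": np.zeros(shape)}
        with pytest.raises(FormatError):
            compute_volumetrics(soft, np.zeros(shape, bool), (1, 1, 1))


class TestExtractScanTraits:
    def _noise_free_scan(self):
        cfg = CohortConfig(mtr_noise_sd=0.0, m0_noise_sd=0.0)
        latents = {
            "lesion_mtr_median": 30.0, "nawm_mtr_median": 38.0, "nagm_mtr_median": 32.0,
            "lesion_mtr_peak_height": 8.0, "nawm_mtr_peak_height": 14.0,
            "nagm_mtr_peak_height": 11.0, "total_brain_volume": 16.0,
            "wm_pct": 40.0, "gm_pct": 45.0, "lesion_volume": 0.5,
        }
        return latents, simulate_scan_images(latents, cfg, rng=np.random.default_rng(9))

    def test_noise_free_round_trip_recovers_medians(self):
        latents, (m0, ms, soft, hard, lesion) = self._noise_free_scan()
        st_ = extract_scan_traits(m0, ms, hard, soft, lesion, lesion)
        assert st_.traits["lesion_mtr_median"] == pytest.approx(30.0, abs=1e-9)
        assert st_.traits["nawm_mtr_median"] == pytest.approx(38.0, abs=1e-9)
        assert st_.traits["nagm_mtr_median"] == pytest.approx(32.0, abs=1e-9)

    def test_empty_lesion_mask_gives_missing_mtr_and_zero_volume(self):
        latents, (m0, ms, soft, hard, lesion) = self._noise_free_scan()
        empty = np.zeros_like(lesion)
        st_ = extract_scan_traits(m0, ms, hard, soft, empty, empty)
        assert np.isnan(st_.traits["lesion_mtr_median"])
        assert np.isnan(st_.traits["lesion_mtr_peak_height"])
        assert st_.traits["lesion_volume"] == 0.0

    def test_all_traits_match_componentwise_oracles(self):
        cfg = CohortConfig()
        latents = {t: m for t, m in zip(
            TRAIT_NAMES, (30.0, 38.0, 32.0, 8.0, 14.0, 11.0, 16.0, 40.0, 45.0, 0.5))}
        m0, ms, soft, hard, lesion = simulate_scan_images(latents, cfg, rng=np.random.default_rng(10))
        st_ = extract_scan_traits(m0, ms, hard, soft, lesion, lesion)
        mtr = compute_mtr_map(m0, ms)
        masks = derive_normal_appearing_masks(hard, lesion, lesion)
        for tissue, mask in (("lesion", masks.lesion), ("nawm", masks.nawm), ("nagm", masks.nagm)):
            s = summarize_mtr_histogram(mtr, mask)
            assert st_.traits[f"{tissue}_mtr_median"] == pytest.approx(s.median)
            assert st_.traits[f"{tissue}_mtr_peak_height"] == pytest.approx(s.peak_height)
        v = compute_volumetrics(soft, lesion, m0.voxel_size)
        assert st_.traits["total_brain_volume"] == pytest.approx(v.total_brain_volume)
        assert st_.traits["wm_pct"] == pytest.approx(v.wm_pct)
        assert st_.traits["gm_pct"] == pytest.approx(v.gm_pct)
        assert st_.traits["lesion_volume"] == pytest.approx(v.lesion_volume)


def test_nifti_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    img = VolumeImage(rng.uniform(0, 1, (9, 9, 9)), voxel_size=(1.0, 1.5, 2.0))
    img.to_nifti(tmp_path / "x.nii")
    back = VolumeImage.from_nifti(tmp_path / "x.nii")
    assert np.allclose(back.data, img.data, atol=1e-6)
    assert back.voxel_size == pytest.approx(img.voxel_size)
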