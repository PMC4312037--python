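import dataclasses
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from murine_dce_quant import ct_quant, phantom, pipeline
from murine_dce_quant.ct_quant import (
    SeedRejectedError, SegmentationParams, ejection_fraction, grow_region,
    hu_calibrate, mask_volume_mm3, percent_infarct_ct, roi_mean_hu,
    segment_infarct, segment_lv_blood, segment_myocardium,
)
from murine_dce_quant.phantom import (
    INFARCT, LV_BLOOD, MYOCARDIUM, PhantomSpec, VoxelVolume,
    build_heart_phantom,
)
from conftest import infarct_wedge, segment_blood_auto


def flood_fill_oracle(values, seeds, low, high, connectivity):
    """Brute-force BFS flood fill, independent of the implementation."""
    if connectivity == 6:
        nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)]
    else:
        nbrs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    shape = values.shape
    mask = np.zeros(shape, dtype=bool)
    queue = deque(seeds)
    for s in seeds:
        mask[s] = True
    while queue:
        p = queue.popleft()
        for d in nbrs:
            q = tuple(p[i] + d[i] for i in range(3))
            if all(0 <= q[i] < shape[i] for i in range(3)) and not mask[q] \
                    and low <= values[q] <= high:
                mask[q] = True
                queue.append(q)
    return mask


class TestHUCalibration:
    def test_water_air_anchors(self):
        raw = np.array([[[0.2, 0.0, 0.1]]])  # water, air, midway
        vol = hu_calibrate(raw, mu_water=0.2, mu_air=0.0)
        assert vol.values[0, 0, 0] == 0.0
        assert vol.values[0, 0, 1] == -1000.0
        assert vol.values[0, 0, 2] == -500.0

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hu_calibrate(np.zeros((2, 2, 2)), mu_water=0.1, mu_air=0.1)


class TestGrowRegion:
    def test_uniform_volume_fills_grid(self):
        vol = VoxelVolume(np.full((5, 5, 5), 100.0), spacing_mm=1.0)
        mask = grow_region(vol, [(2, 2, 2)], (50.0, 150.0))
        assert mask.all()

    def test_wall_blocks_growth(self):
        values = np.full((9, 9, 9), 100.0)
        values[4, :, :] = 900.0  # out-of-range wall splits the grid
        vol = VoxelVolume(values, spacing_mm=1.0)
        mask = grow_region(vol, [(1, 4, 4)], (50.0, 150.0))
        oracle = flood_fill_oracle(values, [(1, 4, 4)], 50.0, 150.0, 6)
        assert np.array_equal(mask, oracle)
        assert not mask[5:, :, :].any()

    def test_out_of_range_seed_rejected(self):
        vol = VoxelVolume(np.full((4, 4, 4), 100.0), spacing_mm=1.0)
        with pytest.raises(SeedRejectedError, match=r"\(1, 1, 1\)"):
            grow_region(vol, [(1, 1, 1)], (200.0, 300.0))

    def test_empty_seed_list_rejected(self):
        vol = VoxelVolume(np.full((4, 4, 4), 100.0), spacing_mm=1.0)
        with pytest.raises(ValueError):
            grow_region(vol, [], (50.0, 150.0))

    @given(data=st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_flood_fill_on_random_grids(self, data):
        shape = tuple(data.draw(st.integers(2, 12), label=f"dim{i}")
                      for i in range(3))
        rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 20)))
        values = rng.integers(0, 4, size=shape).astype(float)
        connectivity = data.draw(st.sampled_from([6, 26]))
        in_range = np.argwhere((values >= 1.0) & (values <= 2.0))
        if len(in_range) == 0:
            return
        seed = tuple(in_range[data.draw(
            st.integers(0, len(in_range) - 1))].tolist())
        vol = VoxelVolume(values, spacing_mm=1.0)
        mask = grow_region(vol, [seed], (1.0, 2.0), connectivity)
        oracle = flood_fill_oracle(values, [seed], 1.0, 2.0, connectivity)
        assert np.array_equal(mask, oracle)


class TestBloodSegmentation:
    def test_noisefree_mask_equals_truth_exactly(self):
        spec = PhantomSpec.from_ef(0.36, noise_sd_hu=0.0, seed=1)
        vol, mask = build_heart_phantom(spec, "diastole", 13.0)
        params = SegmentationParams(blood_hu_range=(300.0, 600.0))
        got = segment_blood_auto(vol, params)
        assert np.array_equal(got, mask.labels == LV_BLOOD)

    def test_noisy_dice_above_095(self, noisy_bloodpool_pair):
        (vol, mask), _ = noisy_bloodpool_pair
        got = segment_blood_auto(vol)
        truth = mask.labels == LV_BLOOD
        dice = 2 * np.count_nonzero(got & truth) / (
            np.count_nonzero(got) + np.count_nonzero(truth))
        assert dice >= 0.95

    def test_systole_smaller_than_diastole(self, noisy_bloodpool_pair):
        (dia, _), (sys_, _) = noisy_bloodpool_pair
        v_dia = mask_volume_mm3(segment_blood_auto(dia), dia.spacing_mm)
        v_sys = mask_volume_mm3(segment_blood_auto(sys_), sys_.spacing_mm)
        assert v_sys < v_dia


class TestVolumesAndEF:
    def test_mask_volume_arithmetic(self):
        assert mask_volume_mm3(np.zeros((3, 3, 3), bool), 1.0) == 0.0
        mask = np.zeros((10, 10, 10), bool)
        mask[:10, :10, :10] = True
        assert mask_volume_mm3(mask, 1.0) == pytest.approx(1000.0)
        one = np.zeros((1, 1, 1000), bool)
        one[:] = True
        assert mask_volume_mm3(one, 0.077) == pytest.approx(1000 * 0.077 ** 3)

    def test_ef_examples(self):
        assert ejection_fraction(50.0, 32.0) == pytest.approx(0.36)
        assert ejection_fraction(40.0, 40.0) == 0.0
        assert ejection_fraction(40.0, 0.0) == 1.0

    def test_negative_ef_warns_not_clamps(self):
        with pytest.warns(UserWarning, match="negative"):
            ef = ejection_fraction(30.0, 40.0)
        assert ef == pytest.approx(-1.0 / 3.0)

    def test_nonpositive_diastolic_volume_rejected(self):
        with pytest.raises(ValueError):
            ejection_fraction(0.0, 1.0)

    def test_ef_recovery_within_003(self):
        params = SegmentationParams()
        for true_ef, seed in [(0.36, 21), (0.59, 22)]:
            spec = PhantomSpec.from_ef(true_ef, noise_sd_hu=30.0, seed=seed)
            vols = {}
            for phase in ("diastole", "systole"):
                vol, _ = build_heart_phantom(spec, phase, 5.0,
                                             washout=spec.washout_blood_pool)
                vols[phase] = mask_volume_mm3(segment_blood_auto(vol, params),
                                              vol.spacing_mm)
            ef = ejection_fraction(vols["diastole"], vols["systole"])
            assert ef == pytest.approx(true_ef, abs=0.03)


class TestMyocardiumAndInfarct:
    def test_myocardium_band_dice_above_09(self, noisy_spec,
                                           noisy_bloodpool_pair):
        (dia, mask), _ = noisy_bloodpool_pair
        blood = segment_blood_auto(dia)
        band = segment_myocardium(dia, blood, SegmentationParams())
        truth = (mask.labels == MYOCARDIUM) | (mask.labels == INFARCT)
        dice = 2 * np.count_nonzero(band & truth) / (
            np.count_nonzero(band) + np.count_nonzero(truth))
        assert dice >= 0.9
        assert not (band & blood).any()

    def test_zero_band_thickness_is_empty(self, noisy_bloodpool_pair):
        (dia, _), _ = noisy_bloodpool_pair
        blood = segment_blood_auto(dia)
        params = SegmentationParams(wall_thickness_mm=0.0)
        assert not segment_myocardium(dia, blood, params).any()

    def test_empty_blood_mask_rejected(self, noisy_bloodpool_pair):
        (dia, _), _ = noisy_bloodpool_pair
        with pytest.raises(ValueError):
            segment_myocardium(dia, np.zeros(dia.shape, bool),
                               SegmentationParams())

    def test_noisefree_infarct_recovered_exactly(self, noisefree_delayed):
        vol, mask = noisefree_delayed
        myo = (mask.labels == MYOCARDIUM) | (mask.labels == INFARCT)
        got = segment_infarct(vol, myo, SegmentationParams())
        assert np.array_equal(got, mask.labels == INFARCT)

    def test_noisefree_without_infarct_is_empty(self):
        spec = PhantomSpec.from_ef(0.36, noise_sd_hu=0.0, seed=3)
        vol, mask = build_heart_phantom(spec, "diastole", 13.0)
        myo = mask.labels == MYOCARDIUM
        assert not segment_infarct(vol, myo, SegmentationParams()).any()

    def test_noisy_infarct_volume_within_10pct(self, noisy_spec):
        vol, mask = build_heart_phantom(noisy_spec, "diastole", 13.0, seed=31)
        myo = (mask.labels == MYOCARDIUM) | (mask.labels == INFARCT)
        got = segment_infarct(vol, myo, SegmentationParams())
        truth = mask.count(INFARCT)
        assert np.count_nonzero(got) == pytest.approx(truth, rel=0.10)

    def test_empty_myocardium_rejected(self, noisefree_delayed):
        vol, _ = noisefree_delayed
        with pytest.raises(ValueError):
            segment_infarct(vol, np.zeros(vol.shape, bool),
                            SegmentationParams())

    def test_hu_shift_invariance(self, noisy_spec):
        """Shifting all HU by a constant (and the blood window equally)
        leaves every mask unchanged; the infarct threshold is data-driven."""
        vol, mask = build_heart_phantom(noisy_spec, "diastole", 5.0, seed=8,
                                        washout=noisy_spec.washout_blood_pool)
        shift = 150.0
        shifted = VoxelVolume(vol.values + shift, vol.spacing_mm,
                              vol.origin_mm)
        params = SegmentationParams()
        p_shift = dataclasses.replace(
            params, blood_hu_range=(params.blood_hu_range[0] + shift,
                                    params.blood_hu_range[1] + shift))
        a = segment_blood_auto(vol, params)
        b = segment_blood_auto(shifted, p_shift)
        assert np.array_equal(a, b)
        myo_a = segment_myocardium(vol, a, params)
        assert np.array_equal(segment_infarct(vol, myo_a, params),
                              segment_infarct(shifted, myo_a, params))


class TestPercentAndROI:
    def test_percent_arithmetic(self):
        inf = np.zeros((10, 10, 1), bool)
        myo = np.zeros((10, 10, 1), bool)
        inf.flat[:30] = True
        myo.flat[30:100] = True
        assert percent_infarct_ct(inf, myo) == pytest.approx(30.0)
        assert percent_infarct_ct(np.zeros_like(inf), myo) == 0.0
        with pytest.raises(ValueError):
            percent_infarct_ct(np.zeros_like(inf), np.zeros_like(myo))

    @given(st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_percent_bounded(self, n_inf, n_myo):
        grid = np.zeros((10, 10, 10), bool)
        inf = grid.copy()
        inf.flat[:n_inf] = True
        myo = grid.copy()
        myo.flat[n_inf:n_inf + n_myo] = True
        assert 0.0 <= percent_infarct_ct(inf, myo) <= 100.0

    def test_roi_stats(self, noisefree_delayed):
        vol, mask = noisefree_delayed
        blood = roi_mean_hu(vol, mask.labels == LV_BLOOD)
        assert blood.mean_hu == pytest.approx(411.0)
        assert blood.sd_hu == 0.0
        single = np.zeros(vol.shape, bool)
        single[0, 0, 0] = True
        stats = roi_mean_hu(vol, single)
        assert stats.mean_hu == vol.values[0, 0, 0]
        assert stats.sd_hu == 0.0
        with pytest.raises(ValueError):
            roi_mean_hu(vol, np.zeros(vol.shape, bool))
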