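import numpy as np
import pytest

from priorseg import (
    AppearanceModel,
    BinaryMask,
    GridVolume,
    accumulate_histograms,
    appearance_map,
    band_partition,
    likelihood,
    neighborhood_response,
)
from priorseg.appearance import UNASSIGNED

from oracles import (
    oracle_band_partition,
    oracle_histograms,
    oracle_likelihood,
    oracle_phi,
    oracle_phi_levels,
)


def hand_model(fg, bg, levels=16, n_bands=1):
    """AppearanceModel from hand-built per-band histograms."""
    hist_fg = np.zeros((n_bands, levels), dtype=np.int64)
    hist_bg = np.zeros((n_bands, levels), dtype=np.int64)
    for (band, lv), c in fg.items():
        hist_fg[band - 1, lv] = c
    for (band, lv), c in bg.items():
        hist_bg[band - 1, lv] = c
    return AppearanceModel(
        hist_fg=hist_fg, hist_bg=hist_bg, n_bands=n_bands, thickness=1, radius=1, levels=levels
    )


class TestBandPartition:
    def test_single_voxel_mask_four_neighbors_in_band_one(self):
        mask = np.zeros((1, 7, 7), dtype=np.uint8)
        mask[0, 3, 3] = 1
        bands = band_partition(BinaryMask(mask), n_bands=3, thickness=1)
        oracle = oracle_band_partition(mask, 3, 1)
        np.testing.assert_array_equal(bands.band_label, oracle)
        # the boundary voxel itself and its 4-neighbors are band 1
        assert bands.band_label[0, 3, 3] == 1
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert bands.band_label[0, 3 + dy, 3 + dx] == 1

    def test_boundary_voxel_is_band_one(self):
        mask = np.zeros((1, 6, 6), dtype=np.uint8)
        mask[0, 2:5, 2:5] = 1
        bands = band_partition(BinaryMask(mask), n_bands=4, thickness=1)
        # every boundary (edge of the square) voxel has d=0 -> band 1
        assert bands.band_label[0, 2, 2] == 1
        assert bands.band_label[0, 2, 4] == 1

    def test_cap_rule(self):
        # distance 3.2 from the boundary with thickness 1 and 3 bands -> band 3
        mask = np.zeros((1, 16, 16), dtype=np.uint8)
        mask[0, 8, 8] = 1
        bands = band_partition(BinaryMask(mask), n_bands=3, thickness=1)
        oracle = oracle_band_partition(mask, 3, 1)
        np.testing.assert_array_equal(bands.band_label, oracle)
        assert bands.band_label[0, 8, 15] == 3  # far voxel capped

    def test_empty_slices_unassigned(self):
        mask = np.zeros((3, 5, 5), dtype=np.uint8)
        mask[1, 2, 2] = 1
        bands = band_partition(BinaryMask(mask), n_bands=2, thickness=1)
        assert (bands.band_label[0] == UNASSIGNED).all()
        assert (bands.band_label[2] == UNASSIGNED).all()
        assert (bands.band_label[1] != UNASSIGNED).all()

    @pytest.mark.parametrize("n_bands,thickness", [(0, 1), (2, 0)])
    def test_invalid_params(self, n_bands, thickness):
        mask = np.zeros((1, 3, 3), dtype=np.uint8)
        mask[0, 1, 1] = 1
        with pytest.raises(ValueError):
            band_partition(BinaryMask(mask), n_bands=n_bands, thickness=thickness)

    def test_thickness_two_matches_oracle(self, rng):
        mask = np.zeros((2, 9, 9), dtype=np.uint8)
        mask[:, 3:6, 2:7] = 1
        bands = band_partition(BinaryMask(mask), n_bands=3, thickness=2)
        np.testing.assert_array_equal(bands.band_label, oracle_band_partition(mask, 3, 2))


class TestNeighborhoodResponse:
    def test_isolated_voxel_sums_itself(self):
        # a banded voxel with no same-band neighbor: phi = own intensity
        vol = np.zeros((1, 5, 5), dtype=np.int32)
        vol[0, 2, 2] = 7
        bands_arr = np.zeros((1, 5, 5), dtype=np.int16)
        bands_arr[0, 2, 2] = 2  # lone band-2 voxel in a band-0 sea? use distinct labels
        bands_arr[0, :, :] = np.where(bands_arr[0] == 2, 2, 1)
        bands_arr[0, 2, 2] = 2
        from priorseg.appearance import ContourBandField

        bands = ContourBandField(band_label=bands_arr, n_bands=2, thickness=1)
        resp = neighborhood_response(GridVolume(vol), bands, radius=1)
        assert resp.phi[0, 2, 2] == 7
        assert resp.count[0, 2, 2] == 1

    def test_vertical_stack_direct_sum(self):
        vol = np.zeros((3, 3, 3), dtype=np.int32)
        vol[0, 1, 1], vol[1, 1, 1], vol[2, 1, 1] = 1, 2, 3
        bands_arr = np.zeros((3, 3, 3), dtype=np.int16)
        bands_arr[:, 1, 1] = 1
        from priorseg.appearance import ContourBandField

        bands = ContourBandField(band_label=bands_arr, n_bands=1, thickness=1)
        resp = neighborhood_response(GridVolume(vol), bands, radius=1)
        assert resp.phi[1, 1, 1] == 6

    def test_matches_exhaustive_oracle(self, rng):
        vol = rng.integers(0, 16, size=(3, 8, 8)).astype(np.int32)
        mask = np.zeros((3, 8, 8), dtype=np.uint8)
        mask[:, 2:6, 3:7] = 1
        bands = band_partition(BinaryMask(mask), n_bands=3, thickness=1)
        resp = neighborhood_response(GridVolume(vol), bands, radius=1)
        phi_o, count_o = oracle_phi(vol, bands.band_label, 1)
        np.testing.assert_array_equal(resp.phi, phi_o)
        np.testing.assert_array_equal(resp.count, count_o)


class TestAccumulateHistograms:
    def test_two_subject_cohort_matches_oracle(self, toy_cohort):
        model = accumulate_histograms(toy_cohort[:2], n_bands=3, thickness=1, radius=1, levels=16)
        fg_o, bg_o = oracle_histograms(
            [(v.data, m.data) for v, m in toy_cohort[:2]], 3, 1, 1, 16
        )
        np.testing.assert_array_equal(model.hist_fg, fg_o)
        np.testing.assert_array_equal(model.hist_bg, bg_o)

    def test_duplication_doubles_counts(self, toy_cohort):
        one = accumulate_histograms(toy_cohort, n_bands=2, thickness=1, radius=1, levels=16)
        two = accumulate_histograms(
            list(toy_cohort) + list(toy_cohort), n_bands=2, thickness=1, radius=1, levels=16
        )
        np.testing.assert_array_equal(two.hist_fg, 2 * one.hist_fg)
        np.testing.assert_array_equal(two.hist_bg, 2 * one.hist_bg)

    def test_conservation_of_banded_voxels(self, toy_cohort):
        model = accumulate_histograms(toy_cohort, n_bands=3, thickness=1, radius=1, levels=16)
        banded = 0
        for _, mask in toy_cohort:
            bands = band_partition(mask, n_bands=3, thickness=1)
            banded += int((bands.band_label != UNASSIGNED).sum())
        assert int(model.hist_fg.sum() + model.hist_bg.sum()) == banded

    def test_empty_training_list_errors(self):
        with pytest.raises(ValueError, match="training"):
            accumulate_histograms([], n_bands=2, thickness=1, radius=1)

    def test_subject_order_invariance(self, toy_cohort):
        a = accumulate_histograms(toy_cohort, n_bands=2, thickness=1, radius=1, levels=16)
        b = accumulate_histograms(toy_cohort[::-1], n_bands=2, thickness=1, radius=1, levels=16)
        np.testing.assert_array_equal(a.hist_fg, b.hist_fg)
        np.testing.assert_array_equal(a.hist_bg, b.hist_bg)


class TestLikelihood:
    def test_direct_ratio(self):
        model = hand_model({(1, 5): 3}, {(1, 5): 1})
        assert likelihood(model, 5, 1) == pytest.approx(0.75)

    def test_neutral_when_no_support_within_tolerance(self):
        model = hand_model({}, {})
        assert likelihood(model, 8, 1) == 0.5

    def test_delta_two_pooling(self):
        # support only at level I+2: found at delta=2 with ratio 2/(2+2)
        model = hand_model({(1, 10): 2}, {(1, 10): 2})
        assert likelihood(model, 8, 1) == pytest.approx(0.5)
        model2 = hand_model({(1, 10): 3}, {(1, 10): 1})
        assert likelihood(model2, 8, 1) == pytest.approx(0.75)

    def test_delta_pooling_is_symmetric_both_sides(self):
        # counts at I-1 and I+1 pool jointly, not first-found
        model = hand_model({(1, 4): 1}, {(1, 6): 3})
        assert likelihood(model, 5, 1) == pytest.approx(0.25)

    def test_matches_oracle_on_random_histograms(self, rng):
        hist_fg = rng.integers(0, 3, size=(2, 16))
        hist_bg = rng.integers(0, 3, size=(2, 16))
        # punch holes so the fallback path is exercised
        hist_fg[:, 5:11] = 0
        hist_bg[:, 5:11] = 0
        model = AppearanceModel(
            hist_fg=hist_fg, hist_bg=hist_bg, n_bands=2, thickness=1, radius=1, levels=16
        )
        for band in (1, 2):
            for lv in range(16):
                assert likelihood(model, lv, band) == pytest.approx(
                    oracle_likelihood(hist_fg, hist_bg, lv, band)
                ), (band, lv)

    def test_band_out_of_range(self):
        model = hand_model({}, {})
        with pytest.raises(ValueError, match="band"):
            likelihood(model, 3, 2)

    def test_fg_bg_swap_symmetry(self, rng):
        hist_fg = rng.integers(0, 4, size=(1, 16))
        hist_bg = rng.integers(0, 4, size=(1, 16))
        m = AppearanceModel(hist_fg=hist_fg, hist_bg=hist_bg, n_bands=1,
                            thickness=1, radius=1, levels=16)
        m_swap = AppearanceModel(hist_fg=hist_bg, hist_bg=hist_fg, n_bands=1,
                                 thickness=1, radius=1, levels=16)
        for lv in range(16):
            assert likelihood(m, lv, 1) == pytest.approx(1.0 - likelihood(m_swap, lv, 1))


class TestAppearanceMap:
    def test_composition_matches_voxelwise_oracle(self, toy_cohort):
        model = accumulate_histograms(toy_cohort[:2], n_bands=3, thickness=1, radius=1, levels=16)
        vol, mask = toy_cohort[2]
        bands = band_partition(mask, n_bands=3, thickness=1)
        amap = appearance_map(model, vol, bands)
        lev = oracle_phi_levels(vol.data, bands.band_label, 1)
        for z in range(3):
            for y in range(8):
                for x in range(8):
                    b = bands.band_label[z, y, x]
                    if b == UNASSIGNED:
                        assert amap.papp[z, y, x] == 0.5
                    else:
                        expected = oracle_likelihood(
                            model.hist_fg, model.hist_bg, int(np.clip(lev[z, y, x], 0, 15)), b
                        )
                        assert amap.papp[z, y, x] == pytest.approx(expected), (z, y, x)

    def test_separable_cohort_gives_extreme_probabilities(self):
        # separable limit: when the accumulated fg and bg histograms have
        # disjoint support in every band, papp is exactly 1 on fg-level
        # voxels and 0 on bg-level voxels. A z-prism cohort with radius 0
        # (same-voxel neighborhood across 3 slices) realizes that premise:
        # every neighborhood is class-pure, so responses stay at the two
        # class intensities.
        pairs = []
        for _ in range(2):
            mask = np.zeros((3, 8, 8), dtype=np.uint8)
            mask[:, 2:6, 2:6] = 1
            vol = np.where(mask, 12, 2).astype(np.int32)
            pairs.append((GridVolume(vol), BinaryMask(mask)))
        model = accumulate_histograms(pairs, n_bands=2, thickness=1, radius=0, levels=16)
        assert not np.any((model.hist_fg > 0) & (model.hist_bg > 0))  # premise
        vol, mask = pairs[0]
        bands = band_partition(mask, n_bands=2, thickness=1)
        amap = appearance_map(model, vol, bands)
        fg = mask.data.astype(bool)
        np.testing.assert_array_equal(amap.papp[fg], 1.0)
        np.testing.assert_array_equal(amap.papp[~fg], 0.0)
        # thresholding at 0.5 inside band 1 recovers the true labels
        b1 = bands.band_label == 1
        np.testing.assert_array_equal((amap.papp >= 0.5)[b1], fg[b1])

    def test_values_in_unit_interval(self, toy_cohort):
        model = accumulate_histograms(toy_cohort, n_bands=3, thickness=1, radius=1, levels=16)
        vol, mask = toy_cohort[0]
        bands = band_partition(mask, n_bands=3, thickness=1)
        amap = appearance_map(model, vol, bands)
        assert (amap.papp >= 0).all() and (amap.papp <= 1).all()

    def test_model_round_trip(self, tmp_path, toy_cohort):
        model = accumulate_histograms(toy_cohort, n_bands=3, thickness=1, radius=1, levels=16)
        model.save(tmp_path / "model.npz")
        back = AppearanceModel.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.hist_fg, model.hist_fg)
        np.testing.assert_array_equal(back.hist_bg, model.hist_bg)
        assert back.n_bands == model.n_bands and back.levels == model.levels
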