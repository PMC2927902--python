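"""Normalization, interpolation, cutline detection, stitching, sinograms."""

import numpy as np
import pytest

import widefieldct as w
from widefieldct.phantom_sim import SubscanSet


class TestNormalize:
    def test_blank_beam_maps_to_one(self):
        flats = np.full((3, 1, 16), 100.0)
        darks = np.full((3, 1, 16), 20.0)
        out = w.normalize(np.full((1, 16), 100.0), darks, flats)
        assert np.allclose(out, 1.0)

    def test_dark_frame_maps_to_zero(self):
        flats = np.full((3, 1, 16), 100.0)
        darks = np.full((3, 1, 16), 20.0)
        out = w.normalize(np.full((1, 16), 20.0), darks, flats)
        assert np.allclose(out, 0.0)

    def test_midrange_value(self):
        flats = np.full((2, 1, 8), 100.0)
        darks = np.full((2, 1, 8), 20.0)
        out = w.normalize(np.full((1, 8), 60.0), darks, flats)
        assert np.allclose(out, 0.5)

    def test_dead_pixel_columns_named_in_error(self):
        flats = np.full((2, 1, 8), 100.0)
        flats[:, :, 3] = 0.0  # dead column: flat below dark
        darks = np.full((2, 1, 8), 20.0)
        with pytest.raises(ValueError, match=r"\[3\]"):
            w.normalize(np.full((1, 8), 50.0), darks, flats)

    def test_clipping_to_range(self):
        flats = np.full((1, 1, 4), 100.0)
        darks = np.full((1, 1, 4), 0.0)
        out = w.normalize(np.full((1, 4), 500.0), darks, flats, clip_max=2.0)
        assert np.all(out == 2.0)


class TestFlipStitch360:
    def test_centered_axis_identity_for_redundant_halves(self):
        # odd detector width: axis pixel is the exact detector center
        ph = w.disc_phantom(101, 30, 1.0, center_px=(10, -5))
        P = 8
        angles = np.arange(P) * (360.0 / P)
        full = w.forward_project(ph, angles, 0, 101).projections
        out = w.flip_stitch_360(full, 0)
        assert out.merged_width_px == 101
        assert np.allclose(out.projections, full[: P // 2], atol=1e-9)

    def test_offset_axis_matches_wide_detector_oracle(self):
        W, dax, P = 101, 25, 16
        wide_w = 2 * W - 1
        ph = w.disc_phantom(wide_w, 30, 1.0, center_px=(15, -7))
        angles = np.arange(P) * (360.0 / P)
        full = w.forward_project(ph, angles, 0, wide_w).projections
        # carve out the small detector whose axis column is W//2 + dax
        lo = wide_w // 2 - (W // 2 + dax)
        det = full[:, lo : lo + W]
        out = w.flip_stitch_360(det, dax)
        oracle = w.wide_projection(ph, angles[: P // 2])
        shift = wide_w // 2 - out.axis_col_px
        cmp = oracle[:, shift : shift + out.merged_width_px]
        scale = np.max(np.abs(oracle))
        assert np.max(np.abs(out.projections - cmp)) <= 1e-3 * scale

    def test_odd_projection_count_rejected(self):
        with pytest.raises(ValueError):
            w.flip_stitch_360(np.zeros((7, 32)), 5)

    def test_axis_off_detector_rejected(self):
        with pytest.raises(ValueError):
            w.flip_stitch_360(np.zeros((8, 32)), 40)


class TestInterpolateMissing:
    def _disc_subscan(self, n_angles, center=(0.0, 0.0)):
        ph = w.disc_phantom(96, 30, 1.0, center_px=center)
        angles = np.arange(n_angles) * (180.0 / n_angles)
        return w.forward_project(ph, angles, 0, 96)

    def test_ratio_one_is_identity(self):
        sub = self._disc_subscan(8)
        out = w.interpolate_missing(sub, 8)
        assert np.array_equal(out.projections, sub.projections)

    def test_ratio_two_inserts_neighbour_midpoints(self):
        sub = self._disc_subscan(4, center=(8.0, 4.0))
        out = w.interpolate_missing(sub, 8)
        assert np.array_equal(out.projections[::2], sub.projections)
        for k in range(3):
            mid = (sub.projections[k] + sub.projections[k + 1]) / 2
            assert np.allclose(out.projections[2 * k + 1], mid)

    def test_doubled_subscan_close_to_direct_simulation(self):
        # axis-centered disc: its projection profile is angle-invariant, so
        # angular interpolation must reproduce the directly simulated rows
        up = w.interpolate_missing(self._disc_subscan(4), 8)
        direct = self._disc_subscan(8)
        dev = np.max(np.abs(up.projections - direct.projections))
        assert dev <= 0.02 * np.ptp(direct.projections)

    def test_inserted_mass_between_neighbour_masses(self):
        ph = w.shepp_logan(96)
        angles = np.arange(6) * 30.0
        sub = w.forward_project(ph, angles, 0, 96)
        out = w.interpolate_missing(sub, 12)
        masses = out.projections.sum(axis=-1)
        for k in range(0, 10, 2):
            lo, hi = sorted((masses[k], masses[k + 2]))
            assert lo - 1e-9 <= masses[k + 1] <= hi + 1e-9

    def test_non_multiple_target_rejected(self):
        with pytest.raises(ValueError):
            w.interpolate_missing(self._disc_subscan(4), 10)


class TestFindCutline:
    def test_identical_strips_zero_shift(self, small_wide):
        left = small_wide[:, 20:164]
        right = small_wide[:, 140:284]
        shift, cut = w.find_cutline(left, right, 24, 4)
        assert shift == 0
        a = left[:, -24:]
        b = right[:, :24]
        assert np.mean((a - b) ** 2) < 1e-20

    def test_constructed_displacement_recovered_exactly(self, small_wide):
        left = small_wide[:, 20:164]
        right_displaced = small_wide[:, 143:287]  # +3 px off its nominal seat
        shift, _ = w.find_cutline(left, right_displaced, 24, 5)
        assert shift == -3

    def test_white_noise_strips_take_warning_path(self):
        rng = np.random.default_rng(0)
        left = rng.normal(size=(8, 50))
        right = rng.normal(size=(8, 50))
        with pytest.warns(UserWarning, match="no registration signal"):
            shift, cut = w.find_cutline(left, right, 20, 3)
        assert shift == 0
        assert cut == 10

    def test_uncorrelated_msd_near_two_sigma_squared(self):
        rng = np.random.default_rng(1)
        sigma = 2.0
        left = rng.normal(0, sigma, size=(200, 64))
        right = rng.normal(0, sigma, size=(200, 64))
        msd = np.mean((left[:, -32:] - right[:, :32]) ** 2)
        assert msd == pytest.approx(2 * sigma**2, rel=0.05)

    def test_flat_strips_warn_center_cut(self):
        with pytest.warns(UserWarning):
            shift, cut = w.find_cutline(np.ones((4, 40)), np.ones((4, 40)), 16, 2)
        assert (shift, cut) == (0, 8)


class TestStitch:
    def test_merged_width_arithmetic(self):
        strips = [np.ones((2, 100)), np.ones((2, 100)), np.ones((2, 100))]
        merged, prov, seams = w.stitch(strips, [10, 10])
        assert merged.shape == (2, 280)
        assert len(seams) == 2

    def test_single_strip_identity(self):
        s = np.arange(12.0).reshape(2, 6)
        merged, prov, seams = w.stitch([s], [])
        assert np.array_equal(merged, s)
        assert seams == ()

    def test_provenance_partitions_columns(self):
        strips = [np.zeros((1, 50)), np.ones((1, 50)), np.full((1, 50), 2.0)]
        merged, prov, _ = w.stitch(strips, [8, 8], [2, 5])
        assert prov.shape == (134,)
        counts = np.bincount(prov)
        assert counts.sum() == 134
        assert np.all(counts > 0)
        # each column's value identifies its source strip here
        assert np.array_equal(merged[0], prov.astype(float))

    def test_cut_column_belongs_to_left_strip(self):
        left = np.zeros((1, 20))
        right = np.ones((1, 20))
        merged, _, seams = w.stitch([left, right], [10], [4])
        seam = seams[0]
        assert merged[0, seam] == 0.0
        assert merged[0, seam + 1] == 1.0

    def test_cutline_outside_overlap_rejected(self):
        with pytest.raises(ValueError):
            w.stitch([np.zeros((1, 20)), np.zeros((1, 20))], [10], [10])

    def test_inconsistent_row_counts_rejected(self):
        with pytest.raises(ValueError):
            w.stitch([np.zeros((2, 20)), np.zeros((3, 20))], [10])


class TestMergeEquivalence:
    def test_merged_equals_wide_detector_away_from_cutlines(
        self, small_geometry, small_subscans, small_wide
    ):
        out = w.merge_subscans(small_subscans, small_geometry)
        assert out.merged_width_px == small_wide.shape[1]
        scale = np.max(np.abs(small_wide))
        keep = np.ones(out.merged_width_px, dtype=bool)
        for seam in out.cutlines_px:
            keep[max(seam - 1, 0) : seam + 2] = False
        err = np.abs(out.projections - small_wide)
        assert np.max(err[:, keep]) <= 1e-3 * scale

    def test_mixed_counts_interpolated_merge_close_to_wide(
        self, small_geometry, small_phantom
    ):
        angles24 = np.arange(24) * (180.0 / 24)
        angles12 = np.arange(12) * (180.0 / 12)
        subs = [
            w.forward_project(small_phantom, angles24, small_geometry.offsets_px[0], 144),
            w.forward_project(small_phantom, angles12, small_geometry.offsets_px[1], 144),
            w.forward_project(small_phantom, angles24, small_geometry.offsets_px[2], 144),
        ]
        out = w.merge_subscans(subs, small_geometry)
        wide = w.wide_projection(small_phantom, angles24)
        scale = np.max(np.abs(wide))
        # interpolated central angles deviate more than simulated ones but
        # stay within a few percent of the projection scale
        assert np.max(np.abs(out.projections - wide)) <= 0.05 * scale

    def test_provenance_complete(self, small_geometry, small_subscans):
        out = w.merge_subscans(small_subscans, small_geometry)
        assert out.provenance is not None
        assert out.provenance.shape == (out.merged_width_px,)
        counts = np.bincount(out.provenance, minlength=3)
        assert counts.sum() == out.merged_width_px
        assert np.all(counts > 0)


class TestSinograms:
    def test_reindexing_exact(self):
        proj = np.arange(2 * 3 * 4.0).reshape(2, 3, 4)
        wide = w.WideProjectionSet(projections=proj, angles_deg=np.array([0.0, 90.0]))
        stack = w.build_sinograms(wide)
        assert stack.sinograms.shape == (3, 2, 4)
        for n in range(3):
            for p in range(2):
                assert np.array_equal(stack.sinograms[n, p], proj[p, n])

    def test_round_trip_bit_exact(self):
        rng = np.random.default_rng(4)
        proj = rng.normal(size=(5, 7, 9))
        wide = w.WideProjectionSet(
            projections=proj, angles_deg=np.arange(5) * 36.0
        )
        back = w.sinograms_to_projections(w.build_sinograms(wide))
        assert np.array_equal(back, proj)

    def test_centered_disc_sinogram_constant_across_angles(self):
        ph = w.disc_phantom(96, 30, 1.0)
        angles = np.arange(12) * 15.0
        sub = w.forward_project(ph, angles, 0, 96)
        wide = w.WideProjectionSet(projections=sub.projections, angles_deg=angles)
        sino = w.build_sinograms(wide).sinograms[0]
        spread = np.max(np.abs(sino - sino[0]), axis=0)
        # pixelization at the disc edge leaves ~1.5% angle-to-angle ripple
        assert np.max(spread) <= 0.02 * np.max(sino)
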