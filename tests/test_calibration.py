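"""Center / tilt / overlap estimation and projection stitching."""

import numpy as np
import pytest

from tomopipe.calibration import (calibrate_scan, estimate_center,
                                  estimate_overlap, estimate_tilt,
                                  rotate_projections, stitch_pairs)
from tomopipe.errors import EstimationFailed, InvalidArgument
from tomopipe.phantom import forward_project, simulate_halfscan
from tomopipe.sinogram import normalize_scan

from conftest import circle_mask, masked_nrmse


class TestEstimateCenter:
    def test_perfectly_mirrored_pair_gives_midline(self):
        rng = np.random.default_rng(0)
        p0 = rng.random((8, 33))
        est = estimate_center(p0, p0[:, ::-1], search_halfwidth=10)
        assert est.center == pytest.approx((33 - 1) / 2.0)
        assert not est.boundary

    def test_recovers_offset_axis(self, asym128):
        w = 200
        c = (w - 1) / 2.0 + 12.5
        fr = forward_project(asym128, [0.0, 180.0], center=c,
                             detector_width=w)
        est = estimate_center(fr[0], fr[1], search_halfwidth=40)
        assert abs(est.center - c) <= 0.5

    def test_invariant_under_additive_offset(self, asym128):
        fr = forward_project(asym128, [0.0, 180.0], detector_width=200)
        a = estimate_center(fr[0], fr[1], search_halfwidth=20)
        b = estimate_center(fr[0] + 5.0, fr[1] + 5.0, search_halfwidth=20)
        assert a.center == pytest.approx(b.center, abs=1e-12)


class TestEstimateTilt:
    def test_equal_row_centers_give_zero_tilt(self):
        rng = np.random.default_rng(1)
        p0 = np.tile(rng.random(65), (40, 1))
        est = estimate_tilt(p0, p0[:, ::-1])
        assert est.tilt == pytest.approx(0.0, abs=1e-6)

    def test_known_slope_closed_form(self):
        # synthetic per-row centers on an exact line: tilt = atan(b)
        rows = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
        centers = 64.0 + 0.01 * rows
        slope, intercept = np.polyfit(rows, centers, 1)
        assert np.degrees(np.arctan(slope)) == pytest.approx(0.5729, abs=1e-3)

    def test_simulated_tilt_round_trip(self, sl128):
        fr = forward_project(sl128, [0.0, 180.0], tilt=0.5, n_rows=256)
        est = estimate_tilt(fr[0], fr[1])
        assert est.tilt == pytest.approx(0.5, abs=0.05)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InvalidArgument):
            estimate_tilt(np.ones((40, 30)), np.ones((40, 30)),
                          rows=[1, 2])


class TestRotateProjections:
    def test_zero_angle_is_identity(self, small_scan):
        scan, _ = small_scan
        stack = normalize_scan(scan)
        assert np.array_equal(rotate_projections(stack, 0.0), stack)

    def test_rotation_near_inverse(self, sl128):
        fr = forward_project(sl128, [0.0], n_rows=64)
        once = rotate_projections(fr, 2.0)
        back = rotate_projections(once, -2.0)
        inner = (slice(None), slice(8, -8), slice(8, -8))
        err = np.abs(back[inner] - fr[inner]).max()
        one_step = np.abs(once[inner] - fr[inner]).max()
        assert err < 0.5 * one_step  # well below the rotation itself

    def test_compensation_closes_the_loop(self, sl128):
        fr = forward_project(sl128, [0.0, 180.0], tilt=0.5, n_rows=256)
        est = estimate_tilt(fr[0], fr[1])
        comp = rotate_projections(fr, est.tilt)
        assert abs(estimate_tilt(comp[0], comp[1]).tilt) < 0.05


class TestEstimateOverlap:
    def test_half_scan_round_trip(self, asym128):
        scan, truth = simulate_halfscan(asym128, n_proj=8, overlap=40,
                                        poisson=False)
        norm = normalize_scan(scan)
        est = estimate_overlap(norm[0], norm[4])
        assert abs(est - truth.true_overlap) <= 1

    def test_centered_scan_fails_or_flags(self, asym128):
        fr = forward_project(asym128, [0.0, 180.0])
        with pytest.raises(EstimationFailed):
            estimate_overlap(np.exp(-0.02 * fr[0]), np.exp(-0.02 * fr[1]))

    def test_invariant_to_intensity_scaling(self, asym128):
        scan, truth = simulate_halfscan(asym128, n_proj=8, overlap=40,
                                        poisson=False)
        norm = normalize_scan(scan)
        assert (estimate_overlap(norm[0], norm[4])
                == estimate_overlap(3.7 * norm[0], 3.7 * norm[4]))


class TestStitchPairs:
    def test_output_width_is_two_w_minus_overlap(self):
        stack = np.ones((4, 2016))
        assert stitch_pairs(stack, 120).shape == (2, 3912)

    def test_ramp_blending_preserves_constants(self):
        stack = np.full((6, 3, 50), 4.25)
        out = stitch_pairs(stack, 11)
        assert np.allclose(out, 4.25)

    def test_blend_weights_sum_to_one(self):
        # a frame of ones must stitch to ones at every column
        out = stitch_pairs(np.ones((2, 40)), 13)
        assert np.allclose(out, 1.0)

    def test_odd_projection_count_rejected(self):
        with pytest.raises(InvalidArgument):
            stitch_pairs(np.ones((5, 40)), 10)

    def test_stitched_reconstruction_matches_full_fov(self, asym128):
        from tomopipe.phantom import simulate_scan
        from tomopipe.recon import gridrec

        scan, truth = simulate_halfscan(asym128, n_proj=240, overlap=40,
                                        poisson=False)
        norm = normalize_scan(scan)[:, 0, :]
        stitched = stitch_pairs(norm, truth.true_overlap)
        ws = stitched.shape[-1]
        rec, _ = gridrec(-np.log(np.clip(stitched, 1e-6, None)),
                         scan.angles[:120])
        ref_scan, ref_truth = simulate_scan(asym128, n_proj=120,
                                            detector_width=ws,
                                            poisson=False)
        ref_norm = normalize_scan(ref_scan)[:, 0, :]
        ref, _ = gridrec(-np.log(np.clip(ref_norm, 1e-6, None)),
                         ref_scan.angles)
        mask = circle_mask(ws, 0.45)
        err = masked_nrmse(rec.values / truth.attenuation_scale,
                           ref.values / ref_truth.attenuation_scale, mask)
        assert err < 0.08


class TestCalibrateScan:
    def test_results_written_to_scanlog(self, asym128):
        from tomopipe.phantom import simulate_scan

        scan, truth = simulate_scan(asym128, n_proj=8, poisson=False)
        geometry, log = calibrate_scan(normalize_scan(scan), scan.angles)
        assert log.center == geometry.center
        assert abs(geometry.center - truth.true_center) <= 0.5
        assert log.n_proj == 8

    def test_halfscan_median_overlap(self, asym128):
        scan, truth = simulate_halfscan(asym128, n_proj=16, overlap=40,
                                        poisson=True, seed=3)
        geometry, log = calibrate_scan(normalize_scan(scan), scan.angles,
                                       halfscan=True)
        assert abs(geometry.overlap - truth.true_overlap) <= 1
        assert log.overlap == geometry.overlap
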