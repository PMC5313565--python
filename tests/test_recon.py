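"""Filter bank, FBP oracle, gridrec and volume reconstruction options."""

import numpy as np
import pytest

from tomopipe.errors import InvalidArgument
from tomopipe.phantom import disc_phantom, forward_project
from tomopipe.recon import (FilterSpec, fbp_reference, filter_kernel,
                            gridrec, pad_width, reconstruct_volume)
from tomopipe.sinogram import Sinogram

from conftest import circle_mask, masked_nrmse


class TestFilterKernel:
    def test_zero_frequency_vanishes_for_all_filters(self):
        for name in ("ramlak", "hanning", "parzen", "hilbert"):
            k = filter_kernel(64, FilterSpec(name))
            assert k[0] == 0.0

    def test_ramlak_reaches_maximum_at_nyquist(self):
        k = filter_kernel(64, FilterSpec("ramlak", 1.0))
        assert np.abs(k).max() == pytest.approx(1.0)
        assert abs(k[32]) == pytest.approx(1.0)  # the Nyquist bin

    def test_hanning_window_zero_at_cutoff(self):
        k = filter_kernel(64, FilterSpec("hanning", 0.5))
        # |nu| = 0.5 lives at index 16 of 64
        assert k[16] == pytest.approx(0.0, abs=1e-15)

    def test_everything_beyond_cutoff_is_zero(self):
        k = filter_kernel(128, FilterSpec("parzen", 0.5))
        nu = 2 * np.fft.fftfreq(128)
        assert np.all(k[np.abs(nu) > 0.5] == 0.0)

    def test_hilbert_is_minus_i_sign(self):
        k = filter_kernel(16, FilterSpec("hilbert", 1.0))
        nu = 2 * np.fft.fftfreq(16)
        assert np.allclose(k[nu > 0], -1j)
        assert np.allclose(k[nu < 0], 1j)

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidArgument):
            FilterSpec("butterworth")

    def test_non_power_of_two_length_rejected(self):
        with pytest.raises(InvalidArgument):
            filter_kernel(48, FilterSpec())


class TestPadWidth:
    @pytest.mark.parametrize("n,expected", [
        (2560, 4096),   # large-sensor width
        (816, 1024),
        (2048, 2048),   # already a power of 2: kept
        (1, 1),
        (3, 4),
    ])
    def test_next_power_of_two(self, n, expected):
        assert pad_width(n) == expected

    def test_invalid_input(self):
        with pytest.raises(InvalidArgument):
            pad_width(0)


class TestFbpReference:
    def test_zero_sinogram_gives_zero_slice(self):
        angles = np.linspace(0, 180, 30, endpoint=False)
        out = fbp_reference(np.zeros((30, 32)), angles)
        assert np.all(out.values == 0.0)

    def test_linearity(self, sino96):
        sino, angles = sino96
        a = fbp_reference(sino, angles).values
        b = fbp_reference(2.0 * sino, angles).values
        assert np.allclose(b, 2.0 * a, atol=1e-12)

    def test_uniform_disc_reconstructs_to_its_density(self):
        d = disc_phantom(64, 20, 0.5)
        angles = np.linspace(0, 180, 120, endpoint=False)
        sino = forward_project(d, angles, detector_width=96)[:, 0, :]
        rec = fbp_reference(sino, angles).values
        n = 96
        c = (n - 1) / 2.0
        y, x = np.mgrid[0:n, 0:n]
        interior = (x - c) ** 2 + (y - c) ** 2 <= 14 ** 2
        assert np.abs(rec[interior] - 0.5).max() / 0.5 < 0.05


class TestGridrec:
    @pytest.mark.parametrize("name,cutoff", [("ramlak", 1.0),
                                             ("hanning", 0.5),
                                             ("parzen", 1.0)])
    def test_matches_fbp_oracle(self, sino96, name, cutoff):
        sino, angles = sino96
        spec = FilterSpec(name, cutoff)
        ref = fbp_reference(sino, angles, spec=spec).values
        got, _ = gridrec(sino, angles, spec=spec)
        mask = circle_mask(96, 0.46)
        dyn = ref[mask].max() - ref[mask].min()
        assert masked_nrmse(got.values, ref, mask) < 0.01
        assert np.abs((got.values - ref)[mask]).max() < 0.02 * dyn

    def test_pair_packing_consistency(self, sino96):
        sino, angles = sino96
        a, _ = gridrec(sino, angles)
        b1, b2 = gridrec(sino, angles, sinogram2=sino)
        assert np.abs(a.values - b1.values).max() <= 1e-10
        assert np.abs(a.values - b2.values).max() <= 1e-10

    def test_rotational_covariance(self, sino96):
        sino, angles = sino96
        base, _ = gridrec(sino, angles)
        rot, _ = gridrec(sino, (angles + 90.0) % 360.0)
        mask = circle_mask(96, 0.45)
        assert masked_nrmse(rot.values, np.rot90(base.values), mask) < 0.01

    def test_off_center_sinogram_matches_oracle(self, sl64):
        angles = np.linspace(0, 180, 120, endpoint=False)
        c = 55.25
        sino = forward_project(sl64, angles, center=c,
                               detector_width=96)[:, 0, :]
        ref = fbp_reference(sino, angles, center=c).values
        got, _ = gridrec(sino, angles, center=c)
        assert masked_nrmse(got.values, ref, circle_mask(96, 0.42)) < 0.01

    def test_mass_conservation(self, sino96):
        # integral of the slice ~ mean ray sum (Radon mass preservation);
        # evaluated on a finely sampled Fourier grid, where the truncated
        # ramp-tail bias of the default grid vanishes
        sino, angles = sino96
        rec, _ = gridrec(sino, angles, oversample=8)
        assert rec.values.sum() == pytest.approx(sino.sum(axis=1).mean(),
                                                 rel=0.02)


@pytest.fixture(scope="module")
def sinos(sino96):
    sino, angles = sino96
    trans = np.exp(-0.02 * sino)
    return [Sinogram(values=trans, row=r, angles=angles) for r in (0, 1)]


class TestReconstructVolume:
    def test_identity_options_match_plain_gridrec(self, sinos):
        plain, _ = gridrec(-np.log(np.clip(sinos[0].values, 1e-6, None)),
                           sinos[0].angles)
        out = reconstruct_volume(sinos)
        n = plain.values.shape[0]
        assert np.allclose(out[0].values, plain.values, atol=1e-12)

    def test_roi_equals_crop_of_full_slice(self, sinos):
        full = reconstruct_volume(sinos)[0].values
        roi = reconstruct_volume(sinos, roi=(10, 40, 20, 50))[0].values
        assert np.array_equal(roi, full[20:50, 10:40])

    def test_rotated_output_matches_rotated_baseline(self, sinos):
        from scipy import ndimage

        full = reconstruct_volume(sinos)[0].values
        rot = reconstruct_volume(sinos, rotate_by=90.0)[0].values
        expected = ndimage.rotate(full, 90.0, reshape=False, order=1,
                                  prefilter=False)
        mask = circle_mask(full.shape[0], 0.4)
        assert masked_nrmse(rot, expected, mask) < 0.01

    def test_invalid_roi_rejected(self, sinos):
        with pytest.raises(InvalidArgument):
            reconstruct_volume(sinos, roi=(0, 500, 0, 500))

    def test_whole_operator_linear_in_log_sinogram(self, sino96):
        sino, angles = sino96
        s1 = [Sinogram(values=np.exp(-0.02 * sino), row=0, angles=angles)]
        s2 = [Sinogram(values=np.exp(-0.04 * sino), row=0, angles=angles)]
        a = reconstruct_volume(s1)[0].values
        b = reconstruct_volume(s2)[0].values
        assert np.allclose(b, 2.0 * a, atol=1e-10)
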