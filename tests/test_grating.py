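"""Phase-stepping analysis, contrast separation and the GI branch."""

import numpy as np
import pytest

from tomopipe.artifacts import ring_remove_wavelet_fft
from tomopipe.errors import InvalidArgument
from tomopipe.grating import (analyze_steps, destripe_dpc, extract_contrasts,
                              gi_pipeline, wrap_phase)
from tomopipe.phantom import simulate_phase_stepping


def maps_for(a0, v, phi, steps):
    shape = (4, 5)
    frames = simulate_phase_stepping(np.full(shape, a0), np.full(shape, v),
                                     np.full(shape, phi), steps)
    return analyze_steps(frames)


class TestAnalyzeSteps:
    def test_closed_form_single_harmonic(self):
        m = maps_for(100.0, 0.4, 0.7, 8)
        assert m.a0 == pytest.approx(100.0)
        assert m.visibility == pytest.approx(0.4)
        assert m.phi == pytest.approx(0.7)

    def test_constant_curve_flags_undefined_phase(self):
        m = maps_for(50.0, 0.0, 1.3, 6)
        assert np.all(m.visibility == 0.0)
        assert np.all(m.phi == 0.0)
        assert not m.valid.any()

    @pytest.mark.parametrize("steps", [3, 4, 5, 8])
    @pytest.mark.parametrize("phi", [-2.9, -0.5, 0.0, 1.2, 3.1])
    def test_exact_recovery_any_step_count_and_phase(self, steps, phi):
        m = maps_for(80.0, 0.35, phi, steps)
        assert np.abs(m.a0 - 80.0).max() <= 1e-10
        assert np.abs(m.visibility - 0.35).max() <= 1e-10
        assert np.abs(wrap_phase(m.phi - phi)).max() <= 1e-10

    def test_too_few_steps_rejected(self):
        with pytest.raises(InvalidArgument):
            analyze_steps(np.ones((2, 4, 4)))


class TestExtractContrasts:
    def test_identical_scans_give_neutral_contrasts(self):
        m = maps_for(100.0, 0.4, 0.7, 8)
        absorption, dpc, dark = extract_contrasts(m, m)
        assert np.allclose(absorption, 1.0)
        assert np.allclose(dpc, 0.0)
        assert np.allclose(dark, 1.0)

    def test_dpc_wrapping(self):
        s = maps_for(100.0, 0.4, 3.0, 8)
        r = maps_for(100.0, 0.4, -3.0, 8)
        _, dpc, _ = extract_contrasts(s, r)
        assert dpc == pytest.approx(6.0 - 2 * np.pi, abs=1e-10)

    def test_wrap_is_2pi_periodic(self):
        phis = np.linspace(-3.1, 3.1, 37)
        assert np.allclose(wrap_phase(phis + 2 * np.pi), wrap_phase(phis),
                           atol=1e-12)

    def test_zero_reference_visibility_masked(self):
        s = maps_for(100.0, 0.4, 0.7, 8)
        r = maps_for(100.0, 0.0, 0.0, 8)
        absorption, dpc, dark = extract_contrasts(s, r)
        assert np.isnan(dpc).all()
        assert np.isnan(dark).all()
        assert np.isfinite(absorption).all()

    def test_known_phase_gradient_recovered(self):
        rows, cols = 6, 40
        grad = np.tile(np.linspace(-1.2, 1.2, cols), (rows, 1))
        sample = simulate_phase_stepping(
            np.full((rows, cols), 90.0), np.full((rows, cols), 0.3),
            grad, 8)
        ref = simulate_phase_stepping(
            np.full((rows, cols), 90.0), np.full((rows, cols), 0.3),
            np.zeros((rows, cols)), 8)
        _, dpc, _ = extract_contrasts(analyze_steps(sample),
                                      analyze_steps(ref))
        assert np.abs(dpc - grad).max() <= 1e-8


class TestDestripeDpc:
    def test_equals_transposed_ring_filter_by_construction(self):
        rng = np.random.default_rng(4)
        img = rng.random((48, 64))
        a = destripe_dpc(img, "db8", 3, 2.0)
        b = ring_remove_wavelet_fft(img.T, "db8", 3, 2.0).T
        assert np.array_equal(a, b)

    def test_horizontal_stripes_suppressed(self):
        stripes = np.zeros((96, 128))
        for row, amp in [(20, 0.1), (41, -0.08), (70, 0.12), (83, -0.1)]:
            stripes[row, :] = amp
        out = destripe_dpc(stripes, "db8", 5, 2.0)
        assert np.abs(out).max() < 0.05 * np.abs(stripes).max()

    def test_stripe_free_image_nearly_unchanged(self):
        a, c = np.mgrid[0:96, 0:128]
        img = np.exp(-((a - 48.0) ** 2 / 500.0 + (c - 64.0) ** 2 / 900.0))
        out = destripe_dpc(img, "db8", 3, 2.0)
        rel = np.sqrt(np.mean((out - img) ** 2)) / np.sqrt(np.mean(img ** 2))
        assert rel < 0.01


def _gi_scan_of_absorber(sl64, n_proj=90, n_steps=4):
    """Stepped GI acquisition of a pure absorber (V, phi unchanged)."""
    from tomopipe.phantom import forward_project

    angles = np.linspace(0, 180, n_proj, endpoint=False)
    proj = forward_project(sl64, angles, n_rows=1)
    proj *= 2.5 / proj.max()
    trans = np.exp(-proj)  # (n_proj, 1, w)
    rows, cols = trans.shape[1:]
    a0_ref = np.full((rows, cols), 100.0)
    vis = np.full((rows, cols), 0.35)
    phi = np.zeros((rows, cols))
    sample = np.stack([simulate_phase_stepping(a0_ref * t, vis, phi, n_steps)
                       for t in trans])
    ref = simulate_phase_stepping(a0_ref, vis, phi, n_steps)
    return sample, ref, angles, proj


class TestGiPipeline:
    def test_absorption_branch_matches_standard_pipeline(self, sl64):
        from tomopipe.recon import gridrec
        from conftest import circle_mask, masked_nrmse

        sample, ref, angles, proj = _gi_scan_of_absorber(sl64)
        slices = gi_pipeline(sample, ref, angles, contrast="absorption")
        direct, _ = gridrec(proj[:, 0, :], angles)
        n = direct.values.shape[0]
        mask = circle_mask(n, 0.45)
        assert masked_nrmse(slices[0].values, direct.values, mask) < 0.02

    def test_darkfield_of_scatter_free_object_is_zero(self, sl64):
        sample, ref, angles, _ = _gi_scan_of_absorber(sl64, n_proj=30)
        slices = gi_pipeline(sample, ref, angles, contrast="darkfield")
        assert np.abs(slices[0].values).max() < 1e-8

    def test_missing_reference_rejected(self, sl64):
        sample, _, angles, _ = _gi_scan_of_absorber(sl64, n_proj=4)
        with pytest.raises(InvalidArgument):
            gi_pipeline(sample, None, angles)

    def test_serial_and_process_backends_bit_identical(self, sl64):
        sample, ref, angles, _ = _gi_scan_of_absorber(sl64, n_proj=8)
        a = gi_pipeline(sample, ref, angles, contrast="absorption",
                        backend="serial")
        b = gi_pipeline(sample, ref, angles, contrast="absorption",
                        backend="process", processes=2)
        assert np.array_equal(a[0].values, b[0].values)

    def test_dpc_cylinder_reconstructs_delta_profile(self):
        from tomopipe.recon import FilterSpec, gridrec

        n, R = 128, 40.0
        t = np.arange(n) - (n - 1) / 2.0
        chord = np.where(np.abs(t) < R,
                         2.0 * np.sqrt(np.clip(R * R - t * t, 0, None)),
                         0.0)
        dpc = np.gradient(chord)
        angles = np.linspace(0, 180, 180, endpoint=False)
        sino = np.tile(dpc, (len(angles), 1))
        rec, _ = gridrec(sino, angles, spec=FilterSpec("hilbert"))
        prof = rec.values[n // 2 - 1]
        truth = np.where(np.abs(t) < R, 1.0, 0.0)
        assert np.corrcoef(prof, truth)[0, 1] > 0.99
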