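"""Hologram processing: windows, demodulation, propagation, focus, unwrapping."""

import numpy as np
import pytest

from flowdht import (
    ComplexField,
    Hologram,
    QPM,
    apodize,
    autofocus,
    compensate_reference,
    demodulate,
    process_sequence,
    propagate_angular_spectrum,
    simulate_rolling_sequence,
    synthesize_hologram,
    tamura_coefficient,
    unwrap_phase,
    wft_denoise,
)


def _flat_hologram(n=128, carrier=(0.25, 0.25), pitch=0.1) -> Hologram:
    u = ComplexField(np.ones((n, n), dtype=complex), pitch)
    return synthesize_hologram(u, carrier)


class TestApodize:
    def test_zero_taper_is_identity(self):
        h = _flat_hologram()
        np.testing.assert_array_equal(apodize(h, 0.0).intensity, h.intensity)

    def test_corners_vanish_and_centre_unchanged(self):
        h = _flat_hologram()
        a = apodize(h, 0.3)
        assert a.intensity[0, 0] == 0.0
        assert a.intensity[-1, -1] == 0.0
        c = h.intensity.shape[0] // 2
        assert a.intensity[c, c] == pytest.approx(h.intensity[c, c])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            apodize(_flat_hologram(), 1.5)


class TestDemodulate:
    def test_flat_field_demodulates_to_constant_phase(self):
        h = _flat_hologram(n=256)
        u = demodulate(apodize(h, 0.2), (0.25, 0.25))
        inner = u.phase[40:-40, 40:-40]
        assert np.ptp(inner) < 1e-3

    def test_auto_peak_search_finds_carrier(self):
        h = _flat_hologram(n=256, carrier=(0.25, 0.1875))
        u_auto = demodulate(apodize(h, 0.2), "auto")
        u_known = demodulate(apodize(h, 0.2), (0.25, 0.1875))
        inner = np.s_[40:-40, 40:-40]
        diff = np.angle(np.exp(1j * (u_auto.phase - u_known.phase)))[inner]
        assert np.abs(diff - diff.mean()).max() < 1e-2

    def test_missing_carrier_raises(self):
        rng = np.random.default_rng(0)
        h = Hologram(1.0 + 0.01 * rng.random((128, 128)), 0.1)
        with pytest.raises(ValueError, match="no carrier"):
            demodulate(h, "auto")


class TestAngularSpectrum:
    def test_zero_distance_is_identity(self):
        rng = np.random.default_rng(3)
        u = ComplexField(rng.standard_normal((64, 64))
                         + 1j * rng.standard_normal((64, 64)), 0.1)
        out = propagate_angular_spectrum(u, 0.0, 0.488)
        np.testing.assert_array_equal(out.data, u.data)

    def test_round_trip_is_unitary(self):
        # band-limited field: propagate +dz then -dz recovers it
        n = 128
        fy, fx = np.meshgrid(np.fft.fftfreq(n, 0.1), np.fft.fftfreq(n, 0.1),
                             indexing="ij")
        rng = np.random.default_rng(4)
        spec = np.where(np.hypot(fy, fx) < 1.0,
                        rng.standard_normal((n, n))
                        + 1j * rng.standard_normal((n, n)), 0.0)
        u = ComplexField(np.fft.ifft2(spec), 0.1)
        back = propagate_angular_spectrum(
            propagate_angular_spectrum(u, 17.3, 0.488), -17.3, 0.488)
        assert np.abs(back.data - u.data).max() < 1e-10

    def test_plane_wave_gains_global_phase(self):
        u = ComplexField(np.ones((64, 64), dtype=complex), 0.1)
        dz = 5.0
        out = propagate_angular_spectrum(u, dz, 0.488)
        expected = np.exp(2j * np.pi * dz / 0.488)
        np.testing.assert_allclose(out.data, expected, atol=1e-10)
        np.testing.assert_allclose(np.abs(out.data), 1.0, atol=1e-10)

    def test_non_finite_distance_rejected(self):
        u = ComplexField(np.ones((8, 8), dtype=complex), 0.1)
        with pytest.raises(ValueError):
            propagate_angular_spectrum(u, np.inf, 0.488)


class TestTamuraCoefficient:
    def test_constant_amplitude_gives_zero(self):
        u = ComplexField(np.full((32, 32), 2.0 + 0j), 0.1)
        assert tamura_coefficient(u) == 0.0

    def test_known_amplitude_set(self):
        # amplitudes {1,1,3,3}: population sigma = 1, mean = 2 -> TC = 0.5
        u = ComplexField(np.array([[1.0, 1.0], [3.0, 3.0]], dtype=complex), 1.0)
        assert tamura_coefficient(u) == pytest.approx(0.5)
        assert tamura_coefficient(u, sqrt_variant=True) == pytest.approx(
            np.sqrt(0.5))

    def test_scale_invariance(self, rng):
        a = rng.random((32, 32)) + 0.1
        u = ComplexField(a.astype(complex), 0.1)
        cu = ComplexField((7.3 * a).astype(complex), 0.1)
        assert tamura_coefficient(cu) == pytest.approx(tamura_coefficient(u))

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError):
            tamura_coefficient(ComplexField(np.zeros((8, 8), complex), 0.1))


class TestAutofocus:
    @staticmethod
    def _defocused_cell(dz, small_phantom):
        from flowdht import project_phase
        q = project_phase(small_phantom, 0.0)
        pad = np.zeros((256, 256))
        pad[104:152, 104:152] = q.phase
        u = ComplexField(np.exp(1j * pad), 0.2)
        return propagate_angular_spectrum(u, dz, 0.488)

    def test_recovers_constructed_defocus(self, small_phantom):
        u = self._defocused_cell(20.0, small_phantom)
        z_grid = np.arange(-30.0, 31.0, 1.0)
        z_bar = autofocus(u, z_grid, 0.488)
        assert z_bar == pytest.approx(-20.0, abs=1.0)

    def test_in_focus_input_returns_zero(self, small_phantom):
        u = self._defocused_cell(0.0, small_phantom)
        z_grid = np.arange(-10.0, 11.0, 1.0)
        assert autofocus(u, z_grid, 0.488) == pytest.approx(0.0, abs=1.0)

    def test_focus_metric_has_unique_minimum(self, small_phantom):
        u = self._defocused_cell(15.0, small_phantom)
        z_grid = np.arange(-25.0, 26.0, 5.0)
        tcs = [tamura_coefficient(propagate_angular_spectrum(u, z, 0.488))
               for z in z_grid]
        interior_minima = [
            i for i in range(1, len(tcs) - 1)
            if tcs[i] < tcs[i - 1] and tcs[i] < tcs[i + 1]
        ]
        assert len(interior_minima) == 1

    def test_single_candidate_returned(self, small_phantom):
        u = self._defocused_cell(0.0, small_phantom)
        assert autofocus(u, [7.5], 0.488) == 7.5

    def test_empty_candidates_rejected(self, small_phantom):
        u = self._defocused_cell(0.0, small_phantom)
        with pytest.raises(ValueError):
            autofocus(u, [], 0.488)


class TestCompensateReference:
    def test_self_division_gives_unit_flat_field(self):
        rng = np.random.default_rng(5)
        u = ComplexField(np.exp(1j * rng.random((32, 32))), 0.1)
        out = compensate_reference(u, u)
        np.testing.assert_allclose(out.data, 1.0 + 0j, atol=1e-12)

    def test_aberration_factorization_recovered(self):
        rng = np.random.default_rng(6)
        yy, xx = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        aberration = np.exp(1j * (0.01 * (yy - 16)**2 + 0.02 * xx))
        obj = np.exp(1j * rng.random((32, 32)))
        u = ComplexField(obj * aberration, 0.1)
        ref = ComplexField(aberration, 0.1)
        out = compensate_reference(u, ref)
        assert np.abs(out.data - obj).max() < 1e-10

    def test_zero_amplitude_reference_rejected(self):
        u = ComplexField(np.ones((8, 8), complex), 0.1)
        bad = np.ones((8, 8), complex)
        bad[2:4, 2:4] = 0.0
        with pytest.raises(ValueError, match="4 pixel"):
            compensate_reference(u, ComplexField(bad, 0.1))


class TestUnwrapPhase:
    def test_planar_ramp_recovered_up_to_constant(self):
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        surface = 0.5 * xx + 0.2 * yy
        wrapped = np.angle(np.exp(1j * surface))
        out = unwrap_phase(wrapped).phase
        offset = out - surface
        assert np.ptp(offset) < 1e-6          # constant offset only
        k = offset.mean() / (2 * np.pi)       # ... and it is a 2 pi multiple
        assert abs(k - round(k)) < 1e-6

    def test_smooth_input_unchanged(self):
        yy, xx = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        smooth = 0.02 * (xx - 16) + 0.01 * (yy - 16)
        out = unwrap_phase(smooth).phase
        np.testing.assert_allclose(out, smooth, atol=1e-9)

    def test_congruence_modulo_two_pi(self, rng):
        wrapped = np.angle(np.exp(1j * rng.normal(0, 2.0, (48, 48))))
        out = unwrap_phase(wrapped).phase
        np.testing.assert_allclose(np.angle(np.exp(1j * (out - wrapped))),
                                   0.0, atol=1e-9)


class TestWftDenoise:
    @staticmethod
    def _ramp(n=128):
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        return 0.02 * xx + 0.015 * yy

    def test_zero_threshold_is_identity(self):
        q = QPM(self._ramp(), 0.1)
        out = wft_denoise(q, window_size=32, threshold=0.0)
        np.testing.assert_allclose(out.phase, q.phase, atol=1e-10)

    def test_reduces_noise_on_smooth_surface(self):
        rng = np.random.default_rng(7)
        clean = self._ramp()
        noisy = clean + rng.normal(0, 0.3, clean.shape)
        out = wft_denoise(QPM(noisy, 0.1), window_size=32, threshold=2.0)
        rmse_in = np.sqrt(((noisy - clean)**2).mean())
        rmse_out = np.sqrt(((out.phase - clean)**2).mean())
        assert rmse_out < rmse_in

    def test_low_distortion_on_noise_free_surface(self):
        clean = self._ramp()
        out = wft_denoise(QPM(clean, 0.1), window_size=32, threshold=2.0)
        assert np.sqrt(((out.phase - clean)**2).mean()) < 1e-2

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            wft_denoise(QPM(np.zeros((16, 16)), 0.1), window_size=32)


class TestEndToEnd:
    def test_noise_free_sequence_phase_recovery(self, optics):
        """Full chain at zero noise recovers ground-truth phase, RMSE < 0.05 rad."""
        from flowdht import FlowSpec, PhantomSpec
        # native 0.1 um object pixel; cell edge at the resolution scale
        spec = PhantomSpec(grid_size=96, voxel_size=0.1, cell_radius=4.0,
                           correlation_length=0.8, seed=2, edge_voxels=4)
        flow = FlowSpec(noise_sigma=0.0, n_frames=6, seed=9)
        sim = simulate_rolling_sequence(spec, flow, optics,
                                        fov_pixels=256)
        qpms = process_sequence(sim.holograms, sim.reference_hologram,
                                optics.wavelength, carrier=sim.carrier)
        c = (256 - qpms[0].phase.shape[0]) // 2
        for q, truth in zip(qpms, sim.truth_phases):
            ref = truth.phase[c:c + q.phase.shape[0], c:c + q.phase.shape[1]]
            rmse = np.sqrt(((q.phase - ref)**2).mean())
            assert rmse < 0.05
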