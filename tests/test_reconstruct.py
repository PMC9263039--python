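"""Reconstruction chain: carrier location, demodulation, propagation,
unwrapping, background compensation and frame averaging."""
import math
from dataclasses import replace

import numpy as np
import pytest

from holoassay.experiments import blob_phantom, _central_region
from holoassay.fields import ComplexField, Hologram, PhaseImage
from holoassay.reconstruct import (CarrierNotFoundError, autofocus,
                                   average_phase, compensate_background,
                                   locate_carrier, propagate,
                                   reconstruct_fourier, reconstruct_series,
                                   unwrap_phase)
from holoassay.simulate import render_hologram, render_series


def _flat_phase(optics):
    shape = (optics.sensor_rows, optics.sensor_cols)
    return PhaseImage(np.zeros(shape), optics.pixel_pitch_um,
                      wavelength_um=optics.wavelength_um)


class TestLocateCarrier:
    def test_noise_free_fringes_recovered_within_one_bin(self, optics_quiet):
        holo = render_hologram(_flat_phase(optics_quiet), optics_quiet, 0, seed=1)
        fx, fy = locate_carrier(holo)
        bin_fx = 1.0 / (optics_quiet.sensor_cols * optics_quiet.pixel_pitch_um)
        bin_fy = 1.0 / (optics_quiet.sensor_rows * optics_quiet.pixel_pitch_um)
        assert abs(fx - optics_quiet.carrier_freq[0]) < bin_fx
        assert abs(fy - optics_quiet.carrier_freq[1]) < bin_fy

    def test_constant_image_raises(self, optics_small):
        holo = Hologram(np.full((192, 256), 3.0), optics_small.pixel_pitch_um,
                        optics_small.wavelength_nm)
        with pytest.raises(CarrierNotFoundError):
            locate_carrier(holo)

    def test_cell_hologram_carrier_within_one_bin(self, optics_small):
        phantom = blob_phantom(optics_small, seed=2)
        holo = render_hologram(phantom, optics_small, 0, seed=3)
        fx, fy = locate_carrier(holo)
        bin_fx = 1.0 / (optics_small.sensor_cols * optics_small.pixel_pitch_um)
        assert abs(fx - optics_small.carrier_freq[0]) < bin_fx
        assert abs(fy - optics_small.carrier_freq[1]) < bin_fx


class TestReconstructFourier:
    def test_pure_fringes_give_constant_phase(self, optics_quiet):
        holo = render_hologram(_flat_phase(optics_quiet), optics_quiet, 0, seed=1)
        field = reconstruct_fourier(holo, optics_quiet.carrier_freq)
        rs, cs = _central_region(holo.shape)
        ph = field.phase[rs, cs]
        assert np.std(ph) < 1e-6

    def test_known_blob_roundtrip_noise_free(self):
        from holoassay.experiments import scaled_optics

        optics_quiet = scaled_optics(512, 384, shot_noise_scale=0.0,
                                     parasitic_fringe_amplitude=0.0,
                                     background_aberration_rad=0.0)
        truth = blob_phantom(optics_quiet, seed=4, peak_range=(0.5, 2.5))
        holo = render_hologram(truth, optics_quiet, 0, seed=5)
        # the sharp-edged (20% rolloff) filter maximizes passband and hence
        # pointwise fidelity on a band-limited phantom; the softer default
        # trades this for a ringing-free response (dry-mass accuracy)
        field = reconstruct_fourier(holo, optics_quiet.carrier_freq,
                                    filter_edge_frac=0.2)
        ph = unwrap_phase(field.phase)
        rs, cs = _central_region(holo.shape)
        diff = ph[rs, cs] - truth.phase[rs, cs]
        diff -= np.median(diff)
        assert np.sqrt(np.mean(diff**2)) < 0.01

    def test_filter_overlapping_zero_order_rejected(self, optics_quiet):
        holo = render_hologram(_flat_phase(optics_quiet), optics_quiet, 0, seed=1)
        fmag = optics_quiet.carrier_magnitude
        with pytest.raises(ValueError, match="zero-order"):
            reconstruct_fourier(holo, optics_quiet.carrier_freq,
                                filter_radius=0.99 * fmag)


class TestPropagate:
    def _gaussian_field(self, optics, w0=12.0):
        pitch = 0.5
        n = 256
        coords = (np.arange(n) - n / 2) * pitch
        xx, yy = np.meshgrid(coords, coords)
        data = np.exp(-(xx**2 + yy**2) / w0**2).astype(complex)
        return ComplexField(data, pitch, optics.wavelength_um)

    def test_zero_distance_identity(self, optics_small):
        f = self._gaussian_field(optics_small)
        g = propagate(f, 0.0)
        assert np.max(np.abs(g.data - f.data)) < 1e-10

    def test_forward_backward_unitarity(self, optics_small):
        f = self._gaussian_field(optics_small)
        g = propagate(propagate(f, 37.0), -37.0)
        rms = np.sqrt(np.mean(np.abs(g.data - f.data) ** 2))
        assert rms < 1e-8

    def test_power_conserved(self, optics_small):
        f = self._gaussian_field(optics_small)
        g = propagate(f, 80.0)
        assert g.power == pytest.approx(f.power, rel=1e-6)

    def test_gaussian_beam_width_law(self, optics_small):
        # closed-form oracle: w(z) = w0 sqrt(1 + (z λ / (π w0²))²)
        w0 = 10.0
        lam = optics_small.wavelength_um
        z = 400.0
        f = self._gaussian_field(optics_small, w0=w0)
        g = propagate(f, z)
        inten = np.abs(g.data) ** 2
        n = inten.shape[0]
        coords = (np.arange(n) - n / 2) * f.pixel_pitch_um
        xx, _ = np.meshgrid(coords, coords)
        var_x = float(np.sum(inten * xx**2) / np.sum(inten))
        w_meas = 2.0 * math.sqrt(var_x)
        zr = math.pi * w0**2 / lam
        w_expect = w0 * math.sqrt(1.0 + (z / zr) ** 2)
        assert w_meas == pytest.approx(w_expect, rel=0.02)


class TestAutofocus:
    """Refocusing needs structure near the resolution limit: wide smooth blobs
    sit inside their own depth of field and carry no focus cue, so these
    tests use the weak-phase fine-grained phantom on the 512×384 grid."""

    @staticmethod
    def _quiet_512():
        from holoassay.experiments import scaled_optics

        return scaled_optics(512, 384, shot_noise_scale=0.0,
                             parasitic_fringe_amplitude=0.0,
                             background_aberration_rad=0.0)

    def test_in_focus_field_returns_near_zero(self):
        from holoassay.experiments import focus_phantom

        opt = self._quiet_512()
        truth = focus_phantom(opt, seed=6)
        holo = render_hologram(truth, opt, 0, seed=7)
        field = reconstruct_fourier(holo, opt.carrier_freq)
        d = autofocus(field, search_range=(-60.0, 60.0), step_um=5.0)
        assert abs(d) <= 5.0

    def test_simulated_defocus_recovered(self):
        from holoassay.experiments import focus_phantom

        opt = replace(self._quiet_512(), defocus_um=50.0)
        truth = focus_phantom(opt, seed=8)
        holo = render_hologram(truth, opt, 0, seed=9)
        field = reconstruct_fourier(holo, opt.carrier_freq)
        d = autofocus(field, search_range=(-100.0, 100.0), step_um=5.0)
        assert d == pytest.approx(-50.0, abs=5.0)

    def test_flat_field_warns_and_returns_zero(self, optics_small):
        data = np.ones((128, 128), dtype=complex)
        field = ComplexField(data, optics_small.pixel_pitch_um,
                             optics_small.wavelength_um)
        with pytest.warns(UserWarning, match="flat"):
            assert autofocus(field, search_range=(-20, 20), step_um=10.0) == 0.0


class TestUnwrap:
    def test_planar_ramp_reaching_6pi(self):
        n = 128
        ramp = np.linspace(0.0, 6.0 * np.pi, n)[None, :] * np.ones((n, 1))
        wrapped = np.angle(np.exp(1j * ramp))
        out = unwrap_phase(wrapped)
        diff = out - ramp
        assert np.ptp(diff) < 1e-6  # exact up to a global piston

    def test_low_phase_blob_unchanged(self, optics_quiet):
        truth = blob_phantom(optics_quiet, seed=10, peak_range=(0.5, 2.8))
        wrapped = np.angle(np.exp(1j * truth.phase))
        out = unwrap_phase(wrapped)
        diff = out - truth.phase
        assert np.ptp(diff) < 1e-9

    def test_congruence_modulo_2pi(self, optics_quiet):
        truth = blob_phantom(optics_quiet, seed=11, peak_range=(2.0, 8.0))
        wrapped = np.angle(np.exp(1j * truth.phase))
        out = unwrap_phase(wrapped)
        k = (out - wrapped) / (2 * np.pi)
        assert np.max(np.abs(k - np.round(k))) < 1e-6


class TestCompensateBackground:
    def test_pure_tilt_removed_exactly(self):
        yy, xx = np.mgrid[0:160, 0:200]
        tilt = 0.8 * xx / 200 + 0.5 * yy / 160
        out = compensate_background(tilt, 0.88)
        assert np.max(np.abs(out.phase)) < 1e-6

    def test_blob_on_tilt_recovered(self, optics_quiet):
        truth = blob_phantom(optics_quiet, seed=12, peak_range=(0.8, 2.0))
        yy, xx = np.mgrid[0:truth.shape[0], 0:truth.shape[1]]
        tilt = 0.9 * xx / truth.shape[1] - 0.4 * yy / truth.shape[0]
        out = compensate_background(truth.phase + tilt, truth.pixel_pitch_um)
        diff = out.phase - truth.phase
        diff -= np.median(diff)
        assert np.sqrt(np.mean(diff**2)) < 0.02

    def test_idempotent_on_flat_input(self, optics_quiet):
        truth = blob_phantom(optics_quiet, seed=13, peak_range=(0.8, 1.5))
        once = compensate_background(truth.phase, truth.pixel_pitch_um)
        twice = compensate_background(once.phase, once.pixel_pitch_um)
        assert np.max(np.abs(twice.phase - once.phase)) < 5e-3

    def test_background_median_is_zero(self, optics_quiet):
        truth = blob_phantom(optics_quiet, seed=14)
        out = compensate_background(truth.phase + 0.7, truth.pixel_pitch_um)
        bg = out.phase[np.abs(out.phase) < 0.3]
        assert abs(np.median(bg)) < 0.05

    def test_dense_fov_falls_back_to_border(self):
        phase = np.full((128, 128), 2.0)
        phase[4:-4, 4:-4] = 3.0  # almost no background
        with pytest.warns(UserWarning, match="border"):
            compensate_background(phase, 0.88)


class TestAveragePhase:
    def _img(self, arr, pitch=0.88):
        return PhaseImage(arr, pitch)

    def test_identical_frames_average_to_the_frame(self, rng):
        base = rng.normal(0.0, 0.2, size=(96, 128))
        frames = [self._img(base.copy()) for _ in range(7)]
        out = average_phase(frames)
        expected = base - np.median(base)
        assert np.max(np.abs(out.phase - expected)) < 1e-12

    def test_opposite_fringes_cancel(self):
        yy, xx = np.mgrid[0:96, 0:128]
        fringe = 0.3 * np.sin(2 * np.pi * xx / 40.0)
        out = average_phase([self._img(fringe), self._img(-fringe)])
        assert np.max(np.abs(out.phase)) < 0.1 * 0.3

    def test_artifact_suppression_scales_with_sqrt_n(self, rng):
        # 7 frames = truth + independent zero-mean structured artifacts
        # (several sinusoidal components per frame, random orientations and
        # offsets); the averaged background RMS should drop by ~1/sqrt(7)
        yy, xx = np.mgrid[0:128, 0:160]
        singles = []
        frames = []
        for _ in range(7):
            art = np.zeros_like(xx, dtype=float)
            for _ in range(12):
                ang = rng.uniform(0, np.pi)
                off = rng.uniform(0, 2 * np.pi)
                period = rng.uniform(30.0, 80.0)
                art += 0.08 * np.cos(
                    2 * np.pi * (xx * np.cos(ang) + yy * np.sin(ang)) / period
                    + off
                )
            singles.append(np.sqrt(np.mean(art**2)))
            frames.append(self._img(art))
        out = average_phase(frames)
        ratio = np.sqrt(np.mean(out.phase**2)) / np.mean(singles)
        assert ratio == pytest.approx(1.0 / math.sqrt(7), rel=0.2)

    def test_geometry_mismatch_rejected(self):
        a = self._img(np.zeros((96, 128)))
        b = self._img(np.zeros((96, 100)))
        with pytest.raises(ValueError, match="geometry"):
            average_phase([a, b])

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            average_phase([self._img(np.zeros((96, 128)))])


class TestEndToEnd:
    def test_piston_invariance(self, optics_quiet):
        truth = blob_phantom(optics_quiet, seed=15, peak_range=(0.5, 1.5))
        shifted = PhaseImage(truth.phase + 1.3, truth.pixel_pitch_um,
                             wavelength_um=truth.wavelength_um)
        qpi_a = reconstruct_series(render_series(truth, optics_quiet, 21))
        qpi_b = reconstruct_series(render_series(shifted, optics_quiet, 21))
        rs, cs = _central_region(truth.shape)
        diff = qpi_a.phase[rs, cs] - qpi_b.phase[rs, cs]
        assert np.sqrt(np.mean(diff**2)) < 5e-3

    def test_full_chain_recovers_phantom(self):
        from holoassay.experiments import scaled_optics

        optics = scaled_optics(512, 384)  # default optics and noise
        truth = blob_phantom(optics, seed=16)
        qpi = reconstruct_series(render_series(truth, optics, 22))
        rs, cs = _central_region(truth.shape)
        diff = qpi.phase[rs, cs] - truth.phase[rs, cs]
        diff -= np.median(diff)
        assert np.sqrt(np.mean(diff**2)) < 0.05
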