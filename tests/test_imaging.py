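"""Space-variant image formation, sensor noise statistics, bank archive.

Oracles: a brute-force per-pixel superposition for the overlap-add renderer,
and closed-form Poisson/Gaussian moments for the sensor model.
"""

import numpy as np
import pytest

from edofscope import (OpticalConfig, SensorConfig, Scene, CaptureFrame,
                       PSFBank, build_defocus_grid, flat_mask, pupil_function,
                       simulate_psf, form_image, space_variant_oracle,
                       render_sparse, add_sensor_noise, dn_to_electrons,
                       demux_channels, save_bank, load_bank)


def _small_bank(small_optics, nz=2, anchors=2, window=21):
    """A (anchors x anchors x nz) bank of genuinely different defocus PSFs."""
    mask = flat_mask(small_optics.pupil_grid_size)
    grid = build_defocus_grid(300.0, nz)
    psfs = np.zeros((anchors, anchors, nz, 1, window, window))
    for iz, z in enumerate(grid.depths):
        psf = simulate_psf(pupil_function(small_optics, mask, z, "fluor"),
                           2.0, window)
        for iy in range(anchors):
            for ix in range(anchors):
                # perturb per anchor so field variation is actually exercised
                roll = iy + 2 * ix
                p = np.roll(psf, roll, axis=1)
                psfs[iy, ix, iz, 0] = p / p.sum()
    coords = np.linspace(-0.05, 0.05, anchors)
    return PSFBank(psfs=psfs, field_x_mm=coords, field_y_mm=coords,
                   depths=grid, channels=("fluor",), pixel_pitch_um=2.0)


class TestFormImage:
    def test_matches_oracle_exactly(self, small_optics):
        bank = _small_bank(small_optics)
        rng = np.random.default_rng(0)
        rad = rng.uniform(0.0, 100.0, (48, 48))
        depth = np.where(rng.uniform(size=(48, 48)) < 0.5, -150.0, 150.0)
        scene = Scene(rad, depth)
        # constant padding matches the oracle, which has no border content
        fast = form_image(scene, bank, pad_mode="constant")
        slow = space_variant_oracle(scene, bank)
        rms = np.sqrt(np.mean((fast - slow) ** 2)) / slow.max()
        assert rms < 1e-10

    def test_oracle_agreement_bilinear_window(self, small_optics):
        bank = _small_bank(small_optics)
        rng = np.random.default_rng(1)
        scene = Scene(rng.uniform(0, 10, (32, 32)), np.zeros((32, 32)))
        fast = form_image(scene, bank, window="bilinear", pad_mode="constant")
        slow = space_variant_oracle(scene, bank, window="bilinear")
        assert np.allclose(fast, slow, atol=1e-10 * slow.max())

    def test_flat_field_interior_flux(self, small_optics):
        """Uniform scene through unit-sum centered PSFs stays uniform.

        Anchor PSFs vary in defocus (width) but share their centroid; windowed
        blending then preserves a flat field away from the borders.
        """
        mask = flat_mask(small_optics.pupil_grid_size)
        grid = build_defocus_grid(300.0, 2)
        psfs = np.zeros((2, 2, 2, 1, 21, 21))
        for iy in range(2):
            for ix in range(2):
                for iz, z in enumerate(grid.depths):
                    extra = 40.0 * (iy + 2 * ix)  # field-dependent blur
                    psfs[iy, ix, iz, 0] = simulate_psf(
                        pupil_function(small_optics, mask, z + extra, "fluor"),
                        2.0, 21)
        coords = np.linspace(-0.05, 0.05, 2)
        bank = PSFBank(psfs=psfs, field_x_mm=coords, field_y_mm=coords,
                       depths=grid)
        scene = Scene(np.full((64, 64), 50.0), np.zeros((64, 64)))
        out = form_image(scene, bank)  # reflect padding
        interior = out[12:-12, 12:-12]
        # small residual ripple from window curvature over the kernel width
        assert np.all(np.abs(interior - 50.0) / 50.0 < 0.02)

    def test_depth_outside_span_rejected(self, small_optics):
        bank = _small_bank(small_optics)
        scene = Scene(np.ones((16, 16)), np.full((16, 16), 400.0))
        with pytest.raises(ValueError, match="span"):
            form_image(scene, bank)

    def test_unknown_window_rejected(self, small_optics):
        bank = _small_bank(small_optics)
        scene = Scene(np.ones((16, 16)), np.zeros((16, 16)))
        with pytest.raises(ValueError, match="window"):
            form_image(scene, bank, window="hann")

    def test_zero_scene_gives_zero(self, small_optics):
        bank = _small_bank(small_optics)
        scene = Scene(np.zeros((16, 16)), np.zeros((16, 16)))
        assert np.all(form_image(scene, bank) == 0)


class TestRenderSparse:
    def test_interior_point_flux(self, small_optics):
        bank = _small_bank(small_optics)
        out = render_sparse([(32.0, 30.0, 1000.0, 0.0)], (64, 64), bank)
        assert abs(out.sum() - 1000.0) / 1000.0 < 1e-9
        peak = np.unravel_index(out.argmax(), out.shape)
        assert abs(peak[0] - 32) <= 1 and abs(peak[1] - 30) <= 1

    def test_kernel_convolution_preserves_flux(self, small_optics):
        bank = _small_bank(small_optics)
        kernel = np.ones((3, 3)) / 9.0
        out = render_sparse([(32.0, 32.0, 500.0, 100.0)], (64, 64), bank,
                            kernel=kernel)
        assert abs(out.sum() - 500.0) / 500.0 < 1e-9


class TestSensorNoise:
    def test_dark_noise_statistics(self, fine_sensor):
        dark = np.zeros((400, 400))
        frame = add_sensor_noise(dark, sensor=fine_sensor, seed=3)
        e = dn_to_electrons(frame, fine_sensor)
        assert abs(e.mean()) < 0.1
        assert abs(e.std() - fine_sensor.read_noise_e) / fine_sensor.read_noise_e < 0.05

    def test_shot_plus_read_variance(self):
        sensor = SensorConfig(adc_bits=16, black_level_e=100.0,
                              quantum_efficiency=1.0)
        level = 1000.0
        frame = add_sensor_noise(np.full((400, 400), level), sensor=sensor,
                                 seed=4)
        e = dn_to_electrons(frame, sensor)
        expected_var = level + sensor.read_noise_e ** 2
        assert abs(e.mean() - level) / level < 0.01
        assert abs(e.var() - expected_var) / expected_var < 0.05

    def test_quantum_efficiency_scales_mean(self):
        sensor = SensorConfig(adc_bits=16, black_level_e=100.0,
                              quantum_efficiency=0.5)
        frame = add_sensor_noise(np.full((256, 256), 2000.0), sensor=sensor,
                                 seed=5)
        e = dn_to_electrons(frame, sensor)
        assert abs(e.mean() - 1000.0) / 1000.0 < 0.02

    def test_seed_determinism_and_distinctness(self, fine_sensor):
        img = np.full((64, 64), 500.0)
        a = add_sensor_noise(img, sensor=fine_sensor, seed=7).image
        b = add_sensor_noise(img, sensor=fine_sensor, seed=7).image
        c = add_sensor_noise(img, sensor=fine_sensor, seed=8).image
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_seed_required(self, fine_sensor):
        with pytest.raises(ValueError, match="seed"):
            add_sensor_noise(np.zeros((4, 4)), sensor=fine_sensor)

    def test_negative_irradiance_rejected(self, fine_sensor):
        with pytest.raises(ValueError, match="nonnegative"):
            add_sensor_noise(np.full((4, 4), -1.0), sensor=fine_sensor, seed=0)

    def test_full_well_clips(self):
        sensor = SensorConfig(adc_bits=16, quantum_efficiency=1.0)
        frame = add_sensor_noise(np.full((32, 32), 1e6), sensor=sensor, seed=9)
        assert np.all(frame.image <= sensor.adc_levels)
        assert frame.image.max() == sensor.adc_levels

    def test_sensor_metadata_roundtrip(self, fine_sensor):
        frame = add_sensor_noise(np.zeros((8, 8)), sensor=fine_sensor, seed=1)
        # dn_to_electrons recovers the sensor from metadata when not passed
        assert np.allclose(dn_to_electrons(frame),
                           dn_to_electrons(frame, fine_sensor))


class TestDemux:
    def test_tagged_frames(self):
        frames = [CaptureFrame(np.zeros((4, 4)), channel=c)
                  for c in ("fluor", "refl", "fluor")]
        fl, rf = demux_channels(frames)
        assert len(fl) == 2 and len(rf) == 1

    def test_timestamp_schedule(self):
        # 1 Hz alternation, first second fluorescence
        frames = [CaptureFrame(np.zeros((4, 4)), channel="untagged",
                               metadata={"timestamp_s": t})
                  for t in (0.1, 0.6, 1.2, 2.5, 3.9)]
        fl, rf = demux_channels(frames, switch_period_s=1.0)
        assert len(fl) == 3 and len(rf) == 2

    def test_untagged_without_timestamp(self):
        with pytest.raises(ValueError, match="timestamp"):
            demux_channels([CaptureFrame(np.zeros((4, 4)), channel="untagged")])


class TestBankValidationAndArchive:
    def test_unnormalized_rejected(self, small_optics):
        bank = _small_bank(small_optics)
        with pytest.raises(ValueError, match="normalized"):
            PSFBank(psfs=bank.psfs * 2.0, field_x_mm=bank.field_x_mm,
                    field_y_mm=bank.field_y_mm, depths=bank.depths)

    def test_axis_mismatch_rejected(self, small_optics):
        bank = _small_bank(small_optics)
        with pytest.raises(ValueError, match="depth"):
            PSFBank(psfs=bank.psfs, field_x_mm=bank.field_x_mm,
                    field_y_mm=bank.field_y_mm,
                    depths=build_defocus_grid(300.0, 5))

    def test_channel_lookup(self, small_optics):
        bank = _small_bank(small_optics)
        assert bank.channel_index("fluor") == 0
        with pytest.raises(ValueError, match="channel"):
            bank.channel_index("refl")

    def test_hdf5_roundtrip(self, small_optics, tmp_path):
        bank = _small_bank(small_optics)
        path = tmp_path / "bank.h5"
        save_bank(bank, path)
        back = load_bank(path)
        assert np.allclose(back.psfs, bank.psfs, atol=1e-6)
        assert np.array_equal(back.field_x_mm, bank.field_x_mm)
        assert np.array_equal(back.depths.depths, bank.depths.depths)
        assert back.channels == bank.channels
        assert back.source == bank.source
        assert np.allclose(back.psfs.sum(axis=(-2, -1)), 1.0)


class TestSceneValidation:
    def test_shape_congruence(self):
        with pytest.raises(ValueError, match="congruent"):
            Scene(np.ones((4, 4)), np.zeros((4, 5)))

    def test_negative_radiance(self):
        with pytest.raises(ValueError, match="nonnegative"):
            Scene(np.full((4, 4), -1.0), np.zeros((4, 4)))

    def test_capture_frame_2d(self):
        with pytest.raises(ValueError, match="2-D"):
            CaptureFrame(np.zeros((4, 4, 3)))
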