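"""Pinhole-array calibration: detection, extraction, interpolation.

Oracle: the synthetic acquisition generator returns the sub-pixel truth
(spot centers and the effective pinhole-convolved spots actually rendered),
so detection accuracy and bank fidelity are checked against known ground truth.
"""

import numpy as np
import pytest

from edofscope import (OpticalConfig, SensorConfig, PSFBank,
                       CalibrationProtocol, CalibrationQualityError,
                       build_defocus_grid, flat_mask, pupil_function,
                       simulate_psf, detect_pinholes, extract_psf_bank,
                       interpolate_bank, make_pinhole_stack)
from edofscope.optics import DefocusGrid
from edofscope.phantoms import _paste_subpixel


SMALL_PROTOCOL = CalibrationProtocol(
    pinhole_diameter_um=3.0, pitch_um=150.0, z_min_um=-100.0, z_max_um=100.0,
    z_step_um=100.0, repeats=3, patch_radius_px=15, grid_rows=3, grid_cols=4)
SMALL_SHAPE = (260, 360)


def _small_stack(small_optics, fine_sensor, seed=0, noiseless=False,
                 protocol=SMALL_PROTOCOL):
    mask = flat_mask(small_optics.pupil_grid_size)
    return make_pinhole_stack(protocol, mask, optics=small_optics,
                              sensor=fine_sensor, seed=seed,
                              shape=SMALL_SHAPE, noiseless=noiseless)


class TestProtocol:
    def test_reference_counts(self):
        p = CalibrationProtocol()
        assert len(p.depths) == 11
        assert np.allclose(np.diff(p.depths.depths), 50.0)
        assert p.depths.depths[0] == -250.0 and p.depths.depths[-1] == 250.0
        assert p.n_positions == 80
        assert p.repeats == 10

    def test_validation(self):
        with pytest.raises(ValueError, match="pitch"):
            CalibrationProtocol(pinhole_diameter_um=600.0)
        with pytest.raises(ValueError, match="integer"):
            CalibrationProtocol(z_step_um=37.0)
        with pytest.raises(ValueError, match="repeats"):
            CalibrationProtocol(repeats=0)


class TestDetection:
    def test_count_and_subpixel_accuracy(self, small_optics, fine_sensor):
        stacks, truth = _small_stack(small_optics, fine_sensor, noiseless=True)
        iz0 = SMALL_PROTOCOL.depths.nearest_index(0.0)
        frame = stacks[0, iz0]
        centers = detect_pinholes(frame, SMALL_PROTOCOL)
        assert centers.shape == (12, 2)
        err = np.linalg.norm(centers - truth["centers_px"], axis=1)
        assert err.max() < 0.3  # sub-pixel

    def test_row_major_ordering(self, small_optics, fine_sensor):
        stacks, truth = _small_stack(small_optics, fine_sensor, noiseless=True)
        iz0 = SMALL_PROTOCOL.depths.nearest_index(0.0)
        centers = detect_pinholes(stacks[0, iz0], SMALL_PROTOCOL)
        # rows increase slowly, columns fast
        assert np.all(np.diff(centers[::4, 0]) > 10)
        assert np.all(np.diff(centers[:4, 1]) > 10)

    def test_empty_frame_rejected(self):
        with pytest.raises(CalibrationQualityError, match="no pinholes"):
            detect_pinholes(np.zeros((128, 128)), SMALL_PROTOCOL)

    def test_grid_inconsistency_reports_offenders(self):
        # paste one column displaced by 25% of the pitch
        frame = np.zeros((260, 360))
        yy, xx = np.mgrid[-4:5, -4:5]
        spot = np.exp(-(yy ** 2 + xx ** 2) / 4.0) * 1000.0
        pitch = 75.0
        for r in range(3):
            for c in range(4):
                cx = 60 + c * pitch + (18.0 if c == 2 else 0.0)
                cy = 55 + r * pitch
                _paste_subpixel(frame, spot, cy, cx)
        with pytest.raises(CalibrationQualityError) as exc:
            detect_pinholes(frame, SMALL_PROTOCOL)
        assert exc.value.offenders
        assert any(kind == "col_spacing" for kind, _ in exc.value.offenders)


class TestExtraction:
    def test_bank_geometry(self, small_optics, fine_sensor):
        stacks, _ = _small_stack(small_optics, fine_sensor)
        bank = extract_psf_bank(stacks, SMALL_PROTOCOL)
        assert bank.psfs.shape == (3, 4, 3, 1, 31, 31)
        assert bank.source == "calibrated"
        assert np.allclose(bank.psfs.sum(axis=(-2, -1)), 1.0)
        # anchor coordinates straddle the frame center
        assert bank.field_x_mm[0] < 0 < bank.field_x_mm[-1]

    def test_roundtrip_fidelity(self, small_optics, fine_sensor):
        """Extracted spots match the generating effective spots within 5% RMS.

        The truth spot is re-pasted at its known sub-pixel center and cropped
        at the same rounded centroid as the extraction, so the comparison
        carries the same half-pixel placement as the measurement.
        """
        stacks, truth = _small_stack(small_optics, fine_sensor)
        bank = extract_psf_bank(stacks, SMALL_PROTOCOL)
        R = SMALL_PROTOCOL.patch_radius_px
        worst = 0.0
        for ip, (cy, cx) in enumerate(truth["centers_px"]):
            iy, ix = divmod(ip, 4)
            for iz in range(3):
                canvas = np.zeros(SMALL_SHAPE)
                _paste_subpixel(canvas, truth["effective_spots"][ip, iz],
                                cy, cx)
                ry, rx = int(round(cy)), int(round(cx))
                ref = canvas[ry - R:ry + R + 1, rx - R:rx + R + 1]
                ref = ref / ref.sum()
                got = bank.psfs[iy, ix, iz, 0]
                rms = np.sqrt(np.mean((got - ref) ** 2)) / ref.max()
                worst = max(worst, rms)
        assert worst < 0.05

    def test_repeat_averaging_sqrt_law(self, small_optics, fine_sensor):
        stacks, _ = _small_stack(small_optics, fine_sensor)
        # background corner far from every spot
        region = (slice(0, 25), slice(0, 25))
        single = stacks[0, 0][region].astype(float)
        mean10 = stacks[:, 0].mean(axis=0)[region]
        ratio = mean10.std() / single.std()
        expected = 1.0 / np.sqrt(SMALL_PROTOCOL.repeats)
        assert abs(ratio - expected) / expected < 0.2

    def test_shape_validation(self, fine_sensor):
        with pytest.raises(ValueError, match="repeats"):
            extract_psf_bank(np.zeros((4, 4, 4)), SMALL_PROTOCOL)
        with pytest.raises(ValueError, match="match the protocol"):
            extract_psf_bank(np.zeros((2, 3, 64, 64), dtype=np.uint16),
                             SMALL_PROTOCOL)

    def test_border_patch_rejected(self):
        proto = CalibrationProtocol(pitch_um=150.0, z_min_um=0.0, z_max_um=0.0,
                                    z_step_um=50.0, repeats=1,
                                    patch_radius_px=20, grid_rows=1,
                                    grid_cols=1)
        frame = np.zeros((64, 64))
        yy, xx = np.mgrid[-3:4, -3:4]
        _paste_subpixel(frame, np.exp(-(yy**2 + xx**2) / 2.0) * 500.0,
                        10.0, 10.0)
        stacks = frame[None, None]
        with pytest.raises(CalibrationQualityError, match="beyond"):
            extract_psf_bank(stacks, proto)

    def test_saturation_flagged(self, small_optics, fine_sensor):
        stacks, _ = _small_stack(small_optics, fine_sensor)
        # the check runs on the repeat-averaged stack, so pick a level that
        # the brightest averaged patch certainly exceeds
        level = 0.5 * float(stacks.mean(axis=0).max())
        with pytest.warns(UserWarning, match="saturated"):
            bank = extract_psf_bank(stacks, SMALL_PROTOCOL,
                                    saturation_level=level)
        assert bank.quality


class TestInterpolation:
    def _bank(self, small_optics):
        mask = flat_mask(small_optics.pupil_grid_size)
        grid = DefocusGrid(np.array([-150.0, 150.0]))
        psfs = np.zeros((2, 2, 2, 1, 21, 21))
        for iy in range(2):
            for ix in range(2):
                for iz, z in enumerate(grid.depths):
                    extra = 30.0 * (iy + 2 * ix)
                    psfs[iy, ix, iz, 0] = simulate_psf(
                        pupil_function(small_optics, mask, z + extra, "fluor"),
                        2.0, 21)
        coords = np.array([-0.5, 0.5])
        return PSFBank(psfs=psfs, field_x_mm=coords, field_y_mm=coords,
                       depths=grid)

    def test_anchor_recovery(self, small_optics):
        bank = self._bank(small_optics)
        got = interpolate_bank(bank, (-0.5, -0.5), -150.0)
        assert np.allclose(got, bank.psfs[0, 0, 0, 0])

    def test_midpoint_average(self, small_optics):
        bank = self._bank(small_optics)
        got = interpolate_bank(bank, (0.0, -0.5), -150.0)
        ref = 0.5 * (bank.psfs[0, 0, 0, 0] + bank.psfs[0, 1, 0, 0])
        assert np.allclose(got, ref / ref.sum())

    def test_clamped_outside_hull(self, small_optics):
        bank = self._bank(small_optics)
        assert np.allclose(interpolate_bank(bank, (-5.0, -5.0), -150.0),
                           interpolate_bank(bank, (-0.5, -0.5), -150.0))

    def test_nearest_depth(self, small_optics):
        bank = self._bank(small_optics)
        assert np.allclose(interpolate_bank(bank, (-0.5, -0.5), 40.0),
                           bank.psfs[0, 0, 1, 0])

    def test_unit_sum(self, small_optics):
        bank = self._bank(small_optics)
        got = interpolate_bank(bank, (0.17, -0.21), 60.0)
        assert np.isclose(got.sum(), 1.0)
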