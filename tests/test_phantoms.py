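"""Synthetic target generators: flux accounting, geometry, reproducibility.

Oracles: analytic bead flux (brightness x pi r^2), the USAF bar arithmetic
(three bars of width w at pitch 2w, length 5w), exact polarity inversion, and
the generator-returned ground truth for the pinhole stacks.
"""

import numpy as np
import pytest

from edofscope import (OpticalConfig, SensorConfig, CalibrationProtocol,
                       PhantomSpec, make_bead_slide, render_usaf,
                       make_tissue_phantom, make_pinhole_stack, disk_kernel,
                       usaf_linewidth, flat_mask)
from edofscope.phantoms import PlacementError, _paste_subpixel, \
    _place_nonoverlapping


class TestSpec:
    def test_grid_shape_and_area(self):
        spec = PhantomSpec()
        assert spec.grid_shape == (256, 256)
        assert np.isclose(spec.area_mm2, 0.512 ** 2)

    def test_validation(self):
        with pytest.raises(ValueError, match="kind"):
            PhantomSpec(kind="stars")
        with pytest.raises(ValueError, match="density"):
            PhantomSpec(bead_density_per_mm2=-1.0)
        with pytest.raises(ValueError, match="half-span"):
            PhantomSpec(surface_amplitude_um=500.0, sim_half_span_um=400.0)
        with pytest.raises(ValueError, match="integer number"):
            PhantomSpec(width_mm=0.5121)

    def test_dict_roundtrip(self):
        spec = PhantomSpec(kind="tissue", seed=7)
        assert PhantomSpec.from_dict(spec.to_dict()) == spec


class TestPrimitives:
    def test_disk_kernel_unit_sum_and_area(self):
        k = disk_kernel(3.0, 2.0, normalize=True)
        assert np.isclose(k.sum(), 1.0)
        raw = disk_kernel(3.0, 2.0, normalize=False)
        # total coverage equals the disk area in pixel units
        area_px = np.pi * (1.5 / 2.0) ** 2
        assert abs(raw.sum() - area_px) / area_px < 0.01

    def test_paste_subpixel_flux_and_centroid(self):
        canvas = np.zeros((32, 32))
        patch = np.ones((5, 5))
        _paste_subpixel(canvas, patch, 15.3, 16.7, scale=2.0)
        assert np.isclose(canvas.sum(), 2.0 * 25.0)
        yy, xx = np.mgrid[:32, :32]
        assert np.isclose((canvas * yy).sum() / canvas.sum(), 15.3)
        assert np.isclose((canvas * xx).sum() / canvas.sum(), 16.7)

    def test_placement_min_distance(self):
        rng = np.random.default_rng(0)
        pts = _place_nonoverlapping(rng, 30, (200, 200), 10.0, 5)
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 100.0

    def test_placement_error_when_too_dense(self):
        rng = np.random.default_rng(0)
        with pytest.raises(PlacementError, match="density"):
            _place_nonoverlapping(rng, 200, (40, 40), 10.0, 2,
                                  max_tries_factor=20)


class TestBeads:
    def test_exact_flux_per_bead(self):
        spec = PhantomSpec(seed=3)
        scene, centers = make_bead_slide(spec)
        r_px = 0.5 * spec.bead_diameter_um / spec.pixel_pitch_um
        expected = len(centers) * spec.bead_brightness * np.pi * r_px ** 2
        assert np.isclose(scene.radiance.sum(), expected, rtol=1e-9)

    def test_seeded_reproducibility(self):
        a, ca = make_bead_slide(PhantomSpec(seed=5))
        b, cb = make_bead_slide(PhantomSpec(seed=5))
        c, _ = make_bead_slide(PhantomSpec(seed=6))
        assert np.array_equal(a.radiance, b.radiance)
        assert np.array_equal(ca, cb)
        assert not np.array_equal(a.radiance, c.radiance)

    def test_zero_density(self):
        scene, centers = make_bead_slide(PhantomSpec(bead_density_per_mm2=0.0))
        assert centers.shape == (0, 2)
        assert np.all(scene.radiance == 0)

    def test_tilt_depth_map(self):
        spec = PhantomSpec(tilt_um_per_mm=100.0, slide_depth_um=10.0)
        scene, _ = make_bead_slide(spec)
        # depth varies along x only, crossing the slide depth at center
        assert np.allclose(scene.depth_map[0], scene.depth_map[-1])
        mid = scene.depth_map[0, 127:129].mean()
        assert abs(mid - 10.0) < 0.2
        span_mm = (spec.grid_shape[1] - 1) * spec.pixel_pitch_um * 1e-3
        assert np.isclose(scene.depth_map[0, -1] - scene.depth_map[0, 0],
                          100.0 * span_mm)

    def test_flat_slide_constant_depth(self):
        scene, _ = make_bead_slide(PhantomSpec(slide_depth_um=-30.0))
        assert np.all(scene.depth_map == -30.0)


class TestUSAFTarget:
    def test_registry_contents(self):
        scene, reg = render_usaf(PhantomSpec(kind="usaf"), groups=(6, 7))
        assert set(reg) == {(g, e) for g in (6, 7) for e in range(1, 7)}
        for (g, e), geom in reg.items():
            assert np.isclose(geom["linewidth_um"], usaf_linewidth(g, e))
        # group 7 element 1 is the paper's reference element
        assert np.isclose(reg[(7, 1)]["linewidth_um"], 3.90625)
        # sampling flag: below one pixel-pitch half, bars cannot be rendered
        assert reg[(7, 6)]["resolvable_by_sampling"] == \
            (usaf_linewidth(7, 6) >= 1.0)

    def test_bar_geometry(self):
        scene, reg = render_usaf(PhantomSpec(kind="usaf"), groups=(5,))
        geom = reg[(5, 1)]
        w_px = geom["linewidth_um"] / 2.0
        cy, cx = geom["center_v"]
        row = scene.radiance[int(round(cy))]
        # three vertical bars: bright at 0 and +/-2w, dark at +/-w
        for off, bright in ((-2 * w_px, True), (-w_px, False), (0.0, True),
                            (w_px, False), (2 * w_px, True)):
            v = row[int(round(cx + off))]
            assert (v > 0.5) == bright

    def test_polarity_inversion_exact(self):
        pos, _ = render_usaf(PhantomSpec(kind="usaf", usaf_invert=False),
                             groups=(6,))
        neg, _ = render_usaf(PhantomSpec(kind="usaf", usaf_invert=True),
                             groups=(6,))
        assert np.allclose(pos.radiance + neg.radiance, 1.0)

    def test_does_not_fit_raises(self):
        with pytest.raises(ValueError, match="does not fit"):
            render_usaf(PhantomSpec(kind="usaf"), groups=(2,))


class TestTissue:
    def test_channels_coregistered(self):
        spec = PhantomSpec(kind="tissue", seed=11)
        fl = make_tissue_phantom(spec, "fluor")
        rf = make_tissue_phantom(spec, "refl")
        # identical shared depth map, different radiance statistics
        assert np.array_equal(fl.depth_map, rf.depth_map)
        assert not np.array_equal(fl.radiance, rf.radiance)
        assert fl.channel == "fluor" and rf.channel == "refl"

    def test_depth_amplitude_bounded(self):
        spec = PhantomSpec(kind="tissue", seed=2, surface_amplitude_um=200.0)
        scene = make_tissue_phantom(spec, "fluor")
        surface = scene.depth_map.copy()
        # vessel pixels sit exactly one offset deeper than the surface
        assert surface.max() <= 200.0 + spec.vessel_depth_offset_um
        assert surface.min() >= -200.0

    def test_vessel_offset_present(self):
        spec = PhantomSpec(kind="tissue", seed=4)
        fl = make_tissue_phantom(spec, "fluor")
        rf = make_tissue_phantom(spec, "refl")
        # reflectance dips mark vessels; those pixels are deeper on average
        vessel = rf.radiance < 0.4
        assert vessel.any()
        nonvessel = ~vessel
        assert fl.depth_map[vessel].mean() > fl.depth_map[nonvessel].mean()

    def test_fluor_bright_nuclei_on_dim_background(self):
        scene = make_tissue_phantom(PhantomSpec(kind="tissue", seed=8),
                                    "fluor")
        assert np.median(scene.radiance) < 0.2      # background dominates
        assert scene.radiance.max() > 0.5           # nuclei are bright
        assert 0 <= scene.radiance.min() and scene.radiance.max() <= 1.0

    def test_seeded_reproducibility(self):
        a = make_tissue_phantom(PhantomSpec(kind="tissue", seed=9), "refl")
        b = make_tissue_phantom(PhantomSpec(kind="tissue", seed=9), "refl")
        assert np.array_equal(a.radiance, b.radiance)
        assert np.array_equal(a.depth_map, b.depth_map)

    def test_unknown_channel(self):
        with pytest.raises(ValueError, match="channel"):
            make_tissue_phantom(PhantomSpec(kind="tissue"), "uv")


class TestPinholeStack:
    PROTO = CalibrationProtocol(
        pinhole_diameter_um=3.0, pitch_um=150.0, z_min_um=-100.0,
        z_max_um=100.0, z_step_um=100.0, repeats=2, patch_radius_px=15,
        grid_rows=2, grid_cols=3)

    def _optics(self):
        return OpticalConfig(pupil_grid_size=128, psf_window_px=31)

    def test_shapes_and_truth(self, fine_sensor):
        stacks, truth = make_pinhole_stack(
            self.PROTO, flat_mask(128), optics=self._optics(),
            sensor=fine_sensor, shape=(240, 320), seed=1)
        assert stacks.shape == (2, 3, 240, 320)
        assert stacks.dtype == np.uint16
        assert truth["centers_px"].shape == (6, 2)
        assert np.array_equal(truth["depths_um"], [-100.0, 0.0, 100.0])
        assert truth["effective_spots"].shape == (6, 3, 31, 31)
        assert np.allclose(truth["effective_spots"].sum(axis=(-2, -1)), 1.0)

    def test_seed_determinism(self, fine_sensor):
        a, ta = make_pinhole_stack(self.PROTO, flat_mask(128),
                                   optics=self._optics(), sensor=fine_sensor,
                                   shape=(240, 320), seed=2)
        b, tb = make_pinhole_stack(self.PROTO, flat_mask(128),
                                   optics=self._optics(), sensor=fine_sensor,
                                   shape=(240, 320), seed=2)
        c, _ = make_pinhole_stack(self.PROTO, flat_mask(128),
                                  optics=self._optics(), sensor=fine_sensor,
                                  shape=(240, 320), seed=3)
        assert np.array_equal(a, b)
        assert np.array_equal(ta["centers_px"], tb["centers_px"])
        assert not np.array_equal(a, c)

    def test_noiseless_frames_are_pasted_spots(self, fine_sensor):
        stacks, truth = make_pinhole_stack(
            self.PROTO, flat_mask(128), optics=self._optics(),
            sensor=fine_sensor, shape=(240, 320), seed=4, noiseless=True)
        assert stacks.dtype == np.float64
        assert np.array_equal(stacks[0], stacks[1])  # repeats identical
        # rebuild one frame from the truth record; must match exactly
        iz = 1
        rebuilt = np.zeros((240, 320))
        for ip, (cy, cx) in enumerate(truth["centers_px"]):
            _paste_subpixel(rebuilt, truth["effective_spots"][ip, iz],
                            cy, cx, scale=truth["flux_e"])
        assert np.allclose(stacks[0, iz], rebuilt)

    def test_grid_must_fit(self, fine_sensor):
        with pytest.raises(ValueError, match="fit"):
            make_pinhole_stack(self.PROTO, flat_mask(128),
                               optics=self._optics(), sensor=fine_sensor,
                               shape=(100, 100), seed=0)
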