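"""Seeded synthetic scenes standing in for the physical targets.

Generators for every target class the system is validated against: fluorescent
bead slides (1 µm / 4 µm), negative USAF-1951 resolution charts, stylized
tissue textures (bright nuclei in fluorescence, dark branching vessels in
reflectance, a shared rough surface depth map), and pinhole-array calibration
stacks synthesized through the imaging forward model.

All generators are pure functions of (spec, seed).  The tissue texture is a
statistical look-alike, not a histologically calibrated model: nuclei are
bright (topical fluorescent labeling), vessels dark (hemoglobin absorption
under green light) and 100-200 µm deeper than the epithelial surface, whose
band-limited height variation is bounded by the spec amplitude (200 µm
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .config import OpticalConfig, SensorConfig, CHANNELS
from .imaging import Scene, add_sensor_noise
from .calibration import CalibrationProtocol, interpolate_bank
from .metrology import usaf_linewidth
from .optics import simulate_psf, pupil_function
from .phase_mask import PhaseMask

__all__ = [
    "PhantomSpec", "PlacementError", "disk_kernel",
    "make_bead_slide", "render_usaf", "make_tissue_phantom",
    "make_pinhole_stack",
]

KINDS = ("beads", "usaf", "tissue", "pinhole_grid")


class PlacementError(RuntimeError):
    """Non-overlapping placement failed within the retry budget."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and statistics of a synthetic target."""

    kind: str = "beads"
    width_mm: float = 0.512
    height_mm: float = 0.512
    pixel_pitch_um: float = 2.0
    seed: int = 0
    # beads
    bead_diameter_um: float = 1.0
    bead_density_per_mm2: float = 100.0
    bead_brightness: float = 1.0          # total flux per unit disk area (px^2)
    slide_depth_um: float = 0.0
    tilt_um_per_mm: float = 0.0           # depth gradient along x
    # usaf
    usaf_brightness: float = 1.0
    usaf_invert: bool = False             # True: dark bars on bright (positive chart)
    # tissue
    nuclei_density_per_mm2: float = 800.0
    nucleus_radius_um: float = 4.0        # lognormal median
    nucleus_radius_sigma: float = 0.25
    vessel_branch_depth: int = 3
    vessel_width_um: float = 12.0
    surface_amplitude_um: float = 200.0
    surface_correlation_um: float = 150.0
    vessel_depth_offset_um: float = 150.0
    # simulation envelope the scene must stay inside
    sim_half_span_um: float = 400.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; expected {KINDS}")
        if self.width_mm <= 0 or self.height_mm <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("field dimensions and pitch must be positive")
        for n, v in (("bead density", self.bead_density_per_mm2),
                     ("nuclei density", self.nuclei_density_per_mm2)):
            if v < 0:
                raise ValueError(f"{n} must be nonnegative")
        if self.bead_diameter_um <= 0:
            raise ValueError("bead diameter must be positive")
        if self.surface_amplitude_um < 0 or \
                self.surface_amplitude_um > self.sim_half_span_um:
            raise ValueError("surface amplitude must lie within the simulation "
                             "half-span")
        for dim_mm in (self.width_mm, self.height_mm):
            n = dim_mm * 1e3 / self.pixel_pitch_um
            if abs(n - round(n)) > 1e-6:
                raise ValueError("field dimensions must be an integer number "
                                 "of pixels")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (int(round(self.height_mm * 1e3 / self.pixel_pitch_um)),
                int(round(self.width_mm * 1e3 / self.pixel_pitch_um)))

    @property
    def area_mm2(self) -> float:
        return self.width_mm * self.height_mm

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


# ----------------------------------------------------------------------
# pitch-integrated primitives
# ----------------------------------------------------------------------

def disk_kernel(diameter_um: float, pitch_um: float, supersample: int = 16,
                normalize: bool = True) -> np.ndarray:
    """Pixel-integrated profile of a uniform disk (e.g. a bead or pinhole).

    Each entry is the fraction of the pixel covered by the disk, estimated on
    a ``supersample`` x ``supersample`` sub-grid; with ``normalize`` the kernel
    sums to 1.
    """
    r_px = 0.5 * diameter_um / pitch_um
    half = int(np.ceil(r_px)) + 1
    n = 2 * half + 1
    ss = supersample
    coords = (np.arange(n * ss) + 0.5) / ss - (n / 2.0)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    inside = (yy ** 2 + xx ** 2) <= r_px ** 2
    cover = inside.reshape(n, ss, n, ss).mean(axis=(1, 3))
    if normalize:
        s = cover.sum()
        if s <= 0:
            raise ValueError("disk smaller than the sub-sampling resolution")
        cover = cover / s
    return cover


def _paste_subpixel(canvas: np.ndarray, patch: np.ndarray, cy: float, cx: float,
                    scale: float = 1.0) -> None:
    """Add ``patch`` (odd-sized, centered) at a sub-pixel position.

    The fractional offset is realized by bilinear splitting over the four
    neighbouring integer positions, which preserves total flux and the
    centroid exactly.
    """
    ph, pw = patch.shape
    iy, ix = int(np.floor(cy)), int(np.floor(cx))
    fy, fx = cy - iy, cx - ix
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            w = wy * wx
            if w == 0:
                continue
            r0 = iy + dy - ph // 2
            c0 = ix + dx - pw // 2
            rr0, cc0 = max(r0, 0), max(c0, 0)
            rr1 = min(r0 + ph, canvas.shape[0])
            cc1 = min(c0 + pw, canvas.shape[1])
            if rr0 >= rr1 or cc0 >= cc1:
                continue
            canvas[rr0:rr1, cc0:cc1] += scale * w * \
                patch[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]


def _place_nonoverlapping(rng, n, shape, min_dist_px, margin_px,
                          max_tries_factor=200):
    """Uniform random centers with a minimum pairwise distance."""
    H, W = shape
    if H - 2 * margin_px <= 0 or W - 2 * margin_px <= 0:
        raise PlacementError("margin leaves no interior to place into")
    centers = []
    tries = 0
    budget = max_tries_factor * max(n, 1)
    while len(centers) < n:
        if tries >= budget:
            raise PlacementError(
                f"placed only {len(centers)}/{n} points without overlap; "
                "density too high for non-overlapping placement")
        tries += 1
        cy = rng.uniform(margin_px, H - 1 - margin_px)
        cx = rng.uniform(margin_px, W - 1 - margin_px)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_dist_px ** 2
               for y, x in centers):
            centers.append((cy, cx))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


# ----------------------------------------------------------------------
# bead slides
# ----------------------------------------------------------------------

def make_bead_slide(spec: PhantomSpec, channel: str = "fluor"):
    """(Scene, centers): sub-pixel beads on a flat or tilted slide.

    Beads are pitch-integrated uniform disks at non-overlapping uniform random
    positions; each bead carries exactly its analytic flux
    brightness x pi x (r/pitch)^2.  ``centers`` is an (n, 2) array of
    (row, col) positions for metrology ground truth.
    """
    H, W = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    n = rng.poisson(spec.bead_density_per_mm2 * spec.area_mm2)
    r_px = 0.5 * spec.bead_diameter_um / spec.pixel_pitch_um
    margin = int(np.ceil(r_px)) + 2
    centers = _place_nonoverlapping(rng, n, (H, W), 2.0 * r_px + 1.0, margin) \
        if n else np.zeros((0, 2))
    kernel = disk_kernel(spec.bead_diameter_um, spec.pixel_pitch_um,
                         normalize=True)
    flux = spec.bead_brightness * np.pi * r_px ** 2
    radiance = np.zeros((H, W))
    for cy, cx in centers:
        _paste_subpixel(radiance, kernel, cy, cx, scale=flux)
    xs_mm = (np.arange(W) - (W - 1) / 2.0) * spec.pixel_pitch_um * 1e-3
    depth = spec.slide_depth_um + spec.tilt_um_per_mm * xs_mm
    depth_map = np.broadcast_to(depth, (H, W)).copy()
    return Scene(radiance=radiance, depth_map=depth_map, channel=channel), centers


# ----------------------------------------------------------------------
# USAF 1951 target
# ----------------------------------------------------------------------

def _add_rect(img: np.ndarray, y0: float, y1: float, x0: float, x1: float,
              value: float) -> None:
    """Add an axis-aligned rectangle with exact per-pixel area coverage."""
    H, W = img.shape
    ys = np.clip(np.minimum(np.arange(H) + 1, y1) - np.maximum(np.arange(H), y0),
                 0.0, 1.0)
    xs = np.clip(np.minimum(np.arange(W) + 1, x1) - np.maximum(np.arange(W), x0),
                 0.0, 1.0)
    img += value * np.outer(ys, xs)


def _render_three_bars(img, cy, cx, w_px, orient, value):
    """Three bars of width w, pitch 2w, length 5w, centered at (cy, cx)."""
    L = 5.0 * w_px
    for k in (-2.0, 0.0, 2.0):
        if orient == "h":     # horizontal bars stacked vertically
            _add_rect(img, cy + k * w_px - w_px / 2, cy + k * w_px + w_px / 2,
                      cx - L / 2, cx + L / 2, value)
        else:                 # vertical bars side by side
            _add_rect(img, cy - L / 2, cy + L / 2,
                      cx + k * w_px - w_px / 2, cx + k * w_px + w_px / 2, value)


def render_usaf(spec: PhantomSpec, groups=(6, 7)):
    """(Scene, registry): negative USAF-1951 chart, bright bars on dark.

    Each element renders its horizontal and vertical three-bar sets side by
    side; the registry maps (group, element) to the geometry consumed by the
    resolvability scorer: line width (µm), per-orientation set centers
    (pixels) and a ``resolvable_by_sampling`` flag (False when the line width
    falls under half the pixel pitch).  ``spec.usaf_invert`` flips to positive
    polarity exactly (brightness − image).
    """
    H, W = spec.grid_shape
    img = np.zeros((H, W))
    registry = {}
    pitch = spec.pixel_pitch_um
    margin_px = 8.0
    x_cursor = margin_px
    for g in groups:
        y_cursor = margin_px
        col_width = 0.0
        for e in range(1, 7):
            lw_um = usaf_linewidth(g, e)
            w_px = lw_um / pitch
            set_h = 5.0 * w_px           # each three-bar set spans 5w x 5w
            gap = 2.0 * w_px + 4.0
            cell_w = 2 * set_h + gap
            cell_h = set_h + 6.0
            if y_cursor + cell_h > H - margin_px or \
                    x_cursor + cell_w > W - margin_px:
                raise ValueError(
                    f"group {g} element {e} does not fit the "
                    f"{spec.width_mm} x {spec.height_mm} mm field")
            cy = y_cursor + cell_h / 2.0
            cx_h = x_cursor + set_h / 2.0
            cx_v = x_cursor + set_h + gap + set_h / 2.0
            _render_three_bars(img, cy, cx_h, w_px, "h", spec.usaf_brightness)
            _render_three_bars(img, cy, cx_v, w_px, "v", spec.usaf_brightness)
            registry[(g, e)] = {
                "linewidth_um": lw_um,
                "center_h": (cy, cx_h),
                "center_v": (cy, cx_v),
                "resolvable_by_sampling": bool(lw_um >= pitch / 2.0),
            }
            y_cursor += cell_h
            col_width = max(col_width, cell_w)
        x_cursor += col_width + 10.0
    if spec.usaf_invert:
        img = spec.usaf_brightness - img
    img = np.clip(img, 0.0, None)
    depth_map = np.zeros((H, W)) + spec.slide_depth_um
    return Scene(radiance=img, depth_map=depth_map, channel="refl"), registry


# ----------------------------------------------------------------------
# tissue
# ----------------------------------------------------------------------

def _band_limited_surface(rng, shape, amplitude_um, correlation_um, pitch_um):
    if amplitude_um == 0:
        return np.zeros(shape)
    noise = rng.normal(size=shape)
    sigma_px = max(correlation_um / pitch_um, 1.0)
    smooth = ndimage.gaussian_filter(noise, sigma_px, mode="wrap")
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.zeros(shape)
    return smooth * (amplitude_um / peak)


def _grow_vessels(rng, shape, spec):
    """Recursive branching tree drawn as a soft width mask in [0, 1]."""
    H, W = shape
    mask = np.zeros(shape)
    w0_px = spec.vessel_width_um / spec.pixel_pitch_um

    def draw_segment(y, x, ang, width_px, gen):
        step = max(2.0, 1.5 * width_px)
        n_steps = int(rng.integers(6, 14))
        r_stamp = max(width_px / 2.0, 0.7)
        r_int = int(np.ceil(r_stamp))
        yy, xx = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
        stamp = np.clip(r_stamp + 0.5 - np.hypot(yy, xx), 0.0, 1.0)
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.25)
            y += step * np.sin(ang)
            x += step * np.cos(ang)
            if not (0 <= y < H and 0 <= x < W):
                return
            iy, ix = int(round(y)), int(round(x))
            y0, y1 = max(iy - r_int, 0), min(iy + r_int + 1, H)
            x0, x1 = max(ix - r_int, 0), min(ix + r_int + 1, W)
            sub = stamp[y0 - (iy - r_int):y1 - (iy - r_int),
                        x0 - (ix - r_int):x1 - (ix - r_int)]
            np.maximum(mask[y0:y1, x0:x1], sub, out=mask[y0:y1, x0:x1])
        if gen < spec.vessel_branch_depth:
            for sign in (-1.0, 1.0):
                if rng.uniform() < 0.7:
                    draw_segment(y, x, ang + sign * rng.uniform(0.4, 0.9),
                                 width_px * 0.7, gen + 1)

    n_trunks = max(2, int(round(np.sqrt(H * W) / 48)))
    for _ in range(n_trunks):
        edge = rng.integers(4)
        if edge == 0:
            y, x, ang = 0.0, rng.uniform(0, W - 1), np.pi / 2
        elif edge == 1:
            y, x, ang = float(H - 1), rng.uniform(0, W - 1), -np.pi / 2
        elif edge == 2:
            y, x, ang = rng.uniform(0, H - 1), 0.0, 0.0
        else:
            y, x, ang = rng.uniform(0, H - 1), float(W - 1), np.pi
        draw_segment(y, x, ang + rng.normal(0.0, 0.3), w0_px, 0)
    return mask


def make_tissue_phantom(spec: PhantomSpec, channel: str) -> Scene:
    """Stylized epithelium: nuclei (fluorescence) or vasculature (reflectance).

    All geometry — the band-limited surface, nucleus placement and the vessel
    tree — is generated from ``spec.seed`` alone, so the two channels of the
    same spec are exactly coregistered and share one depth map: the surface
    height, plus the configured vessel depth offset on vessel pixels (vessels
    run deeper than the epithelial surface).
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    H, W = spec.grid_shape
    rng = np.random.default_rng(spec.seed)

    surface = _band_limited_surface(rng, (H, W), spec.surface_amplitude_um,
                                    spec.surface_correlation_um,
                                    spec.pixel_pitch_um)
    # nuclei geometry
    n_nuclei = rng.poisson(spec.nuclei_density_per_mm2 * spec.area_mm2)
    r_med_px = spec.nucleus_radius_um / spec.pixel_pitch_um
    try:
        centers = _place_nonoverlapping(rng, n_nuclei, (H, W),
                                        2.2 * r_med_px, 1) \
            if n_nuclei else np.zeros((0, 2))
    except PlacementError:
        # dense fields saturate; keep what fits rather than failing tissue synth
        centers = _place_nonoverlapping(rng, max(n_nuclei // 2, 1), (H, W),
                                        2.2 * r_med_px, 1)
    nuclei = []
    for cy, cx in centers:
        r = r_med_px * rng.lognormal(0.0, spec.nucleus_radius_sigma)
        ecc = rng.uniform(0.7, 1.0)
        theta = rng.uniform(0.0, np.pi)
        amp = rng.uniform(0.6, 1.0)
        nuclei.append((cy, cx, r, ecc, theta, amp))
    vessel_soft = _grow_vessels(rng, (H, W), spec)
    vessel_mask = vessel_soft > 0.5

    if channel == "fluor":
        radiance = np.full((H, W), 0.05)
        for cy, cx, r, ecc, theta, amp in nuclei:
            rr = int(np.ceil(3 * r))
            y0, y1 = max(int(cy) - rr, 0), min(int(cy) + rr + 1, H)
            x0, x1 = max(int(cx) - rr, 0), min(int(cx) + rr + 1, W)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            u = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
            v = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
            q = (u / r) ** 2 + (v / (r * ecc)) ** 2
            radiance[y0:y1, x0:x1] += amp * np.exp(-0.5 * q * 4.0)
        radiance = np.clip(radiance, 0.0, 1.0)
    else:
        radiance = np.full((H, W), 0.85)
        radiance += 0.05 * ndimage.gaussian_filter(rng.normal(size=(H, W)), 3.0)
        radiance -= 0.65 * vessel_soft
        radiance = np.clip(radiance, 0.02, 1.0)

    depth_map = surface + spec.vessel_depth_offset_um * vessel_mask
    return Scene(radiance=radiance, depth_map=depth_map, channel=channel)


# ----------------------------------------------------------------------
# pinhole calibration stacks
# ----------------------------------------------------------------------

def make_pinhole_stack(protocol: CalibrationProtocol, system,
                       optics: OpticalConfig | None = None,
                       sensor: SensorConfig | None = None, seed: int = 0,
                       shape: tuple | None = None, flux_e: float = 5000.0,
                       jitter_px: float = 0.3, channel: str = "fluor",
                       noiseless: bool = False):
    """Synthetic calibration acquisition: (stacks, truth).

    ``system`` is either a :class:`PhaseMask` (PSFs simulated per depth
    through ``optics``; space-invariant) or a :class:`~.imaging.PSFBank`
    (PSFs interpolated per grid position).  The protocol's pinhole grid
    (8 x 10 at 500 µm pitch by default) is imaged at every protocol depth with
    the configured repeats and full sensor noise; DN frames are returned as a
    (repeats, n_depths, H, W) uint16 array.

    ``truth`` carries the sub-pixel spot centers (row-major (n, 2)), the depth
    grid, and the effective spots actually rendered — the generating PSFs
    convolved with the pitch-integrated pinhole disk — against which an
    extracted bank should be compared (the finite 3 µm pinhole is part of the
    measured response).
    """
    sensor = sensor or SensorConfig()
    if isinstance(system, PhaseMask):
        optics = optics or OpticalConfig()
        pitch_um = optics.pixel_pitch_um
        if shape is None:
            shape = optics.sensor_shape
    else:
        pitch_um = system.pixel_pitch_um
        if shape is None:
            shape = OpticalConfig(pixel_pitch_um=pitch_um).sensor_shape
    H, W = shape
    depths = protocol.depths.depths
    pitch_px = protocol.pitch_um / pitch_um
    rows, cols = protocol.grid_rows, protocol.grid_cols

    # centered grid with small sub-pixel jitter; must keep the patch inside
    margin = 40.0
    if (rows - 1) * pitch_px > H - 2 * margin or \
            (cols - 1) * pitch_px > W - 2 * margin:
        raise ValueError(
            f"{rows} x {cols} grid at {protocol.pitch_um} µm pitch does not "
            f"fit a {H} x {W} frame")
    rng = np.random.default_rng(seed)
    y0 = (H - 1 - (rows - 1) * pitch_px) / 2.0
    x0 = (W - 1 - (cols - 1) * pitch_px) / 2.0
    centers = np.array([[y0 + r * pitch_px + rng.uniform(-jitter_px, jitter_px),
                         x0 + c * pitch_px + rng.uniform(-jitter_px, jitter_px)]
                        for r in range(rows) for c in range(cols)])

    pinhole = disk_kernel(protocol.pinhole_diameter_um, pitch_um, normalize=True)

    def effective_psf(pos_idx, iz):
        if isinstance(system, PhaseMask):
            key = iz
        else:
            key = (pos_idx, iz)
        if key not in _cache:
            if isinstance(system, PhaseMask):
                psf = simulate_psf(
                    pupil_function(optics, system, float(depths[iz]), channel),
                    pitch_um, optics.psf_window_px)
            else:
                cy, cx = centers[pos_idx]
                pos_mm = ((cx - (W - 1) / 2.0) * pitch_um * 1e-3,
                          (cy - (H - 1) / 2.0) * pitch_um * 1e-3)
                psf = interpolate_bank(system, pos_mm, float(depths[iz]),
                                       channel=channel)
            eff = np.clip(fftconvolve(psf, pinhole, mode="same"), 0.0, None)
            _cache[key] = eff / eff.sum()
        return _cache[key]

    _cache: dict = {}
    n_pos = len(centers)
    # noiseless frames stay in float electrons (exact impulse-definition
    # checks); noisy frames are quantized DN stored compactly as uint16
    stacks = np.zeros((protocol.repeats, len(depths), H, W),
                      dtype=np.float64 if noiseless else np.uint16)
    eff_shape = effective_psf(0, 0).shape
    effective = np.zeros((n_pos, len(depths)) + eff_shape)
    for iz in range(len(depths)):
        clean = np.zeros((H, W))
        for ip, (cy, cx) in enumerate(centers):
            eff = effective_psf(ip, iz)
            effective[ip, iz] = eff
            _paste_subpixel(clean, eff, cy, cx, scale=flux_e)
        if noiseless:
            stacks[:, iz] = clean
            continue
        for rep in range(protocol.repeats):
            frame = add_sensor_noise(
                clean, sensor=sensor,
                seed=int(rng.integers(2 ** 31)), channel=channel,
                metadata={"depth_um": float(depths[iz]), "repeat": rep})
            stacks[rep, iz] = frame.image.astype(np.uint16)

    truth = {
        "centers_px": centers,
        "depths_um": depths.copy(),
        "effective_spots": effective,
        "flux_e": flux_e,
        "channel": channel,
        "pixel_pitch_um": pitch_um,
    }
    return stacks, truth
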