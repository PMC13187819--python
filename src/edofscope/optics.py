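"""Scalar Fourier-optics core: pupil construction, defocus, incoherent PSFs.

The system is modeled as a unit-magnification incoherent imager with a phase
element at the Fourier plane.  The pupil is a circular aperture of radius
NA/lambda in spatial frequency; a depth offset z adds the paraxial defocus
phase pi*lambda*z*rho^2 (rho the radial spatial frequency), an approximation
accurate to well below a milliradian of wavefront error at NA 0.1.  The
intensity PSF is |centered inverse DFT of the pupil|^2, computed on a fine
internal grid and box-integrated to the sensor pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import OpticalConfig

__all__ = [
    "DefocusGrid", "Pupil", "build_defocus_grid", "pupil_function",
    "simulate_psf", "psf_stack", "frequency_grids", "aperture_mask",
    "defocus_phase", "mtf", "mtf_at",
]


# ----------------------------------------------------------------------
# depth grid
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DefocusGrid:
    """Ordered signed axial offsets (µm) relative to the nominal focal plane."""

    depths: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("depth grid must be a nonempty 1-D sequence")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        object.__setattr__(self, "depths", d)

    def __len__(self):
        return self.depths.size

    def __iter__(self):
        return iter(self.depths)

    def nearest_index(self, z) -> np.ndarray:
        """Index of the nearest plane for each query depth (ties to lower index)."""
        z = np.asarray(z, dtype=float)
        return np.abs(z[..., None] - self.depths).argmin(axis=-1)

    @property
    def span(self) -> float:
        return float(self.depths[-1] - self.depths[0])


def build_defocus_grid(span_um: float, n_planes: int) -> DefocusGrid:
    """Uniform grid of ``n_planes`` depths covering [-span/2, +span/2].

    A 500 µm span with 21 planes gives the 25 µm training spacing; with 11
    planes it gives the -250..+250 µm, 50 µm-step calibration ladder.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    if span_um <= 0:
        raise ValueError("span must be positive")
    if n_planes == 1:
        return DefocusGrid(np.array([0.0]))
    return DefocusGrid(np.linspace(-span_um / 2.0, span_um / 2.0, n_planes))


# ----------------------------------------------------------------------
# pupil construction
# ----------------------------------------------------------------------

@dataclass
class Pupil:
    """Complex pupil amplitude on a centered spatial-frequency grid."""

    complex_amplitude: np.ndarray
    frequency_pitch: float       # cycles/µm per sample
    wavelength_nm: float
    pad_factor: int = 2

    def __post_init__(self):
        a = np.asarray(self.complex_amplitude)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("pupil grid must be square")
        if not np.all(np.isfinite(a.real)) or not np.all(np.isfinite(a.imag)):
            raise ValueError("pupil contains non-finite values")

    @property
    def grid_size(self) -> int:
        return self.complex_amplitude.shape[0]


def frequency_grids(cfg: OpticalConfig):
    """Centered (fy, fx) coordinate arrays (cycles/µm) on the N x N pupil grid."""
    n = cfg.pupil_grid_size
    coords = (np.arange(n) - n // 2) * cfg.frequency_pitch
    return np.meshgrid(coords, coords, indexing="ij")


def aperture_mask(cfg: OpticalConfig, channel: str) -> np.ndarray:
    """Binary circular aperture of radius NA/lambda on the pupil grid."""
    fy, fx = frequency_grids(cfg)
    fc = cfg.cutoff_frequency(cfg.wavelength_nm(channel))
    return (fx ** 2 + fy ** 2 <= fc ** 2).astype(float)


def defocus_phase(cfg: OpticalConfig, z_um: float, channel: str) -> np.ndarray:
    """Paraxial defocus phase pi * lambda * z * rho^2 (radians) on the pupil grid."""
    fy, fx = frequency_grids(cfg)
    lam_um = cfg.wavelength_nm(channel) * 1e-3
    return np.pi * lam_um * z_um * (fx ** 2 + fy ** 2)


def pupil_function(cfg: OpticalConfig, mask, z_um: float, channel: str) -> Pupil:
    """Complex pupil for a phase mask at depth offset ``z_um``.

    ``mask`` is a :class:`~edofscope.phase_mask.PhaseMask` whose height map is
    congruent with the pupil grid; its thin-element phase adds to the defocus
    term inside the aperture.
    """
    if abs(z_um) > cfg.max_defocus_um:
        raise ValueError(
            f"depth {z_um} µm outside the simulated range +/-{cfg.max_defocus_um} µm")
    n = cfg.pupil_grid_size
    if mask.height_map.shape != (n, n):
        raise ValueError(
            f"mask grid {mask.height_map.shape} does not match pupil grid {(n, n)}")
    from .phase_mask import height_to_phase

    wavelength = cfg.wavelength_nm(channel)
    amp = aperture_mask(cfg, channel)
    phase = height_to_phase(mask.height_map, wavelength, cfg.mask_refractive_index)
    phase = phase + defocus_phase(cfg, z_um, channel)
    return Pupil(amp * np.exp(1j * phase), cfg.frequency_pitch, wavelength, cfg.pad_factor)


# ----------------------------------------------------------------------
# PSF simulation
# ----------------------------------------------------------------------

def _centered_ifft2(z):
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(z), norm="ortho"))


def simulate_psf(pupil: Pupil, out_pitch_um: float, window_px: int | None = None) -> np.ndarray:
    """Energy-normalized intensity PSF sampled at ``out_pitch_um``.

    The pupil is zero-padded by its pad factor, inverse-transformed, squared,
    cropped to a centered window and box-integrated down to the requested
    pitch.  The output sums to 1 exactly.
    """
    if out_pitch_um <= 0:
        raise ValueError("output pitch must be positive")
    if not np.any(np.abs(pupil.complex_amplitude) > 0):
        raise ValueError("empty aperture: cutoff below one frequency sample")
    n = pupil.grid_size
    m = pupil.pad_factor * n
    internal_pitch = 1.0 / (m * pupil.frequency_pitch)
    binf = out_pitch_um / internal_pitch
    bin_factor = int(round(binf))
    if bin_factor < 1 or abs(binf - bin_factor) > 1e-9:
        raise ValueError(
            f"output pitch {out_pitch_um} µm is not an integer multiple of the "
            f"internal pitch {internal_pitch:.6g} µm")
    padded = np.zeros((m, m), dtype=complex)
    lo = (m - n) // 2
    padded[lo:lo + n, lo:lo + n] = pupil.complex_amplitude
    field = _centered_ifft2(padded)
    intensity = (field * np.conj(field)).real

    if window_px is None:
        window_px = m // bin_factor
    w_int = window_px * bin_factor
    if w_int > m:
        raise ValueError("PSF window larger than the simulated field")
    lo = m // 2 - w_int // 2
    crop = intensity[lo:lo + w_int, lo:lo + w_int]
    psf = crop.reshape(window_px, bin_factor, window_px, bin_factor).sum(axis=(1, 3))
    total = psf.sum()
    if total <= 0:
        raise ValueError("degenerate PSF with zero energy")
    return psf / total


def psf_stack(cfg: OpticalConfig, mask, grid: DefocusGrid, channel: str,
              out_pitch_um: float | None = None, window_px: int | None = None):
    """One-field-position PSF bank: a normalized PSF per depth in grid order."""
    from .imaging import PSFBank

    pitch = cfg.pixel_pitch_um if out_pitch_um is None else out_pitch_um
    wpx = cfg.psf_window_px if window_px is None else window_px
    psfs = np.stack([
        simulate_psf(pupil_function(cfg, mask, z, channel), pitch, wpx)
        for z in grid.depths
    ])
    return PSFBank(
        psfs=psfs[None, None, :, None],            # (ny=1, nx=1, nz, nch=1, h, w)
        field_x_mm=np.array([0.0]),
        field_y_mm=np.array([0.0]),
        depths=grid,
        channels=(channel,),
        source="simulated",
        pixel_pitch_um=pitch,
    )


# ----------------------------------------------------------------------
# MTF utilities
# ----------------------------------------------------------------------

def mtf(psf: np.ndarray, pitch_um: float):
    """Modulation transfer function |FT(psf)| normalized to 1 at DC.

    Returns (frequency axis in cycles/µm along one dimension, centered 2-D MTF).
    """
    otf = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(psf)))
    m = np.abs(otf)
    m /= m[psf.shape[0] // 2, psf.shape[1] // 2]
    freqs = np.fft.fftshift(np.fft.fftfreq(psf.shape[0], d=pitch_um))
    return freqs, m


def mtf_at(psf: np.ndarray, pitch_um: float, freq_cyc_um: float, axis: str = "h") -> float:
    """MTF value at a given spatial frequency along the horizontal or vertical axis."""
    freqs, m = mtf(psf, pitch_um)
    c = psf.shape[0] // 2
    profile = m[c, :] if axis == "h" else m[:, c]
    if freq_cyc_um > freqs.max():
        raise ValueError("frequency beyond the sampled band")
    return float(np.interp(freq_cyc_um, freqs, profile))
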