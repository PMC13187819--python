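"""Fourier-plane phase mask: parameterization, baselines, constraints, I/O.

The mask is a thin refractive surface-relief element described by a height map
h(x, y) in µm; its phase at wavelength lambda is 2*pi*(n-1)*h/lambda.  Heights
are stored nonnegative (piston is optically irrelevant) and bounded by a
configurable maximum chosen to give at least a 4*pi phase range at 520 nm with
n = 1.5.  Fixed baselines (flat, cubic) serve as references for the learned
design: the cubic profile alpha*(x^3 + y^3) over normalized pupil coordinates
is the classical wavefront-coding element whose PSF is nearly depth-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .config import OpticalConfig

__all__ = [
    "PhaseMask", "height_to_phase", "flat_mask", "cubic_mask",
    "init_learnable_mask", "project_fabrication", "save_mask", "load_mask",
    "DEFAULT_MAX_HEIGHT_UM",
]

# >= 4*pi phase range at 520 nm with n = 1.5: h = 2*lambda/(n-1) = 2.08 µm
DEFAULT_MAX_HEIGHT_UM = 2.08

PARAMETERIZATIONS = ("pixelwise", "zernike", "cubic")


@dataclass
class PhaseMask:
    """Surface-height map of the Fourier-plane element."""

    height_map: np.ndarray            # µm, square grid congruent with the pupil
    parameterization: str = "pixelwise"
    coefficients: np.ndarray | None = None
    trainable: bool = False
    max_height_um: float = DEFAULT_MAX_HEIGHT_UM
    lateral_pitch_um: float = 1.0     # mask-plane sample pitch (metadata)

    def __post_init__(self):
        h = np.asarray(self.height_map, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError("height map must be a square 2-D grid")
        if not np.all(np.isfinite(h)):
            raise ValueError("height map contains non-finite values")
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        self.height_map = h

    @property
    def grid_size(self) -> int:
        return self.height_map.shape[0]

    @property
    def n_parameters(self) -> int:
        if self.parameterization == "pixelwise":
            return self.height_map.size
        return 0 if self.coefficients is None else int(np.size(self.coefficients))


def height_to_phase(height_um: np.ndarray, wavelength_nm: float,
                    n_index: float) -> np.ndarray:
    """Thin-element phase phi = 2*pi*(n-1)*h/lambda in radians (no wrapping)."""
    if n_index <= 1:
        raise ValueError("refractive index must exceed 1")
    h = np.asarray(height_um, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("height map contains non-finite values")
    lam_um = wavelength_nm * 1e-3
    return 2.0 * np.pi * (n_index - 1.0) * h / lam_um


def flat_mask(grid_size: int, **kwargs) -> PhaseMask:
    return PhaseMask(np.zeros((grid_size, grid_size)), parameterization="pixelwise",
                     trainable=False, **kwargs)


def cubic_mask(alpha: float, grid_size: int, cfg: OpticalConfig,
               channel: str = "fluor") -> PhaseMask:
    """Cubic wavefront-coding baseline: phase alpha*(x^3 + y^3), x, y in [-1, 1]
    over the aperture, converted to heights at the given channel's wavelength
    and offset so the minimum height is zero."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    from .optics import frequency_grids

    fy, fx = frequency_grids(cfg)
    fc = cfg.cutoff_frequency(cfg.wavelength_nm(channel))
    xt, yt = fx / fc, fy / fc
    phase = alpha * (xt ** 3 + yt ** 3)
    lam_um = cfg.wavelength_nm(channel) * 1e-3
    heights = phase * lam_um / (2.0 * np.pi * (cfg.mask_refractive_index - 1.0))
    # evaluate the offset over the aperture only; outside values are unused
    ap = xt ** 2 + yt ** 2 <= 1.0
    offset = heights[ap].min() if np.any(ap) else heights.min()
    heights = heights - offset
    max_h = max(float(heights[ap].max()) if np.any(ap) else 0.0, DEFAULT_MAX_HEIGHT_UM)
    return PhaseMask(heights, parameterization="cubic",
                     coefficients=np.array([alpha]), trainable=False,
                     max_height_um=max_h)


def init_learnable_mask(parameterization: str, seed: int, init_scale: float,
                        grid_size: int, cfg: OpticalConfig,
                        max_height_um: float = DEFAULT_MAX_HEIGHT_UM) -> PhaseMask:
    """Seeded random initialization of a trainable mask.

    ``init_scale`` is the fraction of ``max_height_um`` used as the range of the
    uniform height initialization; 0 gives a flat mask.
    """
    if parameterization not in PARAMETERIZATIONS:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    rng = np.random.default_rng(seed)
    if parameterization == "pixelwise":
        heights = init_scale * max_height_um * rng.uniform(0.0, 1.0, (grid_size, grid_size))
        coeffs = None
    elif parameterization == "cubic":
        alpha = abs(rng.normal(0.0, 10.0)) * init_scale
        return cubic_mask(alpha, grid_size, cfg)
    else:  # zernike: low-order random aberration seed
        n_coeff = 15
        coeffs = init_scale * rng.normal(0.0, 1.0, n_coeff)
        heights = _zernike_surface(coeffs, grid_size, cfg)
        heights = np.clip(heights - heights.min(), 0.0, max_height_um)
    heights = np.clip(heights, 0.0, max_height_um)
    return PhaseMask(heights, parameterization=parameterization,
                     coefficients=coeffs, trainable=True, max_height_um=max_height_um)


def _zernike_surface(coeffs: np.ndarray, grid_size: int, cfg: OpticalConfig,
                     channel: str = "fluor") -> np.ndarray:
    """Height surface from Noll-ordered Zernike coefficients (µm, j = 1..len)."""
    from .optics import frequency_grids

    fy, fx = frequency_grids(cfg)
    fc = cfg.cutoff_frequency(cfg.wavelength_nm(channel))
    rho = np.sqrt(fx ** 2 + fy ** 2) / fc
    theta = np.arctan2(fy, fx)
    surf = np.zeros_like(rho)
    for j, c in enumerate(coeffs, start=1):
        surf += c * _zernike_noll(j, rho, theta)
    return surf


def _zernike_noll(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    # Noll index -> (n, m)
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    am = abs(m)
    radial = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)))
        radial += c * rho ** (n - 2 * k)
    if m > 0:
        return radial * np.cos(am * theta)
    if m < 0:
        return radial * np.sin(am * theta)
    return radial


def project_fabrication(mask: PhaseMask, height_levels: int,
                        max_height_um: float | None = None) -> PhaseMask:
    """Snap heights to ``height_levels`` uniform levels in [0, max_height].

    Stands in for fabrication constraints of the two-photon printed element;
    idempotent by construction.
    """
    if height_levels < 2:
        raise ValueError("height_levels must be >= 2")
    hmax = mask.max_height_um if max_height_um is None else max_height_um
    step = hmax / (height_levels - 1)
    snapped = np.clip(np.round(mask.height_map / step) * step, 0.0, hmax)
    return PhaseMask(snapped, parameterization=mask.parameterization,
                     coefficients=None if mask.coefficients is None else mask.coefficients.copy(),
                     trainable=mask.trainable, max_height_um=hmax,
                     lateral_pitch_um=mask.lateral_pitch_um)


# ----------------------------------------------------------------------
# archive I/O: float32 TIFF height map + YAML sidecar metadata
# ----------------------------------------------------------------------

def save_mask(mask: PhaseMask, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.height_map.astype(np.float32))
    meta = {
        "parameterization": mask.parameterization,
        "trainable": bool(mask.trainable),
        "max_height_um": float(mask.max_height_um),
        "lateral_pitch_um": float(mask.lateral_pitch_um),
        "coefficients": None if mask.coefficients is None
        else [float(c) for c in np.ravel(mask.coefficients)],
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))


def load_mask(path, expected_grid: int | None = None) -> PhaseMask:
    path = Path(path)
    heights = np.asarray(tifffile.imread(path), dtype=float)
    meta = yaml.safe_load(path.with_suffix(path.suffix + ".yaml").read_text())
    if expected_grid is not None and heights.shape != (expected_grid, expected_grid):
        raise ValueError(
            f"mask grid {heights.shape} incongruent with configured pupil grid "
            f"({expected_grid}, {expected_grid})")
    coeffs = meta.get("coefficients")
    return PhaseMask(
        heights,
        parameterization=meta["parameterization"],
        coefficients=None if coeffs is None else np.asarray(coeffs, dtype=float),
        trainable=bool(meta["trainable"]),
        max_height_um=float(meta["max_height_um"]),
        lateral_pitch_um=float(meta["lateral_pitch_um"]),
    )
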