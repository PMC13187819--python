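"""Optical/sensor configuration for the endomicroscope forward model.

The design is a unit-magnification conjugate pair (identical objective and tube
lens), so every length is expressed at the object plane.  Defaults describe the
reference prototype: NA 0.1 imaging optics, a 5 MP monochrome sensor with
2.0 µm pixels giving a 5.2 mm x 3.9 mm field, fluorescence collected around
520 nm (457 nm excitation) and reflectance at 523 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

CHANNELS = ("fluor", "refl")


@dataclass(frozen=True)
class OpticalConfig:
    """Fixed optical and sensor parameters of the imaging system.

    Simulation sampling: the pupil is an N x N grid (``pupil_grid_size``) of
    spatial frequency, zero-padded by ``pad_factor`` before the Fourier
    transform; the resulting field is sampled at ``pixel_pitch_um /
    oversample`` at the object plane and box-integrated down to the sensor
    pitch to model pixel aggregation.
    """

    numerical_aperture: float = 0.1
    wavelength_fluor_nm: float = 520.0
    wavelength_refl_nm: float = 523.0
    excitation_wavelength_nm: float = 457.0   # metadata only; not propagated
    pixel_pitch_um: float = 2.0
    sensor_width_mm: float = 5.2
    sensor_height_mm: float = 3.9
    mask_refractive_index: float = 1.5
    pupil_grid_size: int = 512
    pad_factor: int = 2
    oversample: int = 5                       # odd: keeps binned PSFs pixel-centered
    max_defocus_um: float = 400.0
    psf_window_px: int = 97                   # odd sensor-pixel count per PSF crop side

    def __post_init__(self):
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("numerical aperture must lie in (0, 1)")
        if min(self.wavelength_fluor_nm, self.wavelength_refl_nm,
               self.excitation_wavelength_nm) <= 0:
            raise ValueError("wavelengths must be positive")
        if self.sensor_width_mm <= 0 or self.sensor_height_mm <= 0:
            raise ValueError("sensor dimensions must be positive")
        if self.mask_refractive_index <= 1:
            raise ValueError("mask refractive index must exceed 1")
        if self.pupil_grid_size < 16 or self.pad_factor < 1 or self.oversample < 1:
            raise ValueError("invalid simulation sampling parameters")
        # The internal spatial sampling must resolve the incoherent cutoff 2 NA/lambda.
        fc = self.cutoff_frequency(min(self.wavelength_fluor_nm, self.wavelength_refl_nm))
        if 1.0 / (2.0 * self.internal_pitch_um) < 2.0 * fc:
            raise ValueError(
                "internal sampling violates the Nyquist constraint for the "
                "incoherent cutoff; increase oversample or reduce pixel pitch")
        # The aperture disk must fit inside the pupil grid.
        if self.aperture_radius_samples(min(self.wavelength_fluor_nm,
                                            self.wavelength_refl_nm)) > self.pupil_grid_size / 2:
            raise ValueError("aperture does not fit the pupil grid; increase pupil_grid_size")

    # -- derived quantities -------------------------------------------
    def wavelength_nm(self, channel: str) -> float:
        if channel == "fluor":
            return self.wavelength_fluor_nm
        if channel == "refl":
            return self.wavelength_refl_nm
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")

    def cutoff_frequency(self, wavelength_nm: float) -> float:
        """Coherent pupil radius NA/lambda in cycles/µm."""
        return self.numerical_aperture / (wavelength_nm * 1e-3)

    @property
    def internal_pitch_um(self) -> float:
        return self.pixel_pitch_um / self.oversample

    @property
    def padded_grid_size(self) -> int:
        return self.pad_factor * self.pupil_grid_size

    @property
    def frequency_pitch(self) -> float:
        """Spatial-frequency sample spacing (cycles/µm) on the pupil grid."""
        return 1.0 / (self.padded_grid_size * self.internal_pitch_um)

    def aperture_radius_samples(self, wavelength_nm: float) -> float:
        return self.cutoff_frequency(wavelength_nm) / self.frequency_pitch

    @property
    def sensor_shape(self) -> tuple[int, int]:
        """(rows, cols) of the sensor in pixels."""
        return (int(round(self.sensor_height_mm * 1e3 / self.pixel_pitch_um)),
                int(round(self.sensor_width_mm * 1e3 / self.pixel_pitch_um)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**d)


@dataclass(frozen=True)
class SensorConfig:
    """Sensor noise/digitization model: Poisson shot noise on photoelectrons,
    additive Gaussian read noise, black-level pedestal, full-well clip and
    uniform quantization."""

    read_noise_e: float = 4.0
    full_well_e: float = 10_000.0
    adc_bits: int = 10
    black_level_e: float = 0.0
    quantum_efficiency: float = 1.0

    def __post_init__(self):
        if self.read_noise_e < 0 or self.full_well_e <= 0:
            raise ValueError("invalid sensor noise parameters")
        if not 2 <= self.adc_bits <= 16:
            raise ValueError("adc_bits out of range")
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum efficiency must lie in (0, 1]")

    @property
    def adc_levels(self) -> int:
        return 2 ** self.adc_bits - 1

    @property
    def gain_dn_per_e(self) -> float:
        return self.adc_levels / self.full_well_e

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SensorConfig":
        return cls(**d)
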