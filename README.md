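# edofscope

Design and evaluation stack for **extended depth-of-field computational
endomicroscopy**: a Fourier-optics forward model with a phase mask in the
pupil plane, a space-variant image-formation engine over a 5.2 × 3.9 mm /
5 MP field of view, a sensor noise model, pinhole-grid PSF calibration, a
NumPy-only restoration network with an end-to-end (mask + network) training
loop, and resolution metrology (bead FWHM, USAF-1951 scoring, depth-of-field
estimation).

## The idea

A fiber-free endomicroscope that images a wide field at cellular resolution
has a very shallow depth of field: at NA 0.1 and 520 nm the in-focus spot is
~2.7 µm wide, but a few hundred micrometers of defocus — unavoidable against
uneven tissue — blurs it by an order of magnitude.  Placing a refractive
phase mask in the pupil (Fourier) plane trades some in-focus sharpness for a
point spread function that barely changes with depth; a restoration step
(Wiener filter or a learned network) then recovers near-diffraction-limited
resolution across the whole depth range.  This package simulates that entire
design loop: the mask can be a classical cubic profile or learned jointly
with the restoration network through a differentiable optical model, and the
resulting system can be calibrated and characterized exactly as a bench
instrument would be.

## Worked example

Bead FWHM through the conventional (flat) and wavefront-coded (cubic)
system, at the sensor pitch, measured by the package's own metrology:

```python
import numpy as np
from scipy.signal import fftconvolve
from edofscope import (OpticalConfig, flat_mask, cubic_mask, pupil_function,
                       simulate_psf, disk_kernel)
from edofscope.metrology import measure_bead

cfg = OpticalConfig()  # NA 0.1, 520 nm fluorescence, 2 um pixels
bead = disk_kernel(3.0, cfg.pixel_pitch_um, normalize=True)
for name, mask in [("flat", flat_mask(cfg.pupil_grid_size)),
                   ("cubic", cubic_mask(25.0, cfg.pupil_grid_size, cfg))]:
    widths = []
    for z_um in (0.0, 125.0, 250.0):
        psf = simulate_psf(pupil_function(cfg, mask, z_um, "fluor"),
                           cfg.pixel_pitch_um, 161)
        image = fftconvolve(psf, bead, mode="same") * 1e6
        widths.append(measure_bead(image, (80.0, 80.0), cfg.pixel_pitch_um)[2])
    print(f"{name:5s} mask bead FWHM at 0 / 125 / 250 um defocus: "
          + " / ".join(f"{w:5.2f}" for w in widths) + "  um")
```

Output:

```
flat  mask bead FWHM at 0 / 125 / 250 um defocus:  3.43 / 20.64 / 36.94  um
cubic mask bead FWHM at 0 / 125 / 250 um defocus:  5.75 / 11.36 / 11.81  um
```

The flat-mask spot degrades ~11× at 250 µm defocus; the coded spot stays
an order of magnitude tighter, and after deconvolution with its in-focus
kernel it measures 3.6–4.1 µm across the full ±250 µm span (see
`results/acceptance.json`, section `depth_of_field`).

## Command-line pipeline

The same loop is available as a CLI (`edofscope`, or
`python -m edofscope.cli`):

```bash
edofscope phantom --kind pinhole_grid --out acq/      # calibration stacks
edofscope calibrate --stacks acq/pinhole_stacks.npz --out cal/
edofscope characterize --bank cal/bank.h5 --out report/

edofscope train --steps 200 --seed 0 --out run/       # joint mask+net design
edofscope reconstruct --input captures.tiff --checkpoint run/checkpoint.npz \
    --out restored/
```

Every run writes a `run_log.json` (command, parameters, warnings, wall
clock) and a `config_snapshot.yaml` next to its outputs.  The YAML config
schema is validated with named errors for unknown sections/keys.

## Reproduction

The unit suite (245 tests, ~20 s) checks every module against independent
oracles — closed-form Gaussian/Airy widths, brute-force space-variant
superposition, finite-difference gradients, exact flux accounting:

```bash
python -m pytest
```

The acceptance suite (one test per release criterion, ~4 min) and the
acceptance script reproduce the headline numbers from scratch:

```bash
python -m pytest tests/test_acceptance.py
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Selected values from `results/acceptance.json` (seed 1):

| quantity | value |
|---|---|
| in-focus FWHM vs 0.5145 λ/NA | 2.6761 µm vs 2.6754 µm (0.03 % off) |
| PSF energy error | 0.0 |
| MTF depth variation, flat → cubic | 0.109 → 0.0051 |
| forward model vs direct summation | 6.0e-16 relative RMS |
| calibration round-trip (80 × 11 × 10) | 4.0 % mean RMS |
| dark-frame noise vs 4.0 e⁻ model | 4.008 e⁻ |
| Wiener recovery of circular blur | 9.2e-7 relative RMS |
| 200-step training, held-out PSNR gain | +1.0 dB over raw captures |
| restored cubic FWHM, worst over ±250 µm | 4.07 µm |

All stochastic paths are seeded; re-running with the same seed reproduces
the JSON bit-for-bit.

## Layout

- `src/edofscope/` — `optics`, `phase_mask`, `imaging`, `calibration`,
  `reconstruction`, `autodiff`, `e2e_train`, `metrology`, `phantoms`,
  `cli`, `io`
- `tests/` — unit suites per module plus `test_acceptance.py`
- `scripts/acceptance.py` — headline-quantity run
- `docs/methods.md` — model, numerical choices, generator realism,
  limitations
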