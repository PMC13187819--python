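"""Joint end-to-end optimization of the phase mask and restoration network.

Design stage: a differentiable chain maps the mask height map to a pupil, the
pupil to a depth-dependent PSF, the PSF to a simulated sensor capture of a
ground-truth scene, and the capture through the restoration network; one
first-order adaptive (Adam) step updates mask heights and network weights
simultaneously against a pixelwise-L1 + multi-scale structural-similarity
loss.  Depths are drawn uniformly from a discrete grid (21 planes over the
500 µm target depth range by default) and both imaging modalities are mixed in
every batch.  Per the two-stage procedure of the reference design, the design
loop uses the on-axis PSF only; spatial PSF variation is handled afterwards by
fine-tuning the network on a calibrated bank.

Shot/read noise is injected through a straight-through estimator: the capture
keeps the analytic gradient of the noiseless forward model while carrying the
sampled noisy values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from . import autodiff as ad
from .autodiff import Tensor
from .config import OpticalConfig, SensorConfig, CHANNELS
from .optics import (DefocusGrid, build_defocus_grid, aperture_mask,
                     defocus_phase, pupil_function, simulate_psf)
from .phase_mask import PhaseMask
from .imaging import Scene, CaptureFrame, PSFBank, add_sensor_noise, dn_to_electrons
from .reconstruction import ModelSpec, ReconstructionModel, normalize_frame, psnr

__all__ = [
    "TrainingConfig", "training_optics", "DifferentiablePSF", "Adam",
    "l1_loss", "ms_ssim", "simulate_training_pair", "EndToEndTrainer",
    "e2e_step", "finetune_on_calibrated_psfs",
]


def training_optics(pupil_grid_size: int = 64, oversample: int = 3,
                    psf_window_px: int = 33, **kwargs) -> OpticalConfig:
    """Reduced-sampling optical configuration for the design loop.

    Same physics as the metrology-grade configuration, smaller grids: the
    design loop only needs the PSF's coarse structure, and the small FFTs keep
    a CPU training step cheap.
    """
    return OpticalConfig(pupil_grid_size=pupil_grid_size, oversample=oversample,
                         psf_window_px=psf_window_px, **kwargs)


@dataclass
class TrainingConfig:
    """Hyperparameters of the end-to-end design stage."""

    depth_span_um: float = 500.0
    n_depths: int = 21
    batch_size: int = 4
    steps: int = 200
    lr_mask: float = 0.02          # µm-scale height updates
    lr_net: float = 2e-3
    loss_l1_weight: float = 1.0
    loss_ssim_weight: float = 0.1
    ssim_scales: int = 3
    modality_mix: float = 0.5      # fraction of fluorescence frames per batch
    seed: int = 0
    train_mask: bool = True
    photon_scale_e: float = 3000.0  # photoelectrons at unit normalized radiance
    tv_weight: float = 1e-4         # smoothness penalty on the height map
    image_size: int = 64

    def __post_init__(self):
        if self.lr_mask <= 0 or self.lr_net <= 0:
            raise ValueError("learning rates must be positive")
        if self.loss_l1_weight < 0 or self.loss_ssim_weight < 0 or \
                (self.loss_l1_weight == 0 and self.loss_ssim_weight == 0):
            raise ValueError("loss weights must be nonnegative and not all zero")
        if not 0 <= self.modality_mix <= 1:
            raise ValueError("modality mix must lie in [0, 1]")

    @property
    def depth_grid(self) -> DefocusGrid:
        return build_defocus_grid(self.depth_span_um, self.n_depths)


# ----------------------------------------------------------------------
# differentiable optical layer
# ----------------------------------------------------------------------

class DifferentiablePSF:
    """Mask heights -> normalized sensor-pitch PSF, differentiable end to end."""

    def __init__(self, cfg: OpticalConfig, max_height_um: float):
        self.cfg = cfg
        self.max_height_um = max_height_um
        self._aperture = {ch: aperture_mask(cfg, ch) for ch in CHANNELS}
        self._phase_scale = {
            ch: 2.0 * np.pi * (cfg.mask_refractive_index - 1.0)
            / (cfg.wavelength_nm(ch) * 1e-3)
            for ch in CHANNELS
        }

    def psf(self, heights: Tensor, z_um: float, channel: str) -> Tensor:
        cfg = self.cfg
        n = cfg.pupil_grid_size
        m = cfg.padded_grid_size
        os_ = cfg.oversample
        w_px = cfg.psf_window_px
        h = ad.clip(heights, 0.0, self.max_height_um)
        phase = h * self._phase_scale[channel] + defocus_phase(cfg, z_um, channel)
        ap = self._aperture[channel]
        re = ad.cos(phase) * ap
        im = ad.sin(phase) * ap
        pupil = ad.make_complex(re, im)
        padded = ad.pad2d(pupil, (m - n) // 2)
        field = ad.cifft2(padded)
        intensity = ad.abs2(field)
        w_int = w_px * os_
        lo = m // 2 - w_int // 2
        crop = ad.crop2d(intensity, lo, lo, w_int, w_int)
        if os_ > 1:
            pooled = ad.avg_pool2d(ad.reshape(crop, (1, 1, w_int, w_int)), os_)
            psf = ad.reshape(pooled * float(os_ * os_), (w_px, w_px))
        else:
            psf = crop
        return psf / ad.tsum(psf)


# ----------------------------------------------------------------------
# optimizer
# ----------------------------------------------------------------------

class Adam:
    """First-order adaptive optimizer with per-parameter learning rates."""

    def __init__(self, params, lrs, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lrs = [lrs] * len(self.params) if np.isscalar(lrs) else list(lrs)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, lr, m, v in zip(self.params, self.lrs, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

def l1_loss(a: Tensor, b: Tensor) -> Tensor:
    return ad.tmean(ad.absolute(a - b))


def _gaussian_kernel(size=7, sigma=1.5):
    x = np.arange(size) - size // 2
    k = np.exp(-x ** 2 / (2 * sigma ** 2))
    k = np.outer(k, k)
    return (k / k.sum())[None, None]


_SSIM_KERNEL = _gaussian_kernel()
# canonical multi-scale weights truncated to three scales and renormalized
_MSSSIM_WEIGHTS = {1: [1.0],
                   2: [0.1356, 0.8644],
                   3: [0.0710, 0.4530, 0.4760],
                   4: [0.0517, 0.3295, 0.3462, 0.2726],
                   5: [0.0448, 0.2856, 0.3001, 0.2363, 0.1333]}


def _ssim_terms(a: Tensor, b: Tensor, c1=0.01 ** 2, c2=0.03 ** 2):
    w = Tensor(_SSIM_KERNEL)
    mu_a = ad.conv2d(a, w, padding=0)
    mu_b = ad.conv2d(b, w, padding=0)
    mu_aa = ad.conv2d(a * a, w, padding=0)
    mu_bb = ad.conv2d(b * b, w, padding=0)
    mu_ab = ad.conv2d(a * b, w, padding=0)
    va = mu_aa - mu_a * mu_a
    vb = mu_bb - mu_b * mu_b
    cov = mu_ab - mu_a * mu_b
    lum = (2.0 * mu_a * mu_b + c1) / (mu_a * mu_a + mu_b * mu_b + c1)
    cs = (2.0 * cov + c2) / (va + vb + c2)
    return ad.tmean(lum), ad.tmean(cs)


def ms_ssim(a: Tensor, b: Tensor, scales: int = 3) -> Tensor:
    """Multi-scale structural similarity on NCHW tensors in [0, 1]."""
    weights = _MSSSIM_WEIGHTS[scales]
    value = None
    for s in range(scales):
        lum, cs = _ssim_terms(a, b)
        term = lum * cs if s == scales - 1 else cs
        term = ad.clip(term, 1e-4, 1.0)
        powed = term ** weights[s]
        value = powed if value is None else value * powed
        if s < scales - 1:
            a = ad.avg_pool2d(a, 2)
            b = ad.avg_pool2d(b, 2)
    return value


# ----------------------------------------------------------------------
# training pairs
# ----------------------------------------------------------------------

def simulate_training_pair(gt: Scene, z_um: float, mask: PhaseMask,
                           cfg: OpticalConfig, seed: int,
                           sensor: SensorConfig | None = None,
                           photon_scale_e: float = 3000.0):
    """(noisy capture, all-in-focus target) for one scene at one depth.

    The capture is the scene's radiance convolved with the on-axis PSF of the
    current mask at depth z, passed through the sensor noise model; the target
    is the scene radiance itself (normalized units).
    """
    sensor = sensor or SensorConfig(adc_bits=12)
    psf = simulate_psf(pupil_function(cfg, mask, z_um, gt.channel),
                       cfg.pixel_pitch_um, cfg.psf_window_px)
    clean_e = fftconvolve(gt.radiance * photon_scale_e, psf, mode="same")
    clean_e = np.clip(clean_e, 0.0, None)
    frame = add_sensor_noise(clean_e, sensor=sensor, seed=seed, channel=gt.channel,
                             metadata={"depth_um": float(z_um)})
    return frame, gt.radiance.copy()


# ----------------------------------------------------------------------
# end-to-end trainer
# ----------------------------------------------------------------------

class EndToEndTrainer:
    """Holds the learnable mask, the network, and the joint Adam state."""

    def __init__(self, mask: PhaseMask, model: ReconstructionModel,
                 cfg: TrainingConfig, optics: OpticalConfig | None = None,
                 sensor: SensorConfig | None = None):
        self.cfg = cfg
        self.mask = mask
        self.model = model
        self.optics = optics or training_optics()
        if mask.height_map.shape[0] != self.optics.pupil_grid_size:
            raise ValueError("mask grid incongruent with the training pupil grid")
        self.sensor = sensor or SensorConfig(adc_bits=12)
        self.diff_psf = DifferentiablePSF(self.optics, mask.max_height_um)
        self.heights = Tensor(mask.height_map.copy(), requires_grad=mask.trainable
                              and cfg.train_mask)
        net_params = model.parameters()
        params = list(net_params)
        lrs = [cfg.lr_net] * len(net_params)
        if self.heights.requires_grad:
            params.append(self.heights)
            lrs.append(cfg.lr_mask)
        self.opt = Adam(params, lrs)
        self.loss_log: list[float] = []
        self._rng = np.random.default_rng(cfg.seed)

    # -- batch construction -------------------------------------------
    def sample_batch(self, corpus, rng=None):
        """Draw (scene, depth, noise_seed) triples; modalities balanced to the
        configured mix ratio within every batch, depths uniform over the grid."""
        rng = rng or self._rng
        depths = self.cfg.depth_grid.depths
        n = self.cfg.batch_size
        n_fluor = int(round(self.cfg.modality_mix * n))
        channels = ["fluor"] * n_fluor + ["refl"] * (n - n_fluor)
        rng.shuffle(channels)
        batch = []
        for ch in channels:
            pool = [s for s in corpus if s.channel == ch] or corpus
            scene = pool[rng.integers(len(pool))]
            z = float(depths[rng.integers(len(depths))])
            batch.append((scene, z, int(rng.integers(2 ** 31))))
        return batch

    # -- one optimization step ------------------------------------------
    def step(self, batch) -> float:
        if not batch:
            raise ValueError("empty batch")
        cfg = self.cfg
        mask_before = self.heights.data.copy()
        total = None
        for scene, z, noise_seed in batch:
            psf_t = self.diff_psf.psf(self.heights, z, scene.channel)
            x = Tensor(scene.radiance[None, None])
            capture = ad.conv2d(x, ad.reshape(ad.flip2d(psf_t),
                                              (1, 1) + psf_t.shape),
                                padding=psf_t.shape[0] // 2)
            # straight-through sensor noise: sampled values, analytic gradient
            clean_e = np.clip(capture.data[0, 0] * cfg.photon_scale_e, 0.0, None)
            frame = add_sensor_noise(clean_e, sensor=self.sensor, seed=noise_seed,
                                     channel=scene.channel)
            noisy = dn_to_electrons(frame, self.sensor) / cfg.photon_scale_e
            capture = capture + Tensor((noisy - capture.data[0, 0])[None, None])
            target = Tensor(scene.radiance[None, None])
            restored = self.model.forward(capture)
            loss = cfg.loss_l1_weight * l1_loss(restored, target)
            if cfg.loss_ssim_weight > 0:
                loss = loss + cfg.loss_ssim_weight * \
                    (1.0 - ms_ssim(ad.clip(restored, 0.0, 1.0),
                                   target, cfg.ssim_scales))
            total = loss if total is None else total + loss
        total = total / len(batch)
        if self.heights.requires_grad and cfg.tv_weight > 0:
            h = self.heights
            tv = ad.tmean(ad.absolute(h[1:, :] - h[:-1, :])) + \
                ad.tmean(ad.absolute(h[:, 1:] - h[:, :-1]))
            total = total + cfg.tv_weight * tv
        value = float(total.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"training diverged: loss={value}, "
                f"|heights|max={np.abs(self.heights.data).max():.3g}")
        self.opt.zero_grad()
        total.backward()
        self.opt.step()
        # project heights back to the fabrication bounds
        if self.heights.requires_grad:
            self.heights.data = np.clip(self.heights.data, 0.0,
                                        self.mask.max_height_um)
            self.mask.height_map = self.heights.data.copy()
        else:
            assert np.array_equal(self.heights.data, mask_before)
        self.loss_log.append(value)
        return value

    def train(self, corpus, steps: int | None = None) -> list[float]:
        for _ in range(steps if steps is not None else self.cfg.steps):
            self.step(self.sample_batch(corpus))
        return self.loss_log


def e2e_step(mask: PhaseMask, model: ReconstructionModel, batch,
             cfg: TrainingConfig, trainer: EndToEndTrainer | None = None):
    """One joint gradient step; returns (mask, model, loss).

    Stateless convenience wrapper around :class:`EndToEndTrainer` (the trainer
    keeps optimizer moments between calls; pass it for multi-step use).
    """
    tr = trainer or EndToEndTrainer(mask, model, cfg)
    loss = tr.step(batch)
    return tr.mask, tr.model, loss


# ----------------------------------------------------------------------
# calibrated fine-tuning (network only, mask frozen)
# ----------------------------------------------------------------------

def finetune_on_calibrated_psfs(model: ReconstructionModel, bank: PSFBank,
                                gt_corpus, cfg: TrainingConfig,
                                sensor: SensorConfig | None = None):
    """Network-only training on pairs synthesized from measured PSFs.

    Each pair blurs a ground-truth scene with a PSF drawn from the calibrated
    bank (uniform over field positions and depth planes), mirroring how the
    hardware-measured responses are replayed through the forward model after
    assembly.  The mask is hardware at this point and is not touched.
    """
    if not gt_corpus:
        raise ValueError("empty ground-truth corpus")
    if bank.psfs.shape[0] * bank.psfs.shape[1] == 1:
        warnings.warn("fine-tuning with a single calibrated field position: "
                      "spatial PSF variation cannot be learned")
    sensor = sensor or SensorConfig(adc_bits=12)
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = Adam(params, cfg.lr_net)
    ny, nx, nz = bank.psfs.shape[:3]
    for _ in range(cfg.steps):
        total = None
        for _ in range(cfg.batch_size):
            scene = gt_corpus[rng.integers(len(gt_corpus))]
            iy, ix, iz = rng.integers(ny), rng.integers(nx), rng.integers(nz)
            ic = bank.channel_index(scene.channel) if scene.channel in bank.channels else 0
            psf = bank.psfs[iy, ix, iz, ic]
            clean_e = np.clip(fftconvolve(scene.radiance * cfg.photon_scale_e,
                                          psf, mode="same"), 0.0, None)
            frame = add_sensor_noise(clean_e, sensor=sensor,
                                     seed=int(rng.integers(2 ** 31)),
                                     channel=scene.channel)
            noisy = dn_to_electrons(frame, sensor) / cfg.photon_scale_e
            x = Tensor(noisy[None, None])
            target = Tensor(scene.radiance[None, None])
            restored = model.forward(x)
            loss = cfg.loss_l1_weight * l1_loss(restored, target)
            if cfg.loss_ssim_weight > 0:
                loss = loss + cfg.loss_ssim_weight * \
                    (1.0 - ms_ssim(ad.clip(restored, 0.0, 1.0), target,
                                   cfg.ssim_scales))
            total = loss if total is None else total + loss
        total = total / cfg.batch_size
        if not np.isfinite(float(total.data)):
            raise FloatingPointError("fine-tuning diverged")
        opt.zero_grad()
        total.backward()
        opt.step()
    return model
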