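"""Restoration: encoder-decoder network and a classical Wiener baseline.

The restoration network is a modified U-Net with residual blocks at every
scale, a pyramid pooling module (PPM) at the bottleneck for multi-scale global
context, and pixel-shuffle (channel-to-space) upsampling in the decoder.  It
maps a single-channel encoded capture to an all-in-focus estimate; a global
input skip keeps the untrained network close to the identity.  The default
spec (4 scales, widths 32/64/128/256, 2 residual blocks per scale, PPM bins
1/2/3/6, shuffle factor 2) is config-driven, so alternative hyperparameters
drop in without code changes.

The Wiener filter H*/(|H|^2 + NSR) provides a linear, assumption-light
deconvolution baseline and an independent oracle for testing the learned
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .imaging import CaptureFrame

__all__ = [
    "ModelSpec", "ReconstructionModel", "build_precisionnet", "build_restoration_net",
    "reconstruct_frame", "normalize_frame", "wiener_deconvolve",
    "psnr", "rms_error", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the restoration network."""

    n_scales: int = 4
    widths: tuple = (32, 64, 128, 256)
    res_blocks: int = 2
    ppm_bins: tuple = (1, 2, 3, 6)
    shuffle_r: int = 2
    in_channels: int = 1
    input_shape: tuple = (368, 480)
    pad_to_fit: bool = False
    leak: float = 0.1

    def __post_init__(self):
        if len(self.widths) != self.n_scales:
            raise ValueError("widths must list one channel count per scale")
        f = self.downsample_factor
        h, w = self.input_shape
        if not self.pad_to_fit and (h % f or w % f):
            raise ValueError(
                f"input shape {self.input_shape} not divisible by the total "
                f"downsampling factor {f}; enable pad_to_fit or change the spec")

    @property
    def downsample_factor(self) -> int:
        return 2 ** (self.n_scales - 1)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["widths"] = tuple(d["widths"])
        d["ppm_bins"] = tuple(d["ppm_bins"])
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


class _Conv:
    """3x3 (or kxk) convolution layer with He-initialized weights."""

    def __init__(self, rng, cin, cout, k=3, zero_init=False):
        std = 0.0 if zero_init else np.sqrt(2.0 / (cin * k * k))
        w = rng.normal(0.0, std, (cout, cin, k, k)) if std > 0 else np.zeros((cout, cin, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.pad = k // 2

    def __call__(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=1, padding=self.pad)

    def params(self):
        return [self.weight, self.bias]


class _StridedConv(_Conv):
    def __call__(self, x):
        return ad.conv2d(x, self.weight, self.bias, stride=2, padding=self.pad)


class _ResBlock:
    def __init__(self, rng, c, leak):
        self.c1 = _Conv(rng, c, c)
        self.c2 = _Conv(rng, c, c)
        self.leak = leak

    def __call__(self, x):
        y = ad.leaky_relu(self.c1(x), self.leak)
        return x + self.c2(y)

    def params(self):
        return self.c1.params() + self.c2.params()


class _PPM:
    """Pyramid pooling: per-bin global pooling, 1x1 projection, upsample, fuse."""

    def __init__(self, rng, c, bins, leak):
        self.bins = bins
        self.proj = [_Conv(rng, c, max(c // len(bins), 1), k=1) for _ in bins]
        self.fuse = _Conv(rng, c + len(bins) * max(c // len(bins), 1), c)
        self.leak = leak

    def __call__(self, x):
        h, w = x.shape[-2:]
        feats = [x]
        for b, proj in zip(self.bins, self.proj):
            pooled = ad.adaptive_avg_pool2d(x, b)
            feats.append(ad.region_upsample(ad.leaky_relu(proj(pooled), self.leak), (h, w)))
        return ad.leaky_relu(self.fuse(ad.concat(feats, axis=1)), self.leak)

    def params(self):
        out = self.fuse.params()
        for p in self.proj:
            out += p.params()
        return out


class ReconstructionModel:
    """Encoder-decoder restoration network over the numpy autodiff engine."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w = spec.widths
        lk = spec.leak
        self.head = _Conv(rng, spec.in_channels, w[0])
        self.enc_blocks = [[_ResBlock(rng, w[s], lk) for _ in range(spec.res_blocks)]
                           for s in range(spec.n_scales)]
        self.down = [_StridedConv(rng, w[s], w[s + 1]) for s in range(spec.n_scales - 1)]
        self.ppm = _PPM(rng, w[-1], spec.ppm_bins, lk)
        r = spec.shuffle_r
        self.up = [_Conv(rng, w[s + 1], w[s] * r * r) for s in range(spec.n_scales - 1)]
        self.merge = [_Conv(rng, 2 * w[s], w[s]) for s in range(spec.n_scales - 1)]
        self.dec_blocks = [[_ResBlock(rng, w[s], lk) for _ in range(spec.res_blocks)]
                           for s in range(spec.n_scales - 1)]
        # zero-init tail: with the global input skip the untrained network is
        # exactly the identity, which stabilizes early joint training
        self.tail = _Conv(rng, w[0], spec.in_channels, zero_init=True)

    # ------------------------------------------------------------------
    def parameters(self):
        out = self.head.params() + self.tail.params() + self.ppm.params()
        for group in self.enc_blocks:
            for b in group:
                out += b.params()
        for layer in self.down + self.up + self.merge:
            out += layer.params()
        for group in self.dec_blocks:
            for b in group:
                out += b.params()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, x: Tensor) -> Tensor:
        """NCHW in, NCHW out (same shape); adds a global input skip."""
        spec = self.spec
        h, w = x.shape[-2:]
        f = spec.downsample_factor
        pad_h = _sym_pad(h, f)
        pad_w = _sym_pad(w, f)
        padded = pad_h > 0 or pad_w > 0
        if padded and not spec.pad_to_fit:
            raise ValueError(
                f"input {h}x{w} not divisible by the downsampling factor {f}; "
                "enable pad_to_fit or resize the input")
        lk = spec.leak
        x_work = ad.pad2d(x, (pad_h, pad_w)) if padded else x
        y = ad.leaky_relu(self.head(x_work), lk)
        skips = []
        for s in range(spec.n_scales):
            for blk in self.enc_blocks[s]:
                y = blk(y)
            if s < spec.n_scales - 1:
                skips.append(y)
                y = ad.leaky_relu(self.down[s](y), lk)
        y = self.ppm(y)
        for s in reversed(range(spec.n_scales - 1)):
            y = ad.pixel_shuffle(self.up[s](y), spec.shuffle_r)
            y = ad.leaky_relu(self.merge[s](ad.concat([y, skips[s]], axis=1)), lk)
            for blk in self.dec_blocks[s]:
                y = blk(y)
        y = self.tail(y)
        if padded:
            y = ad.crop2d(y, pad_h, pad_w, h, w)
        return x + y

    def __call__(self, x):
        return self.forward(x)

    # -- weight store ---------------------------------------------------
    def get_weights(self):
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights):
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = np.asarray(w, dtype=float)


def _sym_pad(n: int, f: int) -> int:
    """Smallest symmetric (both-sides) zero pad making n + 2p divisible by f."""
    for p in range(f):
        if (n + 2 * p) % f == 0:
            return p
    raise ValueError(f"no symmetric padding makes {n} divisible by {f}")


def build_restoration_net(spec: ModelSpec | None = None, seed: int = 0) -> ReconstructionModel:
    """Build the restoration network; deterministic for a fixed (spec, seed)."""
    return ReconstructionModel(spec or ModelSpec(), seed=seed)


# alias kept close to the spec's operation name
build_precisionnet = build_restoration_net


# ----------------------------------------------------------------------
# inference
# ----------------------------------------------------------------------

def normalize_frame(image: np.ndarray, lo_pct: float = 0.1, hi_pct: float = 99.9):
    """Percentile scaling to [0, 1]; returns (scaled, (lo, hi)) for inversion."""
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, [lo_pct, hi_pct])
    if hi <= lo:
        hi = lo + 1.0
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0), (float(lo), float(hi))


def reconstruct_frame(model: ReconstructionModel, capture) -> np.ndarray:
    """Restore one capture; a pure function of (weights, input), clipped to [0, 1]."""
    img = capture.image if isinstance(capture, CaptureFrame) else np.asarray(capture)
    if img.ndim != 2:
        raise ValueError("capture must be a single 2-D frame")
    scaled, _ = normalize_frame(img)
    x = Tensor(scaled[None, None])
    y = model.forward(x).data[0, 0]
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite values in the restored frame")
    return np.clip(y, 0.0, 1.0)


# ----------------------------------------------------------------------
# Wiener baseline
# ----------------------------------------------------------------------

def wiener_deconvolve(capture, psf: np.ndarray, noise_to_signal: float) -> np.ndarray:
    """Frequency-domain Wiener filter H*/(|H|^2 + NSR); real-valued output."""
    if noise_to_signal < 0:
        raise ValueError("noise-to-signal ratio must be nonnegative")
    img = capture.image if isinstance(capture, CaptureFrame) else np.asarray(capture)
    img = np.asarray(img, dtype=float)
    psf = np.asarray(psf, dtype=float)
    kernel = np.zeros_like(img)
    ph, pw = psf.shape
    kernel[:ph, :pw] = psf / psf.sum()
    # center the kernel at the origin so the filter is shift-free
    kernel = np.roll(kernel, (-(ph // 2), -(pw // 2)), axis=(0, 1))
    H = np.fft.fft2(kernel)
    X = np.fft.fft2(img)
    out = np.fft.ifft2(np.conj(H) * X / (np.abs(H) ** 2 + noise_to_signal)).real
    return out


# ----------------------------------------------------------------------
# metrics and checkpoints
# ----------------------------------------------------------------------

def rms_error(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


def psnr(estimate: np.ndarray, reference: np.ndarray, data_range: float = 1.0) -> float:
    err = rms_error(estimate, reference)
    if err == 0:
        return float("inf")
    return float(20.0 * np.log10(data_range / err))


def save_checkpoint(model: ReconstructionModel, path) -> None:
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez_compressed(path, spec=json.dumps(model.spec.to_dict()), **arrays)


def load_checkpoint(path) -> ReconstructionModel:
    with np.load(path, allow_pickle=False) as data:
        spec = ModelSpec.from_dict(json.loads(str(data["spec"])))
        model = ReconstructionModel(spec, seed=0)
        weights = [data[f"w{i}"] for i in range(len(model.parameters()))]
    model.set_weights(weights)
    return model
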