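"""Shared file formats: multi-page TIFF stacks with per-page metadata.

Frames travel as 32-bit float TIFF (lossless for DN data) with a JSON
metadata blob in each page description (channel, exposure, seed, and the
frame's free-form metadata).  A 16-bit unsigned export mode is available for
viewer compatibility.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import tifffile

from .imaging import CaptureFrame

__all__ = ["write_stack", "read_stack", "write_scene_tiff"]


def _frame_meta(frame: CaptureFrame) -> str:
    return json.dumps({
        "channel": frame.channel,
        "exposure_ms": frame.exposure_ms,
        "seed": frame.seed,
        "metadata": frame.metadata,
    }, default=float)


def write_stack(path, frames, dtype: str = "float32") -> None:
    """Write CaptureFrames as a multi-page TIFF with JSON page metadata.

    ``dtype`` is ``"float32"`` (lossless default) or ``"uint16"`` (export for
    external viewers; values are rounded).  An empty sequence produces a valid
    zero-page TIFF container.
    """
    if dtype not in ("float32", "uint16"):
        raise ValueError("dtype must be 'float32' or 'uint16'")
    frames = list(frames)
    with tifffile.TiffWriter(str(path)) as tif:
        for f in frames:
            img = np.asarray(f.image)
            if dtype == "uint16":
                img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
            else:
                img = img.astype(np.float32)
            tif.write(img, description=_frame_meta(f), contiguous=False)


def read_stack(path) -> list[CaptureFrame]:
    """Read a multi-page TIFF back into CaptureFrames.

    Pages without the expected metadata tag are returned with default
    metadata and a warning; pixel data round-trips bit-identically for
    float32 stacks.
    """
    frames = []
    with tifffile.TiffFile(str(path)) as tif:
        for i, page in enumerate(tif.pages):
            img = page.asarray()
            desc = page.tags.get("ImageDescription")
            meta = None
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (json.JSONDecodeError, TypeError):
                    meta = None
            if not isinstance(meta, dict) or "channel" not in meta:
                warnings.warn(f"page {i} of {path} has no frame metadata; "
                              "using defaults")
                meta = {}
            frames.append(CaptureFrame(
                image=img,
                channel=meta.get("channel", "fluor"),
                exposure_ms=float(meta.get("exposure_ms", 65.0)),
                seed=meta.get("seed"),
                metadata=dict(meta.get("metadata", {}))))
    return frames


def write_scene_tiff(path, array: np.ndarray, metadata: dict | None = None) -> None:
    """Write a single float32 image with an optional JSON description."""
    desc = json.dumps(metadata, default=float) if metadata else None
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32),
                     description=desc)
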