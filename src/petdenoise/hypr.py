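"""HYPR composite-ratio spatiotemporal filtering and the chained ANN+HYPR pipeline.

Each frame is replaced by a high-SNR duration-weighted composite of the whole
series, modulated by a weighting image — the ratio of the box-filtered frame to
the box-filtered composite — so temporal contrast is preserved while voxel-level
noise is drawn from the composite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DynamicImage
from .ann import AnnModel, denoise_series

__all__ = [
    "BoxFilterSpec",
    "composite_image",
    "box_filter",
    "hypr_process",
    "ann_hypr",
]


@dataclass(frozen=True)
class BoxFilterSpec:
    """Cubic uniform filter; size is odd voxels per axis (3, 5 or 7 typically)."""

    size: int = 7

    def __post_init__(self):
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError("box filter size must be a positive odd integer")


def composite_image(dyn: DynamicImage) -> np.ndarray:
    """Duration-weighted mean over all frames: C = Σ Δt_i I_i / Σ Δt_i."""
    if dyn.n_frames < 1:
        raise ValueError("empty series")
    dt = dyn.schedule.duration
    return (dyn.frames * dt).sum(axis=-1) / dt.sum()


def box_filter(vol: np.ndarray, spec: BoxFilterSpec) -> np.ndarray:
    """Uniform mean over the size³ neighborhood, replicate padding at borders."""
    vol = np.asarray(vol, dtype=float)
    return ndimage.uniform_filter(vol, size=spec.size, mode="nearest")


def hypr_process(
    dyn: DynamicImage, spec: BoxFilterSpec = BoxFilterSpec(), eps_rel: float = 1e-9
) -> DynamicImage:
    """HYPR: H_i = C · F(I_i) / F(C), frame by frame.

    Where |F(C)| falls below ``eps_rel × max(C)`` the weighting image is set to
    1 so the output falls back to the composite instead of amplifying noise in
    empty background.
    """
    comp = composite_image(dyn)
    fc = box_filter(comp, spec)
    eps = eps_rel * float(np.abs(comp).max()) if comp.size else 0.0
    guard = np.abs(fc) < eps
    fc_safe = np.where(guard, 1.0, fc)
    out = np.empty_like(dyn.frames)
    for i in range(dyn.n_frames):
        w = box_filter(dyn.frames[..., i], spec) / fc_safe
        w[guard] = 1.0
        out[..., i] = comp * w
    return dyn.with_frames(out)


def ann_hypr(
    model: AnnModel,
    dyn: DynamicImage,
    passes: int = 3,
    spec: BoxFilterSpec = BoxFilterSpec(),
) -> DynamicImage:
    """Cascade ANN denoising of every frame followed by HYPR over the series."""
    return hypr_process(denoise_series(model, dyn, passes), spec)
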