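"""Reference denoisers: 3D Gaussian FWHM filtering and 4D spatiotemporal
non-local means (NLM-ST), used for noise-vs-bias comparisons against the
ANN+HYPR chain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DynamicImage

__all__ = [
    "NlmConfig",
    "gaussian_filter_fwhm",
    "gaussian_series",
    "nlm_st",
    "nlm_st_multi",
    "estimate_noise_sigma",
    "match_gaussian_fwhm",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_filter_fwhm(vol: np.ndarray, fwhm: float, voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    """Isotropic Gaussian smoothing specified in mm FWHM.

    σ per axis is fwhm/(2√(2 ln 2)) converted to voxel units; replicate border
    handling; fwhm = 0 is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    vol = np.asarray(vol, dtype=float)
    if fwhm == 0:
        return vol.copy()
    sigma = [fwhm * FWHM_TO_SIGMA / v for v in voxel_size]
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="nearest")


def gaussian_series(dyn: DynamicImage, fwhm: float) -> DynamicImage:
    """Frame-wise Gaussian filtering of a dynamic series."""
    out = np.stack(
        [
            gaussian_filter_fwhm(dyn.frames[..., i], fwhm, dyn.voxel_size)
            for i in range(dyn.n_frames)
        ],
        axis=-1,
    )
    return dyn.with_frames(out)


@dataclass(frozen=True)
class NlmConfig:
    """Spatiotemporal NLM windows (odd extents, voxels/frames).

    The reference configuration is an 11×11×11×7 search window with a
    7×7×7×7 neighborhood; the smoothing constant h multiplies the robust
    noise estimate σ̂.
    """

    search_spatial: int = 11
    search_frames: int = 7
    nbhd_spatial: int = 7
    nbhd_frames: int = 7
    smoothing_constant: float = 1.0
    temporal_window_policy: str = "centered-sliding"  # or "fixed-range"
    fixed_range: tuple = (8, 14)  # 0-based inclusive frame block (frames 9–15)

    def __post_init__(self):
        for name in ("search_spatial", "search_frames", "nbhd_spatial", "nbhd_frames"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{name} must be a positive odd integer")
        if self.nbhd_spatial > self.search_spatial:
            raise ValueError("neighborhood must not exceed the search window spatially")
        if self.temporal_window_policy not in ("centered-sliding", "fixed-range"):
            raise ValueError("unknown temporal_window_policy")


def estimate_noise_sigma(frames: np.ndarray) -> np.ndarray:
    """Per-frame robust noise σ̂ from first differences along the first spatial axis.

    σ̂_f = 1.4826 · median(|∂₁I_f|) / √2 (consistent for Gaussian noise with
    zero-median differences). The median is taken over differences whose
    support is nonzero — empty background (exact zeros, common in low-count
    data) would otherwise drive the median to 0. Returns one σ̂ per frame.
    """
    sigmas = np.zeros(frames.shape[-1])
    for i in range(frames.shape[-1]):
        a = frames[:-1, ..., i]
        b = frames[1:, ..., i]
        support = (a != 0) | (b != 0)
        if support.any():
            d = np.abs(a[support] - b[support])
            sigmas[i] = 1.4826 * np.median(d) / np.sqrt(2.0)
    return sigmas


def _temporal_window(t: int, n_frames: int, cfg: NlmConfig) -> np.ndarray:
    if cfg.temporal_window_policy == "fixed-range":
        lo, hi = cfg.fixed_range
        lo = max(0, lo)
        hi = min(n_frames - 1, hi)
        return np.arange(lo, hi + 1)
    sw = min(cfg.search_frames, n_frames)
    start = int(np.clip(t - sw // 2, 0, n_frames - sw))
    return np.arange(start, start + sw)


def _shift_clamped(vol: np.ndarray, offset) -> np.ndarray:
    """vol sampled at x+offset with replicate clamping at the borders."""
    idx = [np.clip(np.arange(n) + o, 0, n - 1) for n, o in zip(vol.shape, offset)]
    return vol[np.ix_(*idx)]


def nlm_st(dyn: DynamicImage, cfg: NlmConfig = NlmConfig()) -> DynamicImage:
    """Spatiotemporal non-local means.

    Each output voxel is the similarity-weighted average of the voxels in its
    spatial×temporal search window; weights are exp(−d²/h²) where d² is the
    mean squared difference between the two 4D neighborhood blocks
    (replicate-clamped at spatial borders, clamped at the first/last frame) and
    h = smoothing_constant · σ̂. The center voxel is weighted like any other.
    """
    return nlm_st_multi(dyn, cfg, (cfg.smoothing_constant,))[cfg.smoothing_constant]


def nlm_st_multi(dyn: DynamicImage, cfg: NlmConfig, h_values) -> dict:
    """`nlm_st` for several smoothing constants at the cost of roughly one.

    The neighborhood distances d² are independent of h, so an h sweep (as used
    when matching noise levels between methods) only repeats the cheap
    weighting step. Returns {smoothing_constant: DynamicImage}.
    """
    frames = dyn.frames
    n_frames = frames.shape[-1]
    rs = cfg.search_spatial // 2
    rt_n = cfg.nbhd_frames // 2
    nb = cfg.nbhd_spatial

    window_frames = [_temporal_window(t, n_frames, cfg) for t in range(n_frames)]
    # h varies per target frame: σ̂ averaged over that frame's temporal window
    sigma_f = estimate_noise_sigma(frames)
    sig_t = np.array([sigma_f[w].mean() for w in window_frames])
    if np.all(sig_t <= 0):
        return {h: dyn.copy() for h in h_values}
    sig_t[sig_t <= 0] = sig_t[sig_t > 0].mean()  # degenerate frames borrow the mean
    inv_h2 = {h: 1.0 / (h * sig_t) ** 2 for h in h_values}

    offsets = [
        (dx, dy, dz)
        for dx in range(-rs, rs + 1)
        for dy in range(-rs, rs + 1)
        for dz in range(-rs, rs + 1)
    ]
    nt_offsets = np.arange(-rt_n, rt_n + 1)

    acc = {h: np.zeros(frames.shape[:3] + (n_frames,)) for h in h_values}
    wsum = {h: np.zeros(frames.shape[:3] + (n_frames,)) for h in h_values}
    # offset-outermost loop keeps the filtered-squared-difference cache small:
    # per offset only O(n_frames × nbhd_frames) volumes are ever needed.
    for off in offsets:
        shifted = {
            f: _shift_clamped(frames[..., f], off)
            for f in np.unique(np.concatenate(window_frames))
        }
        cache: dict = {}

        def filtered_sqdiff(a: int, b: int) -> np.ndarray:
            hit = cache.get((a, b))
            if hit is not None:
                return hit
            diff = frames[..., a] - _shift_clamped(frames[..., b], off)
            val = ndimage.uniform_filter(diff * diff, size=nb, mode="nearest")
            cache[(a, b)] = val
            return val

        for t in range(n_frames):
            for f in window_frames[t]:
                d2 = np.zeros(frames.shape[:3])
                for nt in nt_offsets:
                    a = int(np.clip(t + nt, 0, n_frames - 1))
                    b = int(np.clip(f + nt, 0, n_frames - 1))
                    d2 += filtered_sqdiff(a, b)
                d2 /= nt_offsets.size
                for h in h_values:
                    w = np.exp(-d2 * inv_h2[h][t])
                    acc[h][..., t] += w * shifted[f]
                    wsum[h][..., t] += w
    return {h: dyn.with_frames(acc[h] / wsum[h]) for h in h_values}


def match_gaussian_fwhm(
    realizations: list,
    roi: np.ndarray,
    target_ennsd: float,
    lo: float = 0.05,
    hi: float = 10.0,
    iters: int = 25,
) -> float:
    """FWHM (mm) whose Gaussian-filtered frame EnNSD over `roi` matches a target.

    Bisection on the ensemble noise of the filtered realization stack —
    the matched-noise protocol used to compare Gaussian smoothing against a
    denoiser at equal noise reduction. EnNSD decreases monotonically with FWHM.
    """
    from .evaluation import RealizationStack, ennsd

    def noise_at(fwhm: float) -> float:
        st = RealizationStack([gaussian_series(r, fwhm).frames for r in realizations])
        return ennsd(st, roi)[0]

    if noise_at(hi) > target_ennsd:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if noise_at(mid) > target_ennsd:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
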