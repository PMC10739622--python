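"""Synthetic dynamic brain phantom with Poisson count noise.

Builds noise-free dynamic series from one-tissue-compartment kinetics driven by a
plasma input function, then emulates a full-count acquisition and disjoint
reduced-count realizations at the count level (decay-corrected images; no
sinogram/scanner modelling).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (
    CountModel,
    DynamicImage,
    FrameSchedule,
    InputFunction,
    KineticGroundTruth,
    RegionMap,
)

__all__ = [
    "feng_aif",
    "tissue_tac",
    "render_phantom",
    "poisson_realizations",
    "calibrate_sensitivity",
    "default_region_map",
    "default_kinetics",
    "texture_field",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

DEFAULT_AIF_AMPLITUDES = (6000.0, 1500.0, 800.0)   # Bq/mL
DEFAULT_AIF_DECAY_RATES = (4.0, 0.25, 0.015)       # min^-1
DEFAULT_AIF_PEAK_MIN = 1.0


def feng_aif(
    peak_time: float = DEFAULT_AIF_PEAK_MIN,
    amplitudes=DEFAULT_AIF_AMPLITUDES,
    decay_rates=DEFAULT_AIF_DECAY_RATES,
    grid_step: float = 1.0 / 60.0,
    total_min: float = 60.0,
) -> InputFunction:
    """Feng-style arterial input: linear rise to the peak, tri-exponential washout.

    Cp(t) = (t / t_peak) * sum(A_i)            for t <= t_peak
          = sum(A_i * exp(-lambda_i (t - t_peak)))  afterwards

    Parameters are in Bq/mL (amplitudes), min^-1 (decay rates), minutes.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    decay_rates = np.asarray(decay_rates, dtype=float)
    if amplitudes.shape != (3,) or decay_rates.shape != (3,):
        raise ValueError("amplitudes and decay_rates must be 3-vectors")
    if np.any(decay_rates <= 0):
        raise ValueError("decay rates must be positive")
    if len(np.unique(decay_rates)) != 3:
        raise ValueError("decay rates must be distinct")
    if grid_step <= 0 or peak_time <= 0:
        raise ValueError("grid_step and peak_time must be positive")

    n = int(round(total_min / grid_step)) + 1
    t = np.arange(n) * grid_step
    peak_value = amplitudes.sum()
    cp = np.where(
        t <= peak_time,
        peak_value * t / peak_time,
        (amplitudes[None, :] * np.exp(-decay_rates[None, :] * (t - peak_time)[:, None])).sum(axis=1),
    )
    return InputFunction(t, np.clip(cp, 0.0, None))


def _convolve_exp(cp: np.ndarray, k2: float, step: float) -> np.ndarray:
    """Trapezoidal convolution (Cp ⊗ e^{-k2 t}) on the uniform grid."""
    n = cp.size
    e = np.exp(-k2 * np.arange(n) * step)
    full = np.convolve(cp, e)[:n] * step
    # trapezoid end-point correction: rectangle sum minus half the two edge terms
    full -= 0.5 * step * (cp[0] * e + cp * e[0])
    return full


def _frame_average(curve: np.ndarray, time: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Exact trapezoidal time-average of a gridded curve over each frame."""
    step = time[1] - time[0]
    out = np.empty(schedule.n_frames)
    for i, (t0, t1) in enumerate(zip(schedule.start, schedule.end)):
        i0 = int(round(t0 / step))
        i1 = int(round(t1 / step))
        if abs(i0 * step - t0) > 1e-9 or abs(i1 * step - t1) > 1e-9:
            raise ValueError("grid step must divide every frame boundary")
        if i1 >= time.size:
            raise ValueError("schedule extends beyond the input-function support")
        out[i] = np.trapezoid(curve[i0 : i1 + 1], dx=step) / (t1 - t0)
    return out


def tissue_tac(
    k1: float, k2: float, aif: InputFunction, schedule: FrameSchedule
) -> np.ndarray:
    """Frame-averaged 1T tissue curve C_T(t) = K1 · (Cp ⊗ e^{-k2 t})."""
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    if not aif.covers(schedule):
        raise ValueError("schedule extends beyond the input-function support")
    ct = k1 * _convolve_exp(aif.cp, k2, aif.step)
    return _frame_average(ct, aif.time, schedule)


def texture_field(
    shape,
    voxel_size=(2.0, 2.0, 2.0),
    amplitude: float = 0.15,
    correlation_mm: float = 6.0,
    seed: int = 0,
) -> np.ndarray:
    """Smooth multiplicative K1-heterogeneity field, mean 1.

    Real gray matter is not kinetically uniform: perfusion and tracer uptake
    vary by 10–20% within a structure at a few-mm spatial scale. A Gaussian
    random field (correlation length = the Gaussian σ, in mm) standardized to
    unit variance and scaled by ``amplitude`` emulates that; without it a
    piecewise-constant phantom gives a patch denoiser no in-region structure
    to learn. Clipped at 0.1 so K1 stays positive.
    """
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(shape)
    sigma_vox = [correlation_mm / v for v in voxel_size]
    g = ndimage.gaussian_filter(g, sigma=sigma_vox, mode="wrap")
    g = (g - g.mean()) / g.std()
    return np.clip(1.0 + amplitude * g, 0.1, None)


def render_phantom(
    regions: RegionMap,
    truth: KineticGroundTruth,
    aif: InputFunction,
    schedule: FrameSchedule,
    psf_fwhm: float = 3.0,
    k1_texture: np.ndarray | None = None,
) -> DynamicImage:
    """Noise-free dynamic phantom: per-region 1T TACs, optional Gaussian PSF blur.

    psf_fwhm is in mm (~3 mm emulates the reconstructed resolution of a
    high-resolution brain scanner); 0 disables the blur. Background stays 0
    before the blur. ``k1_texture`` (see `texture_field`) multiplies the
    voxel-wise K1 — i.e. the whole TAC — inside the labeled regions.
    """
    labels = regions.label_values
    missing = [int(l) for l in labels if l not in truth.k1]
    if missing:
        raise ValueError(f"no kinetic parameters for labels {missing}")
    shape = regions.labels.shape
    frames = np.zeros(shape + (schedule.n_frames,))
    for lab in labels:
        tac = tissue_tac(truth.k1[int(lab)], truth.k2[int(lab)], aif, schedule)
        frames[regions.labels == lab, :] = tac
    if k1_texture is not None:
        if k1_texture.shape != shape:
            raise ValueError("texture field shape must match the label volume")
        frames *= k1_texture[..., None]
    if psf_fwhm > 0:
        sigma_vox = [psf_fwhm * FWHM_TO_SIGMA / v for v in regions.voxel_size]
        for i in range(schedule.n_frames):
            frames[..., i] = ndimage.gaussian_filter(
                frames[..., i], sigma=sigma_vox, mode="nearest"
            )
    return DynamicImage(frames, schedule, regions.voxel_size)


def calibrate_sensitivity(
    img: DynamicImage,
    mask: np.ndarray,
    target_counts_per_voxel: float = 50.0,
    frame_duration_min: float = 5.0,
) -> float:
    """Scalar sensitivity such that full-count frames of the given duration
    average `target_counts_per_voxel` counts over the mask."""
    sel = np.isclose(img.schedule.duration, frame_duration_min)
    if not sel.any():
        sel = img.schedule.duration == img.schedule.duration.max()
    mean_activity = float(img.frames[mask][:, sel].mean())
    if mean_activity <= 0:
        raise ValueError("mask contains no activity to calibrate against")
    return target_counts_per_voxel / (mean_activity * frame_duration_min)


def poisson_realizations(
    img: DynamicImage,
    counts: CountModel,
    partition: bool = True,
    return_counts: bool = False,
):
    """Full-count Poisson sample plus reduced-count realizations.

    Expected counts per voxel/frame are activity × sensitivity × duration. With
    ``partition=True`` (default) one full-count draw is split into
    ``n_realizations`` disjoint subsets by multinomial thinning — the count-level
    analogue of redistributing list-mode events, which conserves total counts
    exactly and induces the same mild cross-realization correlation. With
    ``partition=False`` each realization is an independent Poisson draw at the
    reduced mean.

    Returns ``(full, reduced)`` as DynamicImages; with ``return_counts=True``
    also returns the integer count arrays ``(full_counts, reduced_counts)``.
    """
    if np.any(img.frames < 0):
        raise ValueError("phantom activity must be nonnegative")
    if partition and abs(counts.dose_fraction * counts.n_realizations - 1.0) > 1e-9:
        raise ValueError(
            "partition mode requires dose_fraction × n_realizations == 1 "
            f"(got {counts.dose_fraction} × {counts.n_realizations})"
        )
    rng = np.random.default_rng(counts.seed)
    duration = img.schedule.duration  # broadcast over the frame axis
    lam = img.frames * counts.sensitivity * duration
    full_counts = rng.poisson(lam)
    if partition:
        p = np.full(counts.n_realizations, 1.0 / counts.n_realizations)
        split = rng.multinomial(full_counts, p)  # shape (..., n_realizations)
        reduced_counts = np.moveaxis(split, -1, 0)
    else:
        reduced_counts = np.stack(
            [
                rng.poisson(lam * counts.dose_fraction)
                for _ in range(counts.n_realizations)
            ]
        )
    denom_full = counts.sensitivity * duration
    full = img.with_frames(full_counts / denom_full)
    denom_red = denom_full * counts.dose_fraction
    reduced = [img.with_frames(c / denom_red) for c in reduced_counts]
    if return_counts:
        return full, reduced, full_counts, reduced_counts
    return full, reduced


def default_region_map(shape=(64, 64, 48), voxel_size=(2.0, 2.0, 2.0)) -> RegionMap:
    """Geometric brain-like label volume with 6 regions inside an ellipsoidal head.

    Regions (1..6): cortical gray shell, white-matter core, a deep-gray
    thalamic blob, left/right putamen-like blobs, cerebellum. Structures are
    deliberately sized so that the gray-matter ROIs are interior-dominated at
    the ~8 mm scale of the denoising patches and filters — the regime of the
    large structural (FreeSurfer-style) ROIs used for regional quantification
    in human studies. ROI means of thinner ribbons would be dominated by
    partial-volume flux under *any* smoother, which is a property of the ROI
    geometry rather than of a denoiser.
    """
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    labels = np.zeros(shape, dtype=np.int16)
    head = (x / 0.95) ** 2 + (y / 0.95) ** 2 + (z / 0.92) ** 2 <= 1.0
    inner = (x / 0.50) ** 2 + (y / 0.52) ** 2 + (z / 0.50) ** 2 <= 1.0
    labels[head] = 1                      # cortical gray shell
    labels[inner] = 2                     # white-matter core
    thal = (x / 0.30) ** 2 + ((y - 0.05) / 0.30) ** 2 + (z / 0.30) ** 2 <= 1.0
    labels[thal] = 3
    put_l = ((x - 0.55) / 0.28) ** 2 + ((y - 0.35) / 0.30) ** 2 + (z / 0.40) ** 2 <= 1.0
    labels[put_l & head] = 4
    put_r = ((x + 0.55) / 0.28) ** 2 + ((y - 0.35) / 0.30) ** 2 + (z / 0.40) ** 2 <= 1.0
    labels[put_r & head] = 5
    cereb = (x / 0.5) ** 2 + ((y + 0.65) / 0.30) ** 2 + ((z + 0.35) / 0.45) ** 2 <= 1.0
    labels[cereb & head] = 6
    names = {
        1: "cortex",
        2: "white_matter",
        3: "thalamus",
        4: "putamen_l",
        5: "putamen_r",
        6: "cerebellum",
    }
    names = {k: v for k, v in names.items() if (labels == k).any()}
    return RegionMap(labels, voxel_size, names)


#: labels whose ROI means are reported in evaluations — gray-matter structures,
#: mirroring the gray-only structural ROI sets of human regional quantification
GRAY_MATTER_REGIONS = ("cortex", "thalamus", "putamen_l", "putamen_r", "cerebellum")


def default_kinetics() -> KineticGroundTruth:
    """Ground-truth 1T parameters per region, spanning the gray/white contrast
    of a synaptic-density tracer (K1 0.05–0.3 mL·cm⁻³·min⁻¹, k2 0.02–0.15 min⁻¹)."""
    k1 = {1: 0.25, 2: 0.10, 3: 0.30, 4: 0.28, 5: 0.26, 6: 0.22}
    k2 = {1: 0.055, 2: 0.11, 3: 0.06, 4: 0.05, 5: 0.065, 6: 0.075}
    return KineticGroundTruth(k1, k2)
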