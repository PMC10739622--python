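"""Voxel-wise one-tissue-compartment kinetic analysis by the basis function method.

The 1T model C_T(t) = K1 · (Cp ⊗ e^{-k2 t}) is linear in K1 once k2 is fixed, so
fitting reduces to a weighted least-squares amplitude per candidate k2 on a grid
spanning [0.01, 1.0] min⁻¹ and picking the grid point with the smallest weighted
residual sum of squares. VT = K1/k2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DynamicImage, FrameSchedule, InputFunction
from .phantom import _convolve_exp, _frame_average

__all__ = [
    "BasisSet",
    "FrameWeights",
    "ParametricMaps",
    "compute_frame_weights",
    "build_basis",
    "fit_tac_1t",
    "fit_parametric",
]

K2_MIN = 0.01  # min^-1, washout-rate grid bounds
K2_MAX = 1.0


@dataclass(frozen=True)
class BasisSet:
    """Frame-averaged basis curves Cp ⊗ e^{-k2 t} on an ascending k2 grid."""

    k2_grid: np.ndarray   # (J,), min^-1, ascending within [K2_MIN, K2_MAX]
    basis_tacs: np.ndarray  # (J, n_frames)

    def __post_init__(self):
        if self.k2_grid.ndim != 1 or self.basis_tacs.shape[0] != self.k2_grid.size:
            raise ValueError("one basis row per k2 grid point required")
        if np.any(np.diff(self.k2_grid) <= 0):
            raise ValueError("k2 grid must be strictly ascending")
        if self.k2_grid[0] < K2_MIN - 1e-12 or self.k2_grid[-1] > K2_MAX + 1e-12:
            raise ValueError(f"k2 grid must lie within [{K2_MIN}, {K2_MAX}] min^-1")


@dataclass(frozen=True)
class FrameWeights:
    """Per-frame nonnegative fit weights, normalized to sum 1."""

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        s = w.sum()
        if s <= 0:
            raise ValueError("weights must not be all zero")
        object.__setattr__(self, "w", w / s)

    @classmethod
    def uniform(cls, n_frames: int) -> "FrameWeights":
        return cls(np.full(n_frames, 1.0 / n_frames))


@dataclass
class ParametricMaps:
    """Voxel-wise K1 (mL·cm⁻³·min⁻¹), k2 (min⁻¹), VT (mL·cm⁻³), and weighted RSS."""

    k1: np.ndarray
    k2: np.ndarray
    vt: np.ndarray
    wrss: np.ndarray


def compute_frame_weights(
    counts_per_frame, schedule: FrameSchedule, mode: str = "nec"
) -> FrameWeights:
    """Noise-equivalent-count frame weights: w_i ∝ Δt_i² / C_i.

    C_i is the total image count of frame i (the image-level NEC surrogate);
    the Δt² factor reflects inverse variance of count-normalized activity.
    Frames with zero counts get weight 0. ``mode='uniform'`` ignores counts.
    """
    counts = np.asarray(counts_per_frame, dtype=float)
    if counts.shape != (schedule.n_frames,):
        raise ValueError("one count total per frame required")
    if mode == "uniform":
        return FrameWeights.uniform(schedule.n_frames)
    if mode != "nec":
        raise ValueError("mode must be 'nec' or 'uniform'")
    dt = schedule.duration
    w = np.zeros_like(counts)
    ok = counts > 0
    if not ok.all():
        import warnings

        warnings.warn(
            f"{int((~ok).sum())} frame(s) with zero counts were given zero weight"
        )
    w[ok] = dt[ok] ** 2 / counts[ok]
    return FrameWeights(w)


def build_basis(
    aif: InputFunction, schedule: FrameSchedule, n_bases: int = 100
) -> BasisSet:
    """Log-spaced k2 grid over [0.01, 1.0] min⁻¹ with frame-averaged basis TACs."""
    if n_bases < 2:
        raise ValueError("need at least 2 basis functions")
    if not aif.covers(schedule):
        raise ValueError("input function does not cover the schedule")
    k2_grid = np.geomspace(K2_MIN, K2_MAX, n_bases)
    tacs = np.empty((n_bases, schedule.n_frames))
    for j, k2 in enumerate(k2_grid):
        conv = _convolve_exp(aif.cp, k2, aif.step)
        tacs[j] = _frame_average(conv, aif.time, schedule)
    return BasisSet(k2_grid, tacs)


def fit_tac_1t(tac: np.ndarray, basis: BasisSet, weights: FrameWeights):
    """Fit a single TAC; returns (K1, k2, VT, wrss).

    For each grid k2_j the weighted LS amplitude through the origin is
    K1_j = Σ w_i B_ij y_i / Σ w_i B_ij² (clipped at 0); the j with minimal
    weighted RSS wins. An all-zero TAC returns (0, k2_min, 0, 0) by convention.
    """
    tac = np.asarray(tac, dtype=float)
    if tac.shape != (basis.basis_tacs.shape[1],):
        raise ValueError("TAC length must match the basis frames")
    k1, k2, vt, wrss = _fit_matrix(tac[None, :], basis, weights)
    return float(k1[0]), float(k2[0]), float(vt[0]), float(wrss[0])


def _fit_matrix(tacs: np.ndarray, basis: BasisSet, weights: FrameWeights):
    """Vectorized grid fit of many TACs: tacs is (V, n_frames)."""
    w = weights.w
    b = basis.basis_tacs                       # (J, F)
    wb = b * w                                 # (J, F)
    denom = np.einsum("jf,jf->j", wb, b)       # Σ w B², (J,)
    num = tacs @ wb.T                          # (V, J)
    k1_j = np.clip(num / denom, 0.0, None)     # (V, J)
    y2 = (tacs * tacs * w).sum(axis=1)         # Σ w y², (V,)
    rss = y2[:, None] - 2.0 * k1_j * num + k1_j * k1_j * denom
    jbest = np.argmin(rss, axis=1)
    rows = np.arange(tacs.shape[0])
    k1 = k1_j[rows, jbest]
    k2 = basis.k2_grid[jbest]
    wrss = np.maximum(rss[rows, jbest], 0.0)
    zero = ~np.any(tacs != 0, axis=1)
    k1 = np.where(zero, 0.0, k1)
    k2 = np.where(zero, basis.k2_grid[0], k2)
    vt = np.where(k2 > 0, k1 / k2, 0.0)
    wrss = np.where(zero, 0.0, wrss)
    return k1, k2, vt, wrss


def fit_parametric(
    dyn: DynamicImage,
    basis: BasisSet,
    weights: FrameWeights,
    mask: np.ndarray,
) -> ParametricMaps:
    """Voxel-by-voxel 1T fit over a boolean mask; out-of-mask voxels are 0."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dyn.shape3:
        raise ValueError("mask shape must match the volume")
    if not mask.any():
        raise ValueError("empty mask")
    tacs = dyn.frames[mask]  # (V, F)
    k1, k2, vt, wrss = _fit_matrix(tacs, basis, weights)
    maps = []
    for vals in (k1, k2, vt, wrss):
        vol = np.zeros(dyn.shape3)
        vol[mask] = vals
        maps.append(vol)
    return ParametricMaps(*maps)
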