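"""Quantitative evaluation: ensemble noise (EnNSD), regional bias (RE), noise
reduction (NR), Poisson dose-equivalence, and the noise-vs-bias sweep over
denoising methods."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RealizationStack",
    "ennsd",
    "regional_re",
    "noise_reduction",
    "dose_equivalence_factor",
    "noise_bias_sweep",
    "plot_noise_bias",
]


@dataclass
class RealizationStack:
    """≥2 co-registered volumes (one per noise realization) plus the full-count
    reference. Arrays may be 3D volumes or 4D dynamic series."""

    images: list
    reference: np.ndarray = None

    def __post_init__(self):
        if len(self.images) < 2:
            raise ValueError("need at least 2 realizations")
        shapes = {np.asarray(im).shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError("realizations must share one shape")
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != self.images[0].shape:
                raise ValueError("reference shape must match the realizations")

    @property
    def stack(self) -> np.ndarray:
        return np.stack(self.images)


def ennsd(stack: RealizationStack, roi: np.ndarray, eps_rel: float = 1e-6):
    """Ensemble normalized standard deviation over an ROI, in percent.

    Per voxel: sample SD across realizations (divisor J−1) divided by the
    across-realization mean; averaged over the ROI's voxels. Voxels whose
    |mean| falls below ``eps_rel × max|mean|`` are excluded; the excluded count
    is returned alongside the value.
    """
    roi = np.asarray(roi, dtype=bool)
    arr = stack.stack[:, roi]  # (J, m) or (J, m, F) -> flatten trailing
    arr = arr.reshape(arr.shape[0], -1)
    if arr.shape[1] == 0:
        raise ValueError("empty ROI")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    eps = eps_rel * float(np.abs(mean).max())
    ok = np.abs(mean) >= eps if eps > 0 else np.abs(mean) > 0
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("all ROI voxels excluded by the near-zero-mean guard")
    value = float((sd[ok] / mean[ok]).mean()) * 100.0
    return value, n_excluded


def regional_re(stack: RealizationStack, roi: np.ndarray) -> float:
    """Relative error of the regional mean vs the full-count reference, percent.

    (mean_j − mean_full)/mean_full per realization, averaged over realizations.
    """
    if stack.reference is None:
        raise ValueError("a full-count reference is required for RE")
    roi = np.asarray(roi, dtype=bool)
    ref_mean = float(stack.reference[roi].mean())
    if ref_mean == 0:
        raise ValueError("reference ROI mean is zero")
    means = np.array([im[roi].mean() for im in stack.images])
    return float(((means - ref_mean) / ref_mean).mean()) * 100.0


def noise_reduction(ennsd_raw: float, ennsd_processed: float) -> float:
    """NR = (EnNSD_raw − EnNSD_processed) / EnNSD_raw × 100, percent."""
    if ennsd_raw <= 0:
        raise ValueError("raw EnNSD must be positive")
    return (ennsd_raw - ennsd_processed) / ennsd_raw * 100.0


def dose_equivalence_factor(nr_fraction: float) -> float:
    """Fold dose increase statistically equivalent to a fractional noise
    reduction, under Poisson statistics (σ ∝ 1/√dose): 1/(1 − NR)²."""
    if not (0 <= nr_fraction < 1):
        raise ValueError("nr_fraction must lie in [0, 1)")
    return 1.0 / (1.0 - nr_fraction) ** 2


def _roi_records(name, param, target, proc_stack, raw_ennsd, rois):
    recs = []
    for roi_name, roi_mask in rois.items():
        e, _ = ennsd(proc_stack, roi_mask)
        re = regional_re(proc_stack, roi_mask)
        nr = noise_reduction(raw_ennsd[(roi_name, target)], e)
        recs.append(
            {
                "method": name,
                "parameter": param,
                "roi": roi_name,
                "target": target,
                "ennsd_pct": e,
                "re_pct": re,
                "nr_pct": nr,
            }
        )
    return recs


def noise_bias_sweep(
    raw_frames: list,
    full_frames: np.ndarray,
    methods: dict,
    rois: dict,
    parametric: dict | None = None,
) -> pd.DataFrame:
    """Noise-vs-bias table across methods and ROIs.

    raw_frames — list of 4D arrays, one per reduced-count realization;
    full_frames — the full-count 4D reference;
    methods — {(name, parameter): list of processed 4D arrays (same realizations)},
    with the raw stack added automatically under ("1/10", "");
    rois — {name: 3D boolean mask};
    parametric — optional {(name, parameter): {"K1": (list, ref), "VT": (list, ref)}}
    adding rows per parametric map.

    Returns one row per method × ROI × target with EnNSD/RE/NR in percent;
    NR is relative to the raw stack of the same target.
    """
    all_methods = {("1/10", ""): raw_frames}
    all_methods.update(methods)
    raw_stack = RealizationStack(raw_frames, full_frames)
    raw_ennsd = {}
    for roi_name, roi_mask in rois.items():
        e, _ = ennsd(raw_stack, roi_mask)
        raw_ennsd[(roi_name, "frames")] = e
    if parametric:
        raw_param = parametric.get(("1/10", ""))
        if raw_param is None:
            raise ValueError("parametric results must include the raw ('1/10', '') entry")
        for target, (maps, ref) in raw_param.items():
            st = RealizationStack(maps, ref)
            for roi_name, roi_mask in rois.items():
                e, _ = ennsd(st, roi_mask)
                raw_ennsd[(roi_name, target)] = e

    rows = []
    for (name, param), processed in all_methods.items():
        if np.asarray(processed[0]).shape != np.asarray(raw_frames[0]).shape:
            raise ValueError(f"method {name!r} stack shape mismatch")
        st = RealizationStack(processed, full_frames)
        rows += _roi_records(name, param, "frames", st, raw_ennsd, rois)
    if parametric:
        for (name, param), targets in parametric.items():
            for target, (maps, ref) in targets.items():
                st = RealizationStack(maps, ref)
                rows += _roi_records(name, param, target, st, raw_ennsd, rois)
    return pd.DataFrame(rows)


def plot_noise_bias(table: pd.DataFrame, target: str, out_path):
    """EnNSD-vs-RE scatter per method for one target; writes a figure file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["target"] == target]
    fig, ax = plt.subplots(figsize=(6, 5))
    for (name, param), grp in sub.groupby(["method", "parameter"]):
        label = f"{name} {param}".strip()
        ax.scatter(grp["re_pct"], grp["ennsd_pct"], label=label, s=18)
    ax.set_xlabel("RE (%)")
    ax.set_ylabel("EnNSD (%)")
    ax.set_title(f"noise vs bias — {target}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
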