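"""Patch-based single-hidden-layer ANN denoiser with cascade application.

A fully connected network maps mean-removed 4×4×4 patches of a reduced-count
frame to the central 2×2×2 of the co-located full-count patch. Trained once on
one frame pair by mini-batch SGD, it is applied in cascade (default three
times) to denoise whole dynamic series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import DynamicImage

__all__ = [
    "PatchPairSet",
    "ScalingRecord",
    "TrainConfig",
    "AnnModel",
    "extract_patch_pairs",
    "select_training_patches",
    "fit_row_scaling",
    "apply_row_scaling",
    "invert_row_scaling",
    "train_ann",
    "ann_forward",
    "denoise_frame",
    "denoise_series",
    "train_from_frame_pair",
]

INPUT_PATCH = 4   # input patches are 4x4x4
LABEL_PATCH = 2   # labels are the central 2x2x2
N_INPUT = INPUT_PATCH ** 3
N_LABEL = LABEL_PATCH ** 3


@dataclass
class PatchPairSet:
    """Mean-removed training vectors: inputs (K, 64), labels (K, 8)."""

    inputs: np.ndarray
    labels: np.ndarray
    positions: np.ndarray  # (K, 3) patch origins in the source frame

    def __post_init__(self):
        if self.inputs.shape[0] != self.labels.shape[0]:
            raise ValueError("inputs and labels must have equal pair counts")
        if self.inputs.shape[1] != N_INPUT or self.labels.shape[1] != N_LABEL:
            raise ValueError("inputs must be 64-long and labels 8-long vectors")

    @property
    def count(self) -> int:
        return self.inputs.shape[0]


@dataclass
class ScalingRecord:
    """Per-feature min-max extrema of the training data plus the global
    normalization constant of the training image."""

    input_min: np.ndarray
    input_max: np.ndarray
    label_min: np.ndarray
    label_max: np.ndarray
    global_max: float

    def __post_init__(self):
        if np.any(self.input_max < self.input_min) or np.any(self.label_max < self.label_min):
            raise ValueError("row max must be >= row min")
        if self.global_max <= 0:
            raise ValueError("global_max must be positive")


@dataclass
class TrainConfig:
    k_pairs: int = 100_000            # total training pairs K
    high_variance_count: int = 50_000
    lr0: float = 0.01
    decay_gamma: float = 1e-4         # inverse-decay: lr0 * (1 + gamma*t)^(-power)
    decay_power: float = 0.75
    iterations: int = 150_000         # mini-batch parameter updates
    batch_size: int = 64
    n_hidden: int = 128
    init_scale: float | None = None   # None -> 1/sqrt(fan_in)
    seed: int = 0

    def __post_init__(self):
        if self.high_variance_count > self.k_pairs:
            raise ValueError("high_variance_count must not exceed k_pairs")
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")


@dataclass
class AnnModel:
    """Trained two-layer mapping: out = W2·ReLU(W1·x + b1) + b2."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    scaling: ScalingRecord
    loss_trace: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        n_hid, n_inp = self.w1.shape
        if self.b1.shape != (n_hid,) or self.w2.shape[1] != n_hid:
            raise ValueError("inconsistent layer dimensions")
        if self.w2.shape[0] != self.b2.shape[0]:
            raise ValueError("inconsistent output dimensions")

    @property
    def dims(self):
        return (self.w1.shape[1], self.w1.shape[0], self.w2.shape[0])

    # -- serialization ---------------------------------------------------
    def to_json(self, path):
        doc = {
            "dims": list(self.dims),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "scaling": {
                "input_min": self.scaling.input_min.tolist(),
                "input_max": self.scaling.input_max.tolist(),
                "label_min": self.scaling.label_min.tolist(),
                "label_max": self.scaling.label_max.tolist(),
                "global_max": self.scaling.global_max,
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "AnnModel":
        with open(path) as fh:
            doc = json.load(fh)
        sc = doc["scaling"]
        return cls(
            w1=np.asarray(doc["w1"]),
            b1=np.asarray(doc["b1"]),
            w2=np.asarray(doc["w2"]),
            b2=np.asarray(doc["b2"]),
            scaling=ScalingRecord(
                np.asarray(sc["input_min"]),
                np.asarray(sc["input_max"]),
                np.asarray(sc["label_min"]),
                np.asarray(sc["label_max"]),
                float(sc["global_max"]),
            ),
        )


# ---------------------------------------------------------------------------
# training data preparation
# ---------------------------------------------------------------------------

def _sliding_patches(vol: np.ndarray, size: int) -> np.ndarray:
    """All stride-1 size³ patches, flattened in C order: (n0, n1, n2, size³)."""
    win = np.lib.stride_tricks.sliding_window_view(vol, (size, size, size))
    return win.reshape(win.shape[:3] + (size ** 3,))


def extract_patch_pairs(
    f: np.ndarray, u: np.ndarray, label_mean: str = "patch"
) -> PatchPairSet:
    """One mean-removed (input, label) pair per valid 4×4×4 patch origin.

    `f` and `u` must already share the training image's global-max
    normalization (see `train_from_frame_pair`).

    ``label_mean`` selects the baseline subtracted from the central 2×2×2
    label: ``"patch"`` (default) subtracts the mean of the co-located 4×4×4
    patch of `u`, so the network predicts the center-vs-neighborhood offset
    and the test-time reconstruction (which adds the 4×4×4 test-patch mean
    back) preserves local means; ``"central"`` subtracts the central patch's
    own mean, which couples the reconstructed mean to the 4×4×4 box mean.
    """
    f = np.asarray(f, dtype=float)
    u = np.asarray(u, dtype=float)
    if f.shape != u.shape:
        raise ValueError("f and u must have the same shape")
    if min(f.shape) < INPUT_PATCH:
        raise ValueError("each dimension must be >= 4")
    if label_mean not in ("patch", "central"):
        raise ValueError("label_mean must be 'patch' or 'central'")
    inp = _sliding_patches(f, INPUT_PATCH)          # (gx, gy, gz, 64)
    lab_all = _sliding_patches(u, LABEL_PATCH)      # (nx-1, ny-1, nz-1, 8)
    gx, gy, gz = inp.shape[:3]
    lab = lab_all[1 : gx + 1, 1 : gy + 1, 1 : gz + 1]  # central 2³ at offset (1,1,1)
    inputs = inp.reshape(-1, N_INPUT)
    labels = lab.reshape(-1, N_LABEL)
    if label_mean == "patch":
        u_patch = _sliding_patches(u, INPUT_PATCH).reshape(-1, N_INPUT)
        baseline = u_patch.mean(axis=1, keepdims=True)
    else:
        baseline = labels.mean(axis=1, keepdims=True)
    inputs = inputs - inputs.mean(axis=1, keepdims=True)
    labels = labels - baseline
    pos = np.stack(
        np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    return PatchPairSet(inputs, labels, pos)


def select_training_patches(pairs: PatchPairSet, cfg: TrainConfig) -> PatchPairSet:
    """Variance-ranked selection: top `high_variance_count` by label-patch
    variance, the rest drawn uniformly (seeded) from the remainder."""
    k = cfg.k_pairs
    if pairs.count < k:
        raise ValueError(
            f"only {pairs.count} patch pairs available but k_pairs={k}; "
            "shrink k_pairs for this frame size"
        )
    var = pairs.labels.var(axis=1)
    order = np.argsort(var, kind="stable")[::-1]  # descending variance
    top = order[: cfg.high_variance_count]
    rest = order[cfg.high_variance_count :]
    n_rand = k - cfg.high_variance_count
    rng = np.random.default_rng(cfg.seed)
    picked = rng.choice(rest.size, size=n_rand, replace=False) if n_rand else []
    sel = np.concatenate([top, rest[picked]]) if n_rand else top
    return PatchPairSet(pairs.inputs[sel], pairs.labels[sel], pairs.positions[sel])


def fit_row_scaling(inputs: np.ndarray, labels: np.ndarray, global_max: float = 1.0):
    """Min-max scale every feature row to [-1, 1]; returns the record and data.

    Features are the 64 input and 8 label vector entries; extrema are taken
    across the K training pairs. Degenerate rows (max == min) scale to 0.
    """
    if inputs.shape[0] == 0:
        raise ValueError("empty training set")
    rec = ScalingRecord(
        input_min=inputs.min(axis=0),
        input_max=inputs.max(axis=0),
        label_min=labels.min(axis=0),
        label_max=labels.max(axis=0),
        global_max=global_max,
    )
    xs = apply_row_scaling(inputs, rec.input_min, rec.input_max)
    ys = apply_row_scaling(labels, rec.label_min, rec.label_max)
    return rec, xs, ys


def apply_row_scaling(x: np.ndarray, row_min: np.ndarray, row_max: np.ndarray) -> np.ndarray:
    """x_scaled = 2 (x - min) / (max - min) - 1; constant rows map to 0.

    Values outside the training extrema map outside [-1, 1] — no clipping.
    """
    span = row_max - row_min
    safe = np.where(span > 0, span, 1.0)
    scaled = 2.0 * (x - row_min) / safe - 1.0
    return np.where(span > 0, scaled, 0.0)


def invert_row_scaling(y: np.ndarray, row_min: np.ndarray, row_max: np.ndarray) -> np.ndarray:
    """Inverse of `apply_row_scaling`; degenerate rows recover the stored constant."""
    span = row_max - row_min
    x = (y + 1.0) * 0.5 * span + row_min
    return np.where(span > 0, x, row_min)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def ann_forward(model_or_weights, x: np.ndarray) -> np.ndarray:
    """Network output W2·ReLU(W1·x + b1) + b2 for row vectors x (…, 64)."""
    m = model_or_weights
    w1, b1, w2, b2 = m.w1, m.b1, m.w2, m.b2
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != w1.shape[1]:
        raise ValueError(f"input length {x.shape[-1]} != {w1.shape[1]}")
    h = np.maximum(x @ w1.T + b1, 0.0)
    return h @ w2.T + b2


def train_ann(
    xs: np.ndarray,
    ys: np.ndarray,
    cfg: TrainConfig,
    scaling: ScalingRecord,
) -> AnnModel:
    """Mini-batch SGD on the mean squared recovery loss.

    Learning rate follows the inverse-decay policy
    lr_t = lr0 · (1 + γ t)^(-p); exactly ``cfg.iterations`` parameter updates
    are performed with seeded per-epoch reshuffling. The per-batch loss trace
    is recorded on the returned model.
    """
    k, n_inp = xs.shape
    n_out = ys.shape[1]
    n_hid = cfg.n_hidden
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from selection
    s1 = cfg.init_scale if cfg.init_scale is not None else 1.0 / np.sqrt(n_inp)
    s2 = cfg.init_scale if cfg.init_scale is not None else 1.0 / np.sqrt(n_hid)
    w1 = rng.uniform(-s1, s1, size=(n_hid, n_inp))
    b1 = np.zeros(n_hid)
    w2 = rng.uniform(-s2, s2, size=(n_out, n_hid))
    b2 = np.zeros(n_out)

    bs = min(cfg.batch_size, k)
    n_batches = k // bs
    loss_trace = np.empty(cfg.iterations, dtype=np.float32)
    perm = rng.permutation(k)
    batch_idx = 0
    for t in range(cfg.iterations):
        if batch_idx >= n_batches:
            perm = rng.permutation(k)
            batch_idx = 0
        sel = perm[batch_idx * bs : (batch_idx + 1) * bs]
        batch_idx += 1
        xb = xs[sel]
        yb = ys[sel]
        z1 = xb @ w1.T + b1
        a1 = np.maximum(z1, 0.0)
        out = a1 @ w2.T + b2
        err = out - yb                               # (bs, n_out)
        loss = float(np.einsum("ij,ij->", err, err)) / xb.shape[0]
        loss_trace[t] = loss
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at iteration {t} (loss not finite)"
            )
        lr = cfg.lr0 * (1.0 + cfg.decay_gamma * t) ** (-cfg.decay_power)
        g_out = (2.0 / xb.shape[0]) * err            # dL/dout
        g_w2 = g_out.T @ a1
        g_b2 = g_out.sum(axis=0)
        g_a1 = g_out @ w2
        g_z1 = g_a1 * (z1 > 0)
        g_w1 = g_z1.T @ xb
        g_b1 = g_z1.sum(axis=0)
        w2 -= lr * g_w2
        b2 -= lr * g_b2
        w1 -= lr * g_w1
        b1 -= lr * g_b1
    return AnnModel(w1, b1, w2, b2, scaling, loss_trace=loss_trace)


def train_from_frame_pair(
    low: np.ndarray,
    full: np.ndarray,
    cfg: TrainConfig,
    shared_norm: bool = True,
    label_mean: str = "patch",
) -> AnnModel:
    """End-to-end training on one reduced/full-count frame pair.

    The reduced-count frame is normalized to [0, 1] by its maximum; the label
    frame is divided by the same constant when ``shared_norm`` (activity units
    match between dose levels) or by its own maximum otherwise.
    """
    low = np.asarray(low, dtype=float)
    full = np.asarray(full, dtype=float)
    gmax = float(low.max())
    if gmax <= 0:
        raise ValueError("training frame has no positive intensity")
    umax = gmax if shared_norm else float(full.max())
    pairs = extract_patch_pairs(low / gmax, full / umax, label_mean=label_mean)
    pairs = select_training_patches(pairs, cfg)
    rec, xs, ys = fit_row_scaling(pairs.inputs, pairs.labels, global_max=gmax)
    return train_ann(xs, ys, cfg, rec)


# ---------------------------------------------------------------------------
# cascade denoising
# ---------------------------------------------------------------------------

def _denoise_once(model: AnnModel, z: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    gmax = float(z.max())
    if gmax <= 0:
        return z.copy()
    zn = z / gmax
    pad = np.pad(zn, 1, mode="edge")
    patches = _sliding_patches(pad, INPUT_PATCH)       # (gx, gy, gz, 64)
    gx, gy, gz = patches.shape[:3]
    flat = patches.reshape(-1, N_INPUT)
    means = flat.mean(axis=1, keepdims=True)
    sc = model.scaling
    out = np.empty((flat.shape[0], N_LABEL))
    for i0 in range(0, flat.shape[0], chunk):
        blk = flat[i0 : i0 + chunk]
        xs = apply_row_scaling(blk - means[i0 : i0 + chunk], sc.input_min, sc.input_max)
        ys = ann_forward(model, xs)
        out[i0 : i0 + chunk] = invert_row_scaling(ys, sc.label_min, sc.label_max)
    out += means
    out_grid = out.reshape(gx, gy, gz, LABEL_PATCH, LABEL_PATCH, LABEL_PATCH)
    acc = np.zeros(pad.shape)
    cov = np.zeros(pad.shape)
    for dx in range(LABEL_PATCH):
        for dy in range(LABEL_PATCH):
            for dz in range(LABEL_PATCH):
                acc[1 + dx : 1 + dx + gx, 1 + dy : 1 + dy + gy, 1 + dz : 1 + dz + gz] += out_grid[..., dx, dy, dz]
                cov[1 + dx : 1 + dx + gx, 1 + dy : 1 + dy + gy, 1 + dz : 1 + dz + gz] += 1.0
    result = acc[1:-1, 1:-1, 1:-1] / cov[1:-1, 1:-1, 1:-1]
    return result * gmax


def denoise_frame(model: AnnModel, z: np.ndarray, passes: int = 3) -> np.ndarray:
    """Cascade ANN denoising of one 3D frame.

    Each pass normalizes the frame by its own maximum, replicate-pads by one
    voxel so every voxel is covered, runs every 4×4×4 patch through the network
    (training-set row scaling in, label scaling out, patch mean added back),
    averages the 8 overlapping 2×2×2 contributions per interior voxel, and
    rescales. ``passes=0`` returns the input unchanged.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    z = np.asarray(z, dtype=float)
    if min(z.shape) + 2 < INPUT_PATCH:
        raise ValueError("frame too small to patch even after padding")
    out = z.copy()
    for _ in range(passes):
        out = _denoise_once(model, out)
    return out


def denoise_series(model: AnnModel, dyn: DynamicImage, passes: int = 3) -> DynamicImage:
    """Apply `denoise_frame` independently to every frame; schedule preserved."""
    frames = np.stack(
        [denoise_frame(model, dyn.frames[..., i], passes) for i in range(dyn.n_frames)],
        axis=-1,
    )
    return dyn.with_frames(frames)
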