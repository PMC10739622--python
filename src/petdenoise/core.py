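"""Core containers shared across the toolkit.

Conventions used everywhere in this package:

* all times are in **minutes**; activity is in **Bq/mL**;
* dynamic arrays are indexed ``(x, y, z, frame)`` — frame axis last;
* frame indices are 0-based in code and 1-based in user-facing messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "InputFunction",
    "DynamicImage",
    "RegionMap",
    "KineticGroundTruth",
    "CountModel",
]

#: 21-frame, 60-minute acquisition: 6 x 30 s, 3 x 1 min, 2 x 2 min, 10 x 5 min.
DEFAULT_FRAME_DURATIONS_MIN = (0.5,) * 6 + (1.0,) * 3 + (2.0,) * 2 + (5.0,) * 10


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame timing of a dynamic acquisition."""

    start: np.ndarray  # minutes, first element 0
    end: np.ndarray    # minutes

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("start/end must be equal-length 1D arrays")
        if start[0] != 0.0:
            raise ValueError("first frame must start at t = 0")
        if np.any(end <= start):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], end[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_durations(cls, durations_min) -> "FrameSchedule":
        d = np.asarray(durations_min, dtype=float)
        end = np.cumsum(d)
        start = end - d
        return cls(start, end)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 21-frame / 60-min protocol."""
        return cls.from_durations(DEFAULT_FRAME_DURATIONS_MIN)

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def duration(self) -> np.ndarray:
        """Per-frame duration, minutes."""
        return self.end - self.start

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def total_min(self) -> float:
        return float(self.end[-1])

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class InputFunction:
    """Arterial plasma activity (metabolite-corrected) on a fine uniform grid."""

    time: np.ndarray  # minutes, uniform, starting at 0
    cp: np.ndarray    # Bq/mL, nonnegative

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        cp = np.asarray(self.cp, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "cp", cp)
        if t.ndim != 1 or t.shape != cp.shape or t.size < 2:
            raise ValueError("time/cp must be equal-length 1D arrays with >= 2 samples")
        if t[0] != 0.0:
            raise ValueError("input-function grid must start at t = 0")
        steps = np.diff(t)
        if not np.allclose(steps, steps[0]):
            raise ValueError("input-function grid must be uniform")
        if np.any(cp < 0):
            raise ValueError("plasma activity must be nonnegative")

    @property
    def step(self) -> float:
        """Grid spacing, minutes."""
        return float(self.time[1] - self.time[0])

    def covers(self, schedule: FrameSchedule) -> bool:
        return self.time[-1] >= schedule.end[-1] - 1e-9


@dataclass
class DynamicImage:
    """A 4D activity series bound to its frame schedule and voxel geometry."""

    frames: np.ndarray               # (x, y, z, t), Bq/mL
    schedule: FrameSchedule
    voxel_size: tuple = (2.0, 2.0, 2.0)  # mm

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be a 4D (x, y, z, t) array")
        if self.frames.shape[-1] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis has {self.frames.shape[-1]} frames but the schedule "
                f"defines {self.schedule.n_frames}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape3(self) -> tuple:
        return self.frames.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[-1]

    def with_frames(self, frames: np.ndarray) -> "DynamicImage":
        """Same geometry/schedule, new voxel data."""
        return DynamicImage(frames, self.schedule, self.voxel_size)

    def copy(self) -> "DynamicImage":
        return self.with_frames(self.frames.copy())


@dataclass
class RegionMap:
    """Integer label volume with names; label 0 is background."""

    labels: np.ndarray                    # 3D int volume
    voxel_size: tuple = (2.0, 2.0, 2.0)   # mm
    region_names: dict = field(default_factory=dict)  # label -> name

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def label_values(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        vals = np.unique(self.labels)
        return vals[vals != 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != 0


@dataclass(frozen=True)
class KineticGroundTruth:
    """Per-region 1T-compartment parameters: K1 (mL·cm⁻³·min⁻¹) and k2 (min⁻¹)."""

    k1: dict  # label -> K1
    k2: dict  # label -> k2

    def __post_init__(self):
        if set(self.k1) != set(self.k2):
            raise ValueError("K1 and k2 must cover the same labels")
        for lab in self.k1:
            if self.k1[lab] < 0:
                raise ValueError(f"K1 must be nonnegative (label {lab})")
            if not (0.01 <= self.k2[lab] <= 1.0):
                raise ValueError(
                    f"k2 must lie in [0.01, 1.0] min^-1 (label {lab}: {self.k2[lab]})"
                )

    def vt(self, label: int) -> float:
        return self.k1[label] / self.k2[label]

    @property
    def labels(self):
        return sorted(self.k1)


@dataclass(frozen=True)
class CountModel:
    """Count statistics of the emulated scan.

    sensitivity — expected counts per (Bq/mL)·min per voxel at full dose;
    dose_fraction — fraction of the full count budget per reduced realization;
    n_realizations — number of reduced-count realizations.
    """

    sensitivity: float
    dose_fraction: float = 0.1
    n_realizations: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if not (0 < self.dose_fraction <= 1):
            raise ValueError("dose_fraction must lie in (0, 1]")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
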