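"""Core domain types for echocardiographic cine-loop analysis.

The pipeline works with short grayscale ultrasound video clips ("cine
loops") acquired from five standard probe positions.  Everything downstream
(indexing of probability vectors, confusion-table axes, tie-breaking)
relies on one canonical ordering of those views, defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "ViewLabel",
    "VIEW_ORDER",
    "CineClip",
    "EchoStudy",
    "CohortSpec",
    "FrameSet",
]


class ViewLabel(str, Enum):
    """The five standard echocardiographic views."""

    PLAX = "PLAX"  # parasternal long axis
    PSAX = "PSAX"  # parasternal short axis
    AP2 = "AP2"    # apical 2-chamber
    AP3 = "AP3"    # apical 3-chamber
    AP4 = "AP4"    # apical 4-chamber

    @property
    def index(self) -> int:
        return VIEW_ORDER.index(self)

    @classmethod
    def from_index(cls, i: int) -> "ViewLabel":
        return VIEW_ORDER[i]


#: Canonical ordering used everywhere an index is needed (probability
#: vectors, confusion tables, argmax tie-breaking).
VIEW_ORDER: tuple[ViewLabel, ...] = (
    ViewLabel.PLAX,
    ViewLabel.PSAX,
    ViewLabel.AP3,
    ViewLabel.AP4,
    ViewLabel.AP2,
)


@dataclass
class CineClip:
    """One grayscale cine loop: T frames of H x W 8-bit pixels.

    Parameters
    ----------
    frames
        ``(T, H, W)`` uint8 array.
    pixel_spacing
        Isotropic pixel size in cm/pixel.
    frame_times
        Acquisition time of each frame in seconds, strictly increasing.
    view
        The acquisition view, if known.
    cycle_period
        Ground-truth cardiac period in frames.  Only the simulator fills
        this in; real data would leave it ``None``.
    """

    frames: np.ndarray
    pixel_spacing: float
    frame_times: np.ndarray
    view: ViewLabel | None = None
    cycle_period: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise ValueError("frame intensities must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if len(self.frame_times) != self.n_frames:
            raise ValueError("frame_times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.cycle_period is not None:
            if not (2 <= self.cycle_period <= self.n_frames):
                raise ValueError("need T >= cycle_period >= 2")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray, pixel_spacing: float | None = None) -> "CineClip":
        """Copy of this clip with new pixel data (and optionally spacing)."""
        return replace(
            self,
            frames=frames,
            pixel_spacing=self.pixel_spacing if pixel_spacing is None else pixel_spacing,
        )


@dataclass
class EchoStudy:
    """One patient: reference LVEF, acquiring vendor and one clip per view."""

    patient_id: str
    lvef: float
    vendor: str
    clips: dict[ViewLabel, CineClip] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.lvef <= 100):
            raise ValueError("lvef must be a percentage in (0, 100]")

    def validate(self) -> None:
        if set(self.clips) != set(VIEW_ORDER):
            raise ValueError(
                f"study {self.patient_id} must hold exactly one clip per view"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Stratified cohort design: LVEF strata with patient counts.

    ``strata`` is a list of ``(lvef_low, lvef_high, n_patients)`` with LVEF
    bounds in percent; strata must not overlap.  ``vendors`` maps vendor
    tags to mixing proportions (normalized internally).
    """

    strata: tuple[tuple[float, float, int], ...]
    vendors: tuple[tuple[str, float], ...] = (("vendorA", 0.5), ("vendorB", 0.5))
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi, n in self.strata:
            if n < 0:
                raise ValueError("stratum size must be >= 0")
            if not lo < hi:
                raise ValueError("stratum bounds must satisfy low < high")
        spans = sorted((lo, hi) for lo, hi, _ in self.strata)
        for (lo1, hi1), (lo2, _hi2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError(f"overlapping strata: ({lo1},{hi1}) and ({lo2},..)")
        if self.vendors and sum(p for _, p in self.vendors) <= 0:
            raise ValueError("vendor proportions must sum to a positive value")

    @property
    def n_patients(self) -> int:
        return sum(n for _, _, n in self.strata)


#: The stratified design of the study cohort: 40 patients at LVEF 10-20%
#: and 50 in each 10-point band from 21-30% up to 71-80% (340 total).
STUDY_STRATA: tuple[tuple[float, float, int], ...] = (
    (10.0, 20.0, 40),
    (21.0, 30.0, 50),
    (31.0, 40.0, 50),
    (41.0, 50.0, 50),
    (51.0, 60.0, 50),
    (61.0, 70.0, 50),
    (71.0, 80.0, 50),
)


@dataclass
class FrameSet:
    """The 10 cycle-normalized 120x120 frames of one clip plus their mean.

    ``averaged`` is the pixel-wise arithmetic mean of ``frames`` rounded
    half-up back to 8-bit.  ``source_indices`` are the original frame
    indices the frames were taken from (strictly increasing, within one
    cardiac cycle).
    """

    frames: np.ndarray
    source_indices: np.ndarray
    averaged: np.ndarray
    clip_id: str = ""
    patient_id: str = ""
    view: ViewLabel | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.source_indices = np.asarray(self.source_indices, dtype=int)
        self.averaged = np.asarray(self.averaged)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (k, H, W)")
        if len(self.source_indices) != self.frames.shape[0]:
            raise ValueError("one source index per frame required")
        if np.any(np.diff(self.source_indices) <= 0):
            raise ValueError("source indices must be strictly increasing")
        if self.averaged.shape != self.frames.shape[1:]:
            raise ValueError("averaged image shape must match the frames")


def mean_uint8(frames: np.ndarray) -> np.ndarray:
    """Pixel-wise mean of a frame stack, rounded half-up to uint8."""
    m = np.asarray(frames, dtype=np.float64).mean(axis=0)
    return np.floor(m + 0.5).astype(np.uint8)
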