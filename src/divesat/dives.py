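"""Dive detection and phase segmentation from 1 Hz time-depth records.

A dive is a maximal interval with depth above a surface threshold (default
2 m, standard time-depth-recorder practice) that lasts strictly longer than
a minimum duration (default 2 min, the study inclusion rule).  Each dive is
segmented into descent / bottom / ascent phases from a smoothed vertical
rate, and vertical direction changes (e.g. mid-dive sub-ice excursions) are
located with a dead-banded sign test on the same rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDiveError,
    FormatError,
    InputDomainError,
)

__all__ = [
    "DepthProfile",
    "Phase",
    "Dive",
    "detect_dives",
    "segment_phases",
    "fraction_of_dive",
    "phase_label_at",
]


@dataclass
class DepthProfile:
    """A depth record: strictly increasing time (s) and depth (m, >= 0 down).

    ``nominal_interval_s`` documents the logger cadence (1 s for the study's
    recorders) and is not enforced sample-by-sample.
    """

    time_s: np.ndarray
    depth_m: np.ndarray
    nominal_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if self.time_s.shape != self.depth_m.shape or self.time_s.ndim != 1:
            raise FormatError("time_s and depth_m must be 1-D arrays of equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise FormatError("depth record time axis must be strictly increasing")
        if np.any(~np.isfinite(self.time_s)) or np.any(~np.isfinite(self.depth_m)):
            raise FormatError("depth record contains non-finite samples")
        if np.any(self.depth_m < 0):
            raise FormatError("negative depth sample (depth is positive below surface)")

    def __len__(self) -> int:
        return self.time_s.size

    @classmethod
    def from_csv(cls, path, nominal_interval_s: float = 1.0) -> "DepthProfile":
        df = pd.read_csv(path)
        missing = {"time_s", "depth_m"} - set(df.columns)
        if missing:
            raise FormatError(f"depth CSV {path} missing columns {sorted(missing)}")
        if df[["time_s", "depth_m"]].isna().any().any():
            raise FormatError(f"depth CSV {path} contains missing values")
        return cls(df["time_s"].to_numpy(), df["depth_m"].to_numpy(), nominal_interval_s)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "depth_m": self.depth_m}).to_csv(
            path, index=False, float_format="%.4f"
        )

    def depth_at(self, t_s) -> np.ndarray:
        """Linearly interpolated depth at arbitrary times."""
        return np.interp(t_s, self.time_s, self.depth_m)

    def window(self, t0: float, t1: float) -> "DepthProfile":
        mask = (self.time_s >= t0) & (self.time_s <= t1)
        return DepthProfile(self.time_s[mask], self.depth_m[mask], self.nominal_interval_s)


@dataclass(frozen=True)
class Phase:
    name: str  # 'descent' | 'bottom' | 'ascent'
    t_start_s: float
    t_end_s: float

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    def contains(self, t_s: float) -> bool:
        return self.t_start_s <= t_s <= self.t_end_s


@dataclass
class Dive:
    """One detected submergence.

    ``phases`` tile ``[start_s, end_s]`` without overlap once
    :func:`segment_phases` has run.  ``direction_changes`` are the times of
    dead-banded sign flips of the smoothed vertical rate (a V-dive has one,
    at its apex; a dive with a mid-dive excursion has three).
    """

    start_s: float
    end_s: float
    max_depth_m: float
    t_max_depth_s: float
    phases: list = field(default_factory=list)
    direction_changes: list = field(default_factory=list)
    dive_id: int = 0
    bird_id: str = ""

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s):
            raise FormatError("dive end must be after dive start")

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0

    def contains(self, t_s: float, slack_s: float = 0.0) -> bool:
        return self.start_s - slack_s <= t_s <= self.end_s + slack_s

    def phase_named(self, name: str):
        for ph in self.phases:
            if ph.name == name:
                return ph
        return None


def detect_dives(
    depth: DepthProfile,
    surface_threshold_m: float = 2.0,
    min_duration_min: float = 2.0,
) -> list:
    """Find maximal intervals with depth > threshold lasting strictly more
    than ``min_duration_min`` minutes.

    Returns time-ordered, non-overlapping dives; an empty profile (or one
    that never leaves the surface) yields an empty list.
    """
    if len(depth) == 0:
        return []
    wet = depth.depth_m > surface_threshold_m
    if not wet.any():
        return []
    # run boundaries of the wet mask
    edges = np.diff(wet.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)  # inclusive last wet index
    if wet[0]:
        starts = np.r_[0, starts]
    if wet[-1]:
        ends = np.r_[ends, wet.size - 1]
    dives = []
    for i0, i1 in zip(starts, ends):
        t0, t1 = depth.time_s[i0], depth.time_s[i1]
        if (t1 - t0) / 60.0 > min_duration_min:
            seg = depth.depth_m[i0 : i1 + 1]
            k = int(np.argmax(seg))
            dives.append(
                Dive(
                    start_s=float(t0),
                    end_s=float(t1),
                    max_depth_m=float(seg[k]),
                    t_max_depth_s=float(depth.time_s[i0 + k]),
                    dive_id=len(dives),
                )
            )
    return dives


def _smoothed_rate(t: np.ndarray, d: np.ndarray, window: int) -> np.ndarray:
    """Smoothed vertical rate (m/s, positive = going deeper): the raw
    gradient averaged over a centered window that shrinks at the edges
    (so the first/last rates stay one-sided, not attenuated)."""
    rate = np.gradient(d, t)
    if window > 1:
        half = window // 2
        c = np.cumsum(np.r_[0.0, rate])
        n = rate.size
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        rate = (c[hi] - c[lo]) / (hi - lo)
    return rate


def segment_phases(
    dive: Dive,
    depth: DepthProfile,
    rate_threshold_m_s: float = 0.2,
    bottom_fraction: float = 0.9,
    smooth_window: int = 5,
    direction_deadband_m_s: float = 0.1,
) -> Dive:
    """Fill ``dive.phases`` and ``dive.direction_changes``.

    Descent is the initial contiguous span whose smoothed downward rate
    stays at or above ``rate_threshold_m_s``; ascent is the final contiguous
    span of sustained upward rate; the remainder is the bottom phase.  The
    three phases tile ``[start, end]`` exactly (empty phases are dropped).
    """
    mask = (depth.time_s >= dive.start_s) & (depth.time_s <= dive.end_s)
    t = depth.time_s[mask]
    d = depth.depth_m[mask]
    if t.size < 3:
        raise DegenerateDiveError(
            f"dive {dive.dive_id} at t={dive.start_s:.0f}s has {t.size} depth samples"
        )
    rate = _smoothed_rate(t, d, smooth_window)

    i = 0
    while i < rate.size and rate[i] >= rate_threshold_m_s:
        i += 1
    desc_end = i - 1  # last index of descent span (may be -1: empty descent)

    j = rate.size - 1
    while j >= 0 and -rate[j] >= rate_threshold_m_s:
        j -= 1
    asc_start = j + 1  # first index of ascent span (may be == size: empty ascent)

    if desc_end >= asc_start:  # spans overlap (e.g. sharp V): split at midpoint
        mid = (desc_end + asc_start) // 2
        desc_end = mid
        asc_start = mid + 1

    b1 = t[desc_end] if desc_end >= 0 else t[0]
    b2 = t[asc_start] if asc_start < t.size else t[-1]
    phases = []
    if b1 > t[0]:
        phases.append(Phase("descent", float(t[0]), float(b1)))
    if b2 > b1:
        phases.append(Phase("bottom", float(b1), float(b2)))
    if t[-1] > b2:
        phases.append(Phase("ascent", float(b2), float(t[-1])))
    if not phases:  # pathological flat dive: call it all bottom
        phases = [Phase("bottom", float(t[0]), float(t[-1]))]

    changes = []
    state = 0
    for k in range(rate.size):
        r = rate[k]
        if state == 0:
            if abs(r) > direction_deadband_m_s:
                state = 1 if r > 0 else -1
        elif state == 1 and r < -direction_deadband_m_s:
            state = -1
            changes.append(float(t[k]))
        elif state == -1 and r > direction_deadband_m_s:
            state = 1
            changes.append(float(t[k]))

    return replace(dive, phases=phases, direction_changes=changes)


def fraction_of_dive(t_s: float, dive: Dive) -> float:
    """Elapsed fraction of the dive at time ``t_s`` (0 at start, 1 at end)."""
    if not dive.contains(t_s, slack_s=1e-9):
        raise InputDomainError(
            f"t={t_s}s outside dive [{dive.start_s}, {dive.end_s}]s"
        )
    return float(np.clip((t_s - dive.start_s) / (dive.end_s - dive.start_s), 0.0, 1.0))


def phase_label_at(
    t_s: float,
    dive: Dive,
    depth: DepthProfile | None = None,
    bottom_fraction: float = 0.9,
) -> str:
    """Label a time as 'max_depth', 'descent' or 'ascent'.

    The near-maximum-depth region (depth >= ``bottom_fraction`` * max depth)
    takes precedence; otherwise the segmented phase applies, and a
    bottom-phase time away from maximum depth (e.g. during a sub-ice
    excursion) falls back to descent/ascent by its position relative to the
    time of maximum depth.
    """
    if depth is not None and len(depth):
        if depth.depth_at(t_s) >= bottom_fraction * dive.max_depth_m:
            return "max_depth"
    for ph in dive.phases:
        if ph.contains(t_s) and ph.name in ("descent", "ascent"):
            return ph.name
    return "descent" if t_s <= dive.t_max_depth_s else "ascent"
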