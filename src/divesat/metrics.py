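"""Per-dive hemoglobin-saturation metrics from sparse blood-gas profiles.

Blood-gas loggers sampled at 5 or 15 s while depth was logged at 1 s, so
saturation samples rarely fall exactly on a dive boundary or on a given
decline landmark; following the study convention, the *nearest* sample is
used in every such case.

For each dive the module reports the five saturation values (start-of-dive,
mean, peak, end-of-dive, and the start-to-peak increase), the times and
dive fractions of the peak and of fixed desaturation landmarks (2.5, 5 and
10 percentage points below peak), and interruptions of the desaturation
profile, classified as positive inflections (rise > 4 pp from a local
minimum to the next local maximum) or plateaus (near-flat runs with a net
change in (-1, +4] pp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dives import DepthProfile, Dive, fraction_of_dive, phase_label_at
from .errors import EmptyProfileError, FormatError, InsufficientDataError
from .odc import ODCParams, DEFAULT_ODC, saturation_from_po2

__all__ = [
    "PO2Profile",
    "SaturationProfile",
    "Landmark",
    "Interruption",
    "DiveOxygenMetrics",
    "saturation_profile_from_po2",
    "align_to_dive",
    "compute_metrics",
    "detect_interruptions",
]

_SITES = ("arterial", "venous")


def _validate_series(time_s, values, lo, hi, what):
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise FormatError(f"{what}: time and value arrays must be 1-D and equal length")
    if t.size and np.any(np.diff(t) <= 0):
        raise FormatError(f"{what}: time axis must be strictly increasing")
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
        raise FormatError(f"{what}: non-finite samples")
    if np.any((v < lo) | (v > hi)):
        bad = v[(v < lo) | (v > hi)].flat[0]
        raise FormatError(f"{what}: value {bad!r} outside [{lo}, {hi}]")
    return t, v


@dataclass
class PO2Profile:
    """Sparse intravascular P_O2 record (mmHg) with site metadata."""

    site: str
    time_s: np.ndarray
    po2_mmHg: np.ndarray
    nominal_interval_s: float = 15.0
    bird_id: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if self.site not in _SITES:
            raise FormatError(f"site must be one of {_SITES}, got {self.site!r}")
        self.time_s, self.po2_mmHg = _validate_series(
            self.time_s, self.po2_mmHg, 0.0, np.inf, "P_O2 profile"
        )

    def __len__(self) -> int:
        return self.time_s.size

    @classmethod
    def from_csv(cls, path, site, nominal_interval_s=15.0, bird_id="", year=None):
        df = pd.read_csv(path)
        missing = {"time_s", "po2_mmHg"} - set(df.columns)
        if missing:
            raise FormatError(f"P_O2 CSV {path} missing columns {sorted(missing)}")
        if df[["time_s", "po2_mmHg"]].isna().any().any():
            raise FormatError(f"P_O2 CSV {path} contains missing values")
        return cls(
            site,
            df["time_s"].to_numpy(),
            df["po2_mmHg"].to_numpy(),
            nominal_interval_s,
            bird_id,
            year,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "po2_mmHg": self.po2_mmHg}).to_csv(
            path, index=False, float_format="%.4f"
        )


@dataclass
class SaturationProfile:
    """Sparse Hb-saturation record (percent) with site metadata."""

    site: str
    time_s: np.ndarray
    sat_percent: np.ndarray
    nominal_interval_s: float = 15.0
    bird_id: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if self.site not in _SITES:
            raise FormatError(f"site must be one of {_SITES}, got {self.site!r}")
        self.time_s, self.sat_percent = _validate_series(
            self.time_s, self.sat_percent, 0.0, 100.0, "saturation profile"
        )

    def __len__(self) -> int:
        return self.time_s.size


def saturation_profile_from_po2(
    po2: PO2Profile, odc: ODCParams = DEFAULT_ODC
) -> SaturationProfile:
    """Convert a P_O2 profile to a saturation profile through the Hill curve."""
    return SaturationProfile(
        site=po2.site,
        time_s=po2.time_s.copy(),
        sat_percent=saturation_from_po2(po2.po2_mmHg, odc),
        nominal_interval_s=po2.nominal_interval_s,
        bird_id=po2.bird_id,
        year=po2.year,
    )


def align_to_dive(profile: SaturationProfile, dive: Dive) -> SaturationProfile:
    """Crop a saturation profile to one dive.

    Samples within half a sampling interval of the dive boundaries are kept
    so that the nearest-sample rule can select a boundary value recorded
    just outside the dive.
    """
    half = profile.nominal_interval_s / 2.0
    mask = (profile.time_s >= dive.start_s - half) & (profile.time_s <= dive.end_s + half)
    if not mask.any():
        raise EmptyProfileError(
            f"no {profile.site} saturation samples overlap dive {dive.dive_id} "
            f"[{dive.start_s:.0f}, {dive.end_s:.0f}]s"
        )
    return SaturationProfile(
        site=profile.site,
        time_s=profile.time_s[mask],
        sat_percent=profile.sat_percent[mask],
        nominal_interval_s=profile.nominal_interval_s,
        bird_id=profile.bird_id,
        year=profile.year,
    )


@dataclass(frozen=True)
class Landmark:
    """Nearest sample to a fixed decline below peak saturation."""

    decline_pp: float
    sat_percent: float
    t_min: float  # minutes after dive start
    fraction: float  # fraction of dive duration


@dataclass(frozen=True)
class Interruption:
    """One interruption of a desaturation profile.

    ``kind`` is 'inflection' (rise > 4 pp, onset at the local minimum,
    ``time_to_peak_s`` to the following local maximum) or 'plateau'
    (near-flat run, ``duration_s`` long, net change ``magnitude_pp``).
    """

    kind: str
    t_onset_s: float
    magnitude_pp: float
    time_to_peak_s: float | None = None
    duration_s: float | None = None
    phase_label: str | None = None


@dataclass
class DiveOxygenMetrics:
    start_sat: float
    peak_sat: float
    end_sat: float
    mean_sat: float
    increase_start_to_peak: float
    net_peak_to_end_decrease: float
    t_peak_min: float
    frac_peak: float
    landmarks: dict = field(default_factory=dict)  # decline_pp -> Landmark
    interruptions: list = field(default_factory=list)


def _clipped_fraction(t_s: float, dive: Dive) -> float:
    return fraction_of_dive(
        float(np.clip(t_s, dive.start_s, dive.end_s)), dive
    )


def compute_metrics(
    profile: SaturationProfile,
    dive: Dive,
    landmark_declines=(2.5, 5.0, 10.0),
) -> DiveOxygenMetrics:
    """Compute the per-dive saturation metrics from an aligned profile.

    Start and end values are the samples nearest the dive boundaries, the
    peak is the maximum over the dive (earliest sample on ties), and the
    mean is the unweighted mean of the aligned samples (sampling is uniform
    at the logger cadence).  A landmark for decline ``d`` is the sample
    nearest ``peak - d`` at the first crossing after the peak, and is absent
    when saturation never falls that far.
    """
    t = profile.time_s
    s = profile.sat_percent
    if t.size < 3:
        raise InsufficientDataError(
            f"dive {dive.dive_id}: {t.size} saturation samples, need >= 3"
        )
    i_start = int(np.argmin(np.abs(t - dive.start_s)))
    i_end = int(np.argmin(np.abs(t - dive.end_s)))
    i_peak = int(np.argmax(s))  # argmax returns the earliest maximum

    start_sat = float(s[i_start])
    end_sat = float(s[i_end])
    peak_sat = float(s[i_peak])
    mean_sat = float(np.mean(s))

    landmarks = {}
    for d in landmark_declines:
        target = peak_sat - d
        after = np.flatnonzero(s[i_peak + 1 :] <= target)
        if after.size == 0:
            continue  # never declined that far: landmark absent
        j = i_peak + 1 + int(after[0])  # first crossing
        cand = [j]
        if j - 1 > i_peak:
            cand.append(j - 1)
        k = min(cand, key=lambda idx: (abs(s[idx] - target), idx != j))
        landmarks[float(d)] = Landmark(
            decline_pp=float(d),
            sat_percent=float(s[k]),
            t_min=max(0.0, (float(t[k]) - dive.start_s) / 60.0),
            fraction=_clipped_fraction(float(t[k]), dive),
        )

    return DiveOxygenMetrics(
        start_sat=start_sat,
        peak_sat=peak_sat,
        end_sat=end_sat,
        mean_sat=mean_sat,
        increase_start_to_peak=peak_sat - start_sat,
        net_peak_to_end_decrease=peak_sat - end_sat,
        t_peak_min=max(0.0, (float(t[i_peak]) - dive.start_s) / 60.0),
        frac_peak=_clipped_fraction(float(t[i_peak]), dive),
        landmarks=landmarks,
    )


def _local_extrema(s: np.ndarray):
    """Indices of alternating local minima and maxima of a sampled series.

    Flat stretches are collapsed to their first sample.  Returns a list of
    (index, kind) with kind in {-1: minimum, +1: maximum}, in time order.
    """
    n = s.size
    if n < 2:
        return []
    sign = np.sign(np.diff(s))
    # carry the previous non-zero slope through flats
    last = 0.0
    slopes = np.empty_like(sign)
    for i, g in enumerate(sign):
        if g != 0:
            last = g
        slopes[i] = last
    ext = []
    if (first := np.flatnonzero(sign != 0)).size == 0:
        return []
    f = first[0]
    ext.append((0, -1 if sign[f] > 0 else +1))
    for i in range(1, n - 1):
        a, b = slopes[i - 1], sign[i]
        if b == 0 or a == 0:
            continue
        if a < 0 and b > 0:
            ext.append((i, -1))
        elif a > 0 and b < 0:
            ext.append((i, +1))
    ext.append((n - 1, +1 if slopes[-1] > 0 else -1))
    return ext


def detect_interruptions(
    profile: SaturationProfile,
    dive: Dive,
    depth: DepthProfile | None = None,
    inflection_threshold_pp: float = 4.0,
    plateau_min_duration_s: float = 30.0,
    plateau_net_change_pp=(-1.0, 4.0),
    plateau_max_step_drop_pp: float = 1.0,
    bottom_fraction: float = 0.9,
) -> list:
    """Find desaturation interruptions in an aligned profile.

    Inflections are rises strictly greater than ``inflection_threshold_pp``
    from a local minimum to the next local maximum (a rise of exactly 4.0 pp
    is *not* an inflection).  Plateaus are maximal runs at least
    ``plateau_min_duration_s`` long whose net change lies in
    ``plateau_net_change_pp`` and that contain no sample-to-sample drop
    larger than ``plateau_max_step_drop_pp``; runs overlapping an inflection
    are not re-reported.  Each interruption is labelled with the dive phase
    of its onset; the near-maximum-depth label takes precedence.
    """
    t = profile.time_s
    s = profile.sat_percent
    out = []
    covered = np.zeros(t.size, dtype=bool)

    ext = _local_extrema(s)
    for (i, ki), (j, kj) in zip(ext, ext[1:]):
        if ki == -1 and kj == +1:
            rise = s[j] - s[i]
            if rise > inflection_threshold_pp:
                out.append(
                    Interruption(
                        kind="inflection",
                        t_onset_s=float(t[i]),
                        magnitude_pp=float(rise),
                        time_to_peak_s=float(t[j] - t[i]),
                        phase_label=phase_label_at(float(t[i]), dive, depth, bottom_fraction),
                    )
                )
                covered[i : j + 1] = True

    lo, hi = plateau_net_change_pp
    i = 0
    n = t.size
    while i < n - 1:
        if covered[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and not covered[j + 1]
            and s[j + 1] - s[j] >= -plateau_max_step_drop_pp
            and lo < s[j + 1] - s[i] <= hi
        ):
            j += 1
        if j > i and t[j] - t[i] >= plateau_min_duration_s:
            out.append(
                Interruption(
                    kind="plateau",
                    t_onset_s=float(t[i]),
                    magnitude_pp=float(s[j] - s[i]),
                    duration_s=float(t[j] - t[i]),
                    phase_label=phase_label_at(float(t[i]), dive, depth, bottom_fraction),
                )
            )
            i = j + 1
        else:
            i += 1

    out.sort(key=lambda itr: itr.t_onset_s)
    return out
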