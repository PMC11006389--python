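"""Rule-based typing of venous Hb-saturation dive profiles.

Venous profiles fall into two physiological patterns: Type A (saturation
increases and/or plateaus for most of the dive, often arterialized by
arterio-venous shunting, declining only in the late ascent) and Type B
(progressive desaturation from an early peak, reflecting sustained tissue
O2 extraction).  Profiles matching neither pattern are 'Other'.

The deciding quantity is the *sustained-decline onset*: the earliest sample
after which saturation never again rises to within 10 pp of the running
peak.  A dive with no such onset never really commits to desaturating;
a dive whose onset falls late (fraction >= 0.5) and inside the final ascent
declines "only during the latter stages of ascent".  The visual criteria of
the original analysis are formalized as a deterministic rule cascade, with
the fired rule recorded for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dives import Dive, fraction_of_dive
from .errors import SiteMismatchError
from .metrics import DiveOxygenMetrics, SaturationProfile

__all__ = [
    "ClassifierParams",
    "ProfileClass",
    "sustained_decline_onset",
    "classify",
    "classify_dataset",
]

LABELS = ("TypeA", "TypeB", "Other")


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the rule cascade.

    arterialized_floor_pct
        Minimum saturation above which a dive is Type A outright (the
        "never below 90%" criterion).
    sustained_decline_pp
        Drop below the running peak that defines the sustained-decline
        onset (10 pp, mirroring the ~10% landmark convention).
    late_onset_fraction
        Dive fraction at or beyond which an in-ascent onset still counts as
        a late, Type A decline.
    min_terminal_decline_pp
        Smallest net peak-to-end decrease that lets a no-onset profile count
        as Type A ("declined only late"); profiles flatter than this and
        below the arterialized floor fit neither pattern and fall to Other.
    """

    arterialized_floor_pct: float = 90.0
    sustained_decline_pp: float = 10.0
    late_onset_fraction: float = 0.5
    min_terminal_decline_pp: float = 2.0


DEFAULT_CLASSIFIER = ClassifierParams()


@dataclass(frozen=True)
class ProfileClass:
    label: str  # 'TypeA' | 'TypeB' | 'Other'
    fired_rule: str
    onset_s: float | None = None
    onset_fraction: float | None = None


def sustained_decline_onset(
    profile: SaturationProfile,
    dive: Dive,
    drop_pp: float = 10.0,
):
    """Earliest sample after which saturation never again rises above
    (running peak - ``drop_pp``).

    Returns ``(t_onset_s, fraction)`` or ``None`` when the profile never
    commits to a sustained decline (including profiles that only reach the
    condition at their very last sample, which leave no "after").
    """
    s = profile.sat_percent
    t = profile.time_s
    n = s.size
    if n < 2:
        return None
    running_peak = np.maximum.accumulate(s)
    # suffix_max[i] = max of s[i+1:]
    suffix = np.maximum.accumulate(s[::-1])[::-1]
    suffix_max = np.r_[suffix[1:], -np.inf]
    ok = np.flatnonzero(suffix_max[:-1] < running_peak[:-1] - drop_pp)
    if ok.size == 0:
        return None
    i = int(ok[0])
    t_onset = float(t[i])
    frac = fraction_of_dive(float(np.clip(t_onset, dive.start_s, dive.end_s)), dive)
    return t_onset, frac


def _in_final_ascent(t_s: float, dive: Dive) -> bool:
    ph = dive.phase_named("ascent")
    return ph is not None and ph.contains(t_s)


def classify(
    metrics: DiveOxygenMetrics,
    profile: SaturationProfile,
    dive: Dive,
    params: ClassifierParams = DEFAULT_CLASSIFIER,
) -> ProfileClass:
    """Assign one venous dive profile to Type A, Type B or Other.

    Rule cascade (first match wins):

    1. minimum saturation >= ``arterialized_floor_pct``      -> Type A
    2. no sustained-decline onset:
       net peak-to-end decrease >= ``min_terminal_decline_pp`` -> Type A
       (a discernible but small/late decline), otherwise       -> Other
    3. onset at fraction >= ``late_onset_fraction`` and inside the final
       ascent                                                -> Type A
    4. otherwise (onset exists, early or outside ascent)     -> Type B
    """
    if profile.site != "venous":
        raise SiteMismatchError(
            f"classifier applies to venous profiles, got site={profile.site!r}"
        )
    if float(np.min(profile.sat_percent)) >= params.arterialized_floor_pct:
        return ProfileClass("TypeA", "A_never_below_90")

    onset = sustained_decline_onset(profile, dive, params.sustained_decline_pp)
    if onset is None:
        if metrics.net_peak_to_end_decrease >= params.min_terminal_decline_pp:
            return ProfileClass("TypeA", "A_late_decline_only")
        return ProfileClass("Other", "other_unmatched")

    t_onset, frac = onset
    # the true onset lies between this sample and the next; locate the
    # late/in-ascent tests at the half-interval midpoint so coarse blood-gas
    # sampling cannot push a late-ascent decline just outside the ascent
    t_eval = min(t_onset + profile.nominal_interval_s / 2.0, dive.end_s)
    frac_eval = fraction_of_dive(float(np.clip(t_eval, dive.start_s, dive.end_s)), dive)
    if frac_eval >= params.late_onset_fraction and _in_final_ascent(t_eval, dive):
        return ProfileClass("TypeA", "A_late_decline_only", t_onset, frac)
    return ProfileClass("TypeB", "B_progressive_decline", t_onset, frac)


def classify_dataset(records, params: ClassifierParams = DEFAULT_CLASSIFIER):
    """Classify a list of ``(metrics, profile, dive)`` triples.

    Returns ``(counts, table)``: per-label counts summing to the input size
    and a per-dive DataFrame with the fired rule for audit.  An empty input
    yields all-zero counts.
    """
    rows = []
    counts = {label: 0 for label in LABELS}
    for metrics, profile, dive in records:
        pc = classify(metrics, profile, dive, params)
        counts[pc.label] += 1
        rows.append(
            {
                "bird_id": profile.bird_id,
                "dive_id": dive.dive_id,
                "label": pc.label,
                "fired_rule": pc.fired_rule,
                "onset_s": pc.onset_s,
                "onset_fraction": pc.onset_fraction,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["bird_id", "dive_id", "label", "fired_rule", "onset_s", "onset_fraction"],
    )
    return counts, table
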