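"""End-to-end orchestration: segment -> convert -> metrics -> classify -> summarize.

The pipeline consumes records of paired depth and P_O2 logs (one bird and
logger deployment per record; a record may contain several dives), applies
the dive-inclusion filter, converts P_O2 to Hb saturation through the
dissociation curve, computes per-dive metrics and desaturation
interruptions, types venous profiles, and aggregates a per-group summary
table (mean +/- s.e.m. and median of the dive and saturation variables,
plus counts of dives at or beyond the aerobic dive limit).

Also provided: the fixed-arterial arterio-venous Hb-bound O2 difference
series over the early dive, and a tidy long-format export for external
mixed-model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierParams, classify
from .dives import DepthProfile, Dive, detect_dives, segment_phases
from .errors import EmptyProfileError, InputDomainError, ZeroDivesError
from .metrics import (
    PO2Profile,
    SaturationProfile,
    align_to_dive,
    compute_metrics,
    detect_interruptions,
    saturation_profile_from_po2,
)
from .odc import BloodParams, DEFAULT_BLOOD, DEFAULT_ODC, ODCParams, av_o2_difference

__all__ = [
    "RunConfig",
    "RecordInput",
    "PipelineResult",
    "run_pipeline",
    "summarize_groups",
    "av_difference_series",
    "export_stats_table",
]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds and physical parameters in one place."""

    odc: ODCParams = DEFAULT_ODC
    blood: BloodParams = DEFAULT_BLOOD
    surface_threshold_m: float = 2.0
    min_duration_min: float = 2.0
    rate_threshold_m_s: float = 0.2
    bottom_fraction: float = 0.9
    inflection_threshold_pp: float = 4.0
    plateau_min_duration_s: float = 30.0
    landmark_declines: tuple = (2.5, 5.0, 10.0)
    classifier: ClassifierParams = ClassifierParams()
    adl_min: float = 5.6

    def __post_init__(self) -> None:
        if self.surface_threshold_m < 0:
            raise InputDomainError("surface_threshold_m must be non-negative")
        if self.min_duration_min < 0 or self.adl_min <= 0:
            raise InputDomainError("durations must be non-negative")
        if not (0 < self.bottom_fraction <= 1):
            raise InputDomainError("bottom_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "odc" in raw:
            kwargs["odc"] = ODCParams(**raw.pop("odc"))
        if "blood" in raw:
            kwargs["blood"] = BloodParams(**raw.pop("blood"))
        if "classifier" in raw:
            kwargs["classifier"] = ClassifierParams(**raw.pop("classifier"))
        if "landmark_declines" in raw:
            raw["landmark_declines"] = tuple(raw["landmark_declines"])
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class RecordInput:
    """One logger deployment: a depth trace with its blood-gas trace."""

    record_id: int
    depth: DepthProfile
    po2: PO2Profile
    bird_id: str = ""
    year: int | None = None

    @property
    def site(self) -> str:
        return self.po2.site


@dataclass
class PipelineResult:
    per_dive: pd.DataFrame
    interruptions: pd.DataFrame
    summary: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_dive.to_csv(out / "per_dive.csv", index=False, float_format="%.4f")
        self.interruptions.to_csv(
            out / "interruptions.csv", index=False, float_format="%.4f"
        )
        self.summary.to_csv(out / "group_summary.csv", index=False, float_format="%.4f")


_SUMMARY_VARS = (
    "duration_min",
    "max_depth_m",
    "start_sat",
    "peak_sat",
    "end_sat",
    "mean_sat",
    "increase_start_to_peak",
    "net_peak_to_end_decrease",
    "t_peak_min",
    "frac_peak",
)


def run_pipeline(records, config: RunConfig = RunConfig()) -> PipelineResult:
    """Run every stage on a list of :class:`RecordInput`.

    Only dives passing the duration filter enter the tables; venous dives
    are typed, arterial dives form their own group.  Raises
    :class:`ZeroDivesError` when nothing survives the filter.
    """
    dive_rows, intr_rows = [], []
    for rec in records:
        sat_full = saturation_profile_from_po2(rec.po2, config.odc)
        dives = detect_dives(rec.depth, config.surface_threshold_m, config.min_duration_min)
        for dive in dives:
            dive = segment_phases(
                dive, rec.depth, config.rate_threshold_m_s, config.bottom_fraction
            )
            try:
                prof = align_to_dive(sat_full, dive)
            except EmptyProfileError:
                continue  # logger gap over this dive
            if len(prof) < 3:
                continue
            metrics = compute_metrics(prof, dive, config.landmark_declines)
            interruptions = detect_interruptions(
                prof,
                dive,
                rec.depth,
                config.inflection_threshold_pp,
                config.plateau_min_duration_s,
                bottom_fraction=config.bottom_fraction,
            )
            metrics.interruptions = interruptions

            if rec.site == "venous":
                pc = classify(metrics, prof, dive, config.classifier)
                group, fired = pc.label, pc.fired_rule
                onset_s, onset_frac = pc.onset_s, pc.onset_fraction
            else:
                group, fired = "arterial", ""
                onset_s, onset_frac = None, None

            row = {
                "record_id": rec.record_id,
                "bird_id": rec.bird_id or rec.po2.bird_id,
                "year": rec.year if rec.year is not None else rec.po2.year,
                "site": rec.site,
                "dive_id": dive.dive_id,
                "start_s": dive.start_s,
                "end_s": dive.end_s,
                "duration_min": dive.duration_min,
                "max_depth_m": dive.max_depth_m,
                "t_max_depth_s": dive.t_max_depth_s,
                "start_sat": metrics.start_sat,
                "peak_sat": metrics.peak_sat,
                "end_sat": metrics.end_sat,
                "mean_sat": metrics.mean_sat,
                "increase_start_to_peak": metrics.increase_start_to_peak,
                "net_peak_to_end_decrease": metrics.net_peak_to_end_decrease,
                "t_peak_min": metrics.t_peak_min,
                "frac_peak": metrics.frac_peak,
                "n_interruptions": len(interruptions),
                "group": group,
                "fired_rule": fired,
                "onset_s": onset_s,
                "onset_fraction": onset_frac,
            }
            for d, lm in metrics.landmarks.items():
                key = f"lm{d:g}"
                row[f"{key}_sat"] = lm.sat_percent
                row[f"{key}_t_min"] = lm.t_min
                row[f"{key}_frac"] = lm.fraction
            dive_rows.append(row)

            for it in interruptions:
                intr_rows.append(
                    {
                        "record_id": rec.record_id,
                        "bird_id": rec.bird_id or rec.po2.bird_id,
                        "dive_id": dive.dive_id,
                        "group": group,
                        "kind": it.kind,
                        "t_onset_s": it.t_onset_s,
                        "magnitude_pp": it.magnitude_pp,
                        "time_to_peak_s": it.time_to_peak_s,
                        "duration_s": it.duration_s,
                        "phase_label": it.phase_label,
                    }
                )

    if not dive_rows:
        raise ZeroDivesError("no dive passed the inclusion filter")

    per_dive = pd.DataFrame(dive_rows)
    interruptions = pd.DataFrame(
        intr_rows,
        columns=[
            "record_id", "bird_id", "dive_id", "group", "kind", "t_onset_s",
            "magnitude_pp", "time_to_peak_s", "duration_s", "phase_label",
        ],
    )
    summary = summarize_groups(per_dive, adl_min=config.adl_min)
    return PipelineResult(per_dive=per_dive, interruptions=interruptions, summary=summary)


def summarize_groups(per_dive: pd.DataFrame, adl_min: float = 5.6) -> pd.DataFrame:
    """Group summary (Table-1 style): n, mean, s.e.m., median per variable,
    and the count of dives at or beyond the aerobic dive limit.

    'Other' dives are excluded, as in the study.  Summaries are unweighted
    across dives (not per-bird means).
    """
    rows = []
    for group in ("arterial", "TypeA", "TypeB"):
        sub = per_dive[per_dive["group"] == group]
        row = {"group": group, "n_dives": int(len(sub))}
        for var in _SUMMARY_VARS:
            if len(sub):
                x = sub[var].to_numpy(dtype=float)
                row[f"{var}_mean"] = float(np.mean(x))
                row[f"{var}_sem"] = (
                    float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
                )
                row[f"{var}_median"] = float(np.median(x))
            else:
                row[f"{var}_mean"] = row[f"{var}_sem"] = row[f"{var}_median"] = np.nan
        row["n_dives_ge_adl"] = int((sub["duration_min"] >= adl_min).sum()) if len(sub) else 0
        rows.append(row)
    return pd.DataFrame(rows)


def av_difference_series(
    art_sat_percent: float,
    ven_profile: SaturationProfile,
    blood: BloodParams = DEFAULT_BLOOD,
    dive: Dive | None = None,
    window_s: float = 120.0,
) -> pd.DataFrame:
    """Arterio-venous Hb-bound O2 difference over the early dive.

    Uses a fixed assumed arterial saturation (95% in the study's figure)
    against the venous samples within ``window_s`` of the dive start
    (default: the first 2 minutes).  Negative values mean arterialized
    venous blood and are reported as-is.
    """
    t0 = dive.start_s if dive is not None else float(ven_profile.time_s[0])
    mask = (ven_profile.time_s >= t0) & (ven_profile.time_s <= t0 + window_s)
    if not mask.any():
        raise EmptyProfileError(
            f"no venous samples in the first {window_s:.0f}s window from t={t0:.0f}s"
        )
    t = ven_profile.time_s[mask]
    ven = ven_profile.sat_percent[mask]
    diff = av_o2_difference(art_sat_percent, ven, blood)
    return pd.DataFrame(
        {"time_s": t, "ven_sat_percent": ven, "av_o2_ml_dl": diff}
    )


def export_stats_table(per_dive: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format table for external mixed-effects modelling.

    One row per dive, no rows dropped; natural-log companions are added for
    duration, depth and the start-to-peak increase (NaN where the value is
    not positive, rather than silently removing the row).
    """
    cols = [
        "bird_id", "year", "record_id", "dive_id", "group", "site",
        "duration_min", "max_depth_m",
        "start_sat", "peak_sat", "end_sat", "mean_sat",
        "increase_start_to_peak", "net_peak_to_end_decrease",
        "t_peak_min", "frac_peak",
    ]
    out = per_dive[cols].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for src, dst in (
            ("duration_min", "log_duration_min"),
            ("max_depth_m", "log_max_depth_m"),
            ("increase_start_to_peak", "log_increase_start_to_peak"),
        ):
            x = out[src].to_numpy(dtype=float)
            out[dst] = np.where(x > 0, np.log(np.where(x > 0, x, np.nan)), np.nan)
    return out
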