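"""Synthetic dive-profile generator with ground-truth labels.

Emits labelled depth (1 Hz) and intravascular P_O2 (5 or 15 s) records
whose population statistics are calibrated to the study groups:

* **arterial** - saturation rises ~2.5 pp over the first minute to a peak
  above 99%, stays at 95-100% through most of the dive, then falls through
  fixed late-dive landmarks (96.6% at 0.70, 94.5% at 0.77, 89.2% at 0.85 of
  dive time) to a mean end-of-dive value of 77.9%.
* **venousA** - saturation rises ~11.4 pp to a ~94.1% peak by ~0.4 of dive
  time, plateaus, and declines only late; in ~45% of dives the decline stays
  under 10 pp (population mean end-of-dive 74.5%).
* **venousB** - saturation rises ~1.8 pp to a ~79.1% early peak, falls ~10.8
  pp by ~0.18 of dive time and declines progressively to ~31.1% at the end,
  interrupted 1-3 times by transient re-saturation inflections (dip-and-
  recover events, rise > 4 pp) or near-flat plateaus (~107 s).

Durations and maximum depths are log-normal per group (Type B dives longer
and deeper), truncated at the 2-min inclusion floor.  Saturation
trajectories are piecewise-linear in time; interruptions use smooth cosine
legs.  P_O2 is the exact Hill-curve inverse of the trajectory plus additive
Gaussian noise (default sd 1 mmHg), sampled at the logger cadence, so the
full pipeline applied to noise-free output reproduces the planted truth.

Reproducibility: each record draws from a substream seeded by
``(seed, record index)``, so a record is byte-identical whether generated
alone or within a dataset, in any order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dives import DepthProfile
from .errors import GeneratorError, InputDomainError
from .metrics import Interruption, PO2Profile
from .odc import DEFAULT_ODC, ODCParams, po2_from_saturation

__all__ = [
    "DiveShapeParams",
    "TypeATrajectory",
    "TypeBTrajectory",
    "ArterialTrajectory",
    "GeneratorConfig",
    "SyntheticRecord",
    "generate_dive",
    "generate_record",
    "generate_dataset",
    "write_dataset",
]

GROUPS = ("arterial", "venousA", "venousB")


# --------------------------------------------------------------------------
# parameter blocks (defaults are the study's printed group statistics)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DiveShapeParams:
    """Log-normal duration/depth draws plus trapezoidal dive geometry."""

    dur_median_min: float
    dur_sigma: float
    dur_min_min: float
    dur_max_min: float
    depth_median_m: float
    depth_sigma: float
    depth_min_m: float
    depth_max_m: float
    descent_rate_lo: float = 0.8
    descent_rate_hi: float = 1.3
    ascent_rate_lo: float = 0.3
    ascent_rate_hi: float = 0.7
    excursion_prob: float = 0.35
    max_vertical_time_frac: float = 0.6


@dataclass(frozen=True)
class TypeATrajectory:
    peak_mean: float = 94.1
    peak_sd: float = 3.0
    peak_lo: float = 86.0
    peak_hi: float = 99.5
    increase_mean: float = 11.4
    increase_sd: float = 3.5
    increase_lo: float = 2.0
    increase_hi: float = 25.0
    frac_peak_mean: float = 0.40
    frac_peak_sd: float = 0.10
    frac_peak_lo: float = 0.15
    frac_peak_hi: float = 0.50
    # 45% of dives decline < 10 pp from peak; the rest decline ~31 pp so the
    # population mean net decrease is 19.6 pp (end-of-dive mean 74.5%)
    p_small_decline: float = 0.45
    small_decline_lo: float = 2.0
    small_decline_hi: float = 9.5
    big_decline_mean: float = 30.9
    big_decline_sd: float = 8.0
    big_decline_lo: float = 10.5


@dataclass(frozen=True)
class TypeBTrajectory:
    peak_mean: float = 79.1
    peak_sd: float = 6.0
    peak_lo: float = 55.0
    peak_hi: float = 95.0
    increase_mean: float = 1.8
    increase_sd: float = 1.2
    increase_lo: float = 0.0
    increase_hi: float = 3.9
    frac_peak_lo: float = 0.01
    frac_peak_hi: float = 0.08
    end_mean: float = 31.1
    end_sd: float = 12.0
    end_lo: float = 2.0
    min_net_decrease: float = 12.0  # every Type B dive declines >= 10 pp
    mid_frac_mean: float = 0.18
    mid_frac_sd: float = 0.05
    mid_frac_lo: float = 0.08
    mid_frac_hi: float = 0.32
    mid_drop_pp: float = 10.8  # saturation ~peak-10.8 at the mid landmark
    # interruptions of the desaturation profile
    p_any_interruption: float = 64.0 / 65.0
    count_probs: tuple = (0.538, 0.323, 0.123)  # 1, 2, 3 given any
    p_inflection: float = 0.816
    inflection_mag_mean: float = 15.1
    inflection_mag_sd: float = 9.9
    inflection_mag_lo: float = 8.0
    inflection_mag_hi: float = 46.8
    inflection_ttp_mean: float = 82.0
    inflection_ttp_sd: float = 50.0
    inflection_ttp_lo: float = 45.0
    inflection_ttp_hi: float = 160.0
    inflection_fall_lo: float = 30.0
    inflection_fall_hi: float = 120.0
    plateau_dur_mean: float = 107.0
    plateau_dur_sd: float = 56.0
    plateau_dur_lo: float = 70.0
    plateau_dur_hi: float = 240.0
    plateau_rise_mean: float = 2.4
    plateau_rise_sd: float = 1.5
    plateau_rise_lo: float = 0.0
    plateau_rise_hi: float = 3.9
    plateau_rejoin_s: float = 40.0
    placement_probs: tuple = (0.484, 0.281, 0.235)  # descent, ascent, max_depth
    # an interruption extending past this dive fraction must stay well below
    # the dive's peak so the late profile cannot mimic a Type A late decline
    late_cap_frac: float = 0.45
    late_cap_below_peak_pp: float = 11.0


@dataclass(frozen=True)
class ArterialTrajectory:
    peak_mean: float = 99.4
    peak_sd: float = 0.3
    peak_lo: float = 98.2
    peak_hi: float = 99.8
    increase_mean: float = 2.5
    increase_sd: float = 0.8
    increase_lo: float = 0.5
    increase_hi: float = 3.9
    rise_time_s: float = 60.0
    landmark_fracs: tuple = (0.70, 0.77, 0.85)
    landmark_sats: tuple = (96.6, 94.5, 89.2)
    landmark_sat_sds: tuple = (0.8, 0.8, 1.0)
    landmark_frac_jitter: float = 0.02
    end_mean: float = 77.9
    end_sd: float = 6.0
    end_lo: float = 50.0
    end_hi: float = 92.0


_DEFAULT_SHAPES = {
    # medians/sigmas reproduce the printed group mean & median durations and
    # depths (log-normal: mean = median * exp(sigma^2 / 2))
    "arterial": DiveShapeParams(5.3, 0.272, 2.3, 12.0, 23.0, 0.729, 8.0, 92.0),
    # Type A dives get a slower final ascent (gradual return to the ice
    # hole) so the late-ascent saturation decline has a phase to live in
    "venousA": DiveShapeParams(3.1, 0.748, 2.3, 9.1, 24.0, 0.485, 8.0, 65.0,
                               ascent_rate_lo=0.25, ascent_rate_hi=0.45),
    "venousB": DiveShapeParams(9.0, 0.256, 2.5, 23.1, 51.0, 0.338, 12.0, 155.0),
}

_DEFAULT_MIX = {"arterial": 0.40, "venousA": 0.19, "venousB": 0.41}

_TRUE_LABEL = {"arterial": "arterial", "venousA": "TypeA", "venousB": "TypeB"}


@dataclass(frozen=True)
class GeneratorConfig:
    n_dives: int = 100
    group_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    seed: int = 0
    po2_noise_sd_mmHg: float = 1.0
    depth_noise_sd_m: float = 0.0
    sampling_interval_s: float = 15.0
    surface_pad_s: float = 30.0
    odc: ODCParams = DEFAULT_ODC
    shapes: dict = field(default_factory=lambda: dict(_DEFAULT_SHAPES))
    type_a: TypeATrajectory = TypeATrajectory()
    type_b: TypeBTrajectory = TypeBTrajectory()
    arterial: ArterialTrajectory = ArterialTrajectory()
    n_venous_birds: int = 10
    n_arterial_birds: int = 5
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_dives < 1:
            raise InputDomainError("n_dives must be >= 1")
        total = sum(self.group_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise InputDomainError(f"group_mix must sum to 1, got {total}")
        if any(g not in GROUPS for g in self.group_mix):
            raise InputDomainError(f"group_mix keys must be among {GROUPS}")
        if self.po2_noise_sd_mmHg < 0 or self.depth_noise_sd_m < 0:
            raise InputDomainError("noise standard deviations must be non-negative")
        if self.sampling_interval_s not in (5.0, 15.0, 5, 15):
            raise InputDomainError("sampling_interval_s must be 5 or 15")


@dataclass
class SyntheticRecord:
    """One synthetic dive with full ground truth."""

    record_id: int
    bird_id: str
    year: int
    group: str  # 'arterial' | 'venousA' | 'venousB'
    true_label: str  # 'arterial' | 'TypeA' | 'TypeB'
    depth: DepthProfile
    po2: PO2Profile
    traj_time_s: np.ndarray  # dense 1 Hz truth trajectory
    traj_sat_percent: np.ndarray
    dive_start_s: float
    dive_end_s: float
    max_depth_m: float
    truth: dict  # drawn trajectory parameters (start/peak/end sat, fractions)
    planted_interruptions: list = field(default_factory=list)

    @property
    def site(self) -> str:
        return "arterial" if self.group == "arterial" else "venous"

    @property
    def duration_min(self) -> float:
        return (self.dive_end_s - self.dive_start_s) / 60.0

    def true_sat_at(self, t_s) -> np.ndarray:
        return np.interp(t_s, self.traj_time_s, self.traj_sat_percent)


# --------------------------------------------------------------------------
# draw helpers
# --------------------------------------------------------------------------


def _trunc_normal(rng, mean, sd, lo, hi, tries=200):
    for _ in range(tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise GeneratorError(
        f"no draw from N({mean}, {sd}) landed in [{lo}, {hi}] after {tries} tries"
    )


def _trunc_lognormal(rng, median, sigma, lo, hi, tries=200):
    mu = math.log(median)
    for _ in range(tries):
        x = rng.lognormal(mu, sigma)
        if lo <= x <= hi:
            return float(x)
    raise GeneratorError(
        f"no log-normal(median={median}, sigma={sigma}) draw in [{lo}, {hi}]"
    )


def _piecewise_linear(frac_grid, knots):
    """Evaluate piecewise-linear (fraction, sat) knots on a fraction grid."""
    f = np.array([k[0] for k in knots])
    s = np.array([k[1] for k in knots])
    order = np.argsort(f, kind="stable")
    return np.interp(frac_grid, f[order], s[order])


# --------------------------------------------------------------------------
# dive geometry
# --------------------------------------------------------------------------


def _draw_geometry(shape: DiveShapeParams, pad_s: float, rng, retries: int):
    dur_s = _trunc_lognormal(
        rng, shape.dur_median_min * 60.0, shape.dur_sigma,
        shape.dur_min_min * 60.0, shape.dur_max_min * 60.0,
    )
    for _ in range(retries):
        dr = rng.uniform(shape.descent_rate_lo, shape.descent_rate_hi)
        ar = rng.uniform(shape.ascent_rate_lo, shape.ascent_rate_hi)
        depth = _trunc_lognormal(
            rng, shape.depth_median_m, shape.depth_sigma,
            shape.depth_min_m, shape.depth_max_m,
        )
        if depth * (1.0 / dr + 1.0 / ar) <= shape.max_vertical_time_frac * dur_s:
            break
    else:
        raise GeneratorError(
            f"could not draw a feasible depth for a {dur_s:.0f}s dive"
        )

    t_desc = depth / dr
    t_asc = depth / ar
    knots_t = [0.0, pad_s, pad_s + t_desc]
    knots_d = [0.0, 0.0, depth]
    bot0, bot1 = pad_s + t_desc, pad_s + dur_s - t_asc

    if rng.random() < shape.excursion_prob:
        er = rng.uniform(0.5, 1.0)
        up_frac = rng.uniform(0.35, 0.65)
        climb = depth * (1.0 - up_frac)
        t_leg = climb / er
        t_need = 2.0 * t_leg + 6.0
        if bot1 - bot0 > t_need + 40.0:
            e0 = rng.uniform(bot0 + 20.0, bot1 - 20.0 - t_need)
            knots_t += [bot0, e0, e0 + t_leg, e0 + t_leg + 6.0, e0 + t_need]
            knots_d += [depth, depth, depth - climb, depth - climb, depth]

    knots_t += [bot1, pad_s + dur_s, pad_s + dur_s + pad_s]
    knots_d += [depth, 0.0, 0.0]

    total = int(math.ceil(pad_s + dur_s + pad_s))
    t_grid = np.arange(0.0, total + 1.0)
    d_grid = np.interp(t_grid, knots_t, knots_d)
    return t_grid, d_grid, depth, dur_s, (bot0, bot1)


# --------------------------------------------------------------------------
# trajectory builders (return knots in dive-fraction space + truth dict)
# --------------------------------------------------------------------------


def _build_type_a(params: TypeATrajectory, rng, dur_true_s, f_ascent_start, retries):
    for _ in range(retries):
        peak = _trunc_normal(rng, params.peak_mean, params.peak_sd,
                             params.peak_lo, params.peak_hi)
        increase = _trunc_normal(rng, params.increase_mean, params.increase_sd,
                                 params.increase_lo, params.increase_hi)
        start = peak - increase
        if start < 40.0:
            continue
        f_peak = _trunc_normal(rng, params.frac_peak_mean, params.frac_peak_sd,
                               params.frac_peak_lo, params.frac_peak_hi)
        small = rng.random() < params.p_small_decline
        if small:
            decline = rng.uniform(params.small_decline_lo, params.small_decline_hi)
        else:
            decline = _trunc_normal(rng, params.big_decline_mean, params.big_decline_sd,
                                    params.big_decline_lo, peak - 1.0)
        end = peak - decline

        margin = max(0.04, 12.0 / dur_true_s)
        if small:
            base = max(f_peak + max(0.05, 35.0 / dur_true_s), 0.60)
            f_onset = base + rng.random() * max(0.0, 0.90 - base)
        else:
            base = max(0.58, f_ascent_start + margin,
                       f_peak + max(0.05, 35.0 / dur_true_s))
            if base > 0.94:
                continue  # ascent too late to host the decline; redraw
            f_onset = base + rng.random() * max(0.0, 0.93 - base)
        # short terminal flat so the end-of-dive value is sampled exactly
        # rather than read off the steep final decline
        f_flat = max(f_onset + 0.02, 1.0 - 12.0 / dur_true_s)
        knots = [(0.0, start), (f_peak, peak), (f_onset, peak), (f_flat, end), (1.0, end)]
        truth = {
            "start_sat": start, "peak_sat": peak, "end_sat": end,
            "frac_peak": f_peak, "decline_onset_frac": f_onset,
            "net_decrease": decline, "small_decline": small,
        }
        return knots, truth
    raise GeneratorError("no feasible Type A trajectory draw")


def _build_type_b_base(params: TypeBTrajectory, rng, dur_true_s, retries):
    for _ in range(retries):
        peak = _trunc_normal(rng, params.peak_mean, params.peak_sd,
                             params.peak_lo, params.peak_hi)
        increase = _trunc_normal(rng, params.increase_mean, params.increase_sd,
                                 params.increase_lo, params.increase_hi)
        start = peak - increase
        end_hi = peak - params.min_net_decrease
        if end_hi <= params.end_lo:
            continue
        end = _trunc_normal(rng, params.end_mean, params.end_sd,
                            params.end_lo, end_hi)
        f_peak = rng.uniform(params.frac_peak_lo, params.frac_peak_hi)
        # hold the peak as a short crest spanning at least one sampling
        # interval, so the sparse blood-gas record captures the peak value
        # instead of straddling a kink
        f_crest = f_peak + 18.0 / dur_true_s
        f_mid = _trunc_normal(rng, params.mid_frac_mean, params.mid_frac_sd,
                              max(params.mid_frac_lo, f_crest + 0.02),
                              max(params.mid_frac_hi, f_crest + 0.04))
        s_mid = peak - params.mid_drop_pp
        if not (end + 0.5 < s_mid < peak):
            continue
        f_flat = max(f_mid + 0.05, 1.0 - 12.0 / dur_true_s)
        knots = [(0.0, start), (f_peak, peak), (f_crest, peak),
                 (f_mid, s_mid), (f_flat, end), (1.0, end)]
        truth = {
            "start_sat": start, "peak_sat": peak, "end_sat": end,
            "frac_peak": f_peak, "crest_frac": f_crest,
            "mid_frac": f_mid, "mid_sat": s_mid,
            "net_decrease": peak - end,
        }
        return knots, truth
    raise GeneratorError("no feasible Type B trajectory draw")


def _build_arterial(params: ArterialTrajectory, rng, dur_true_s, retries):
    for _ in range(retries):
        peak = _trunc_normal(rng, params.peak_mean, params.peak_sd,
                             params.peak_lo, params.peak_hi)
        increase = _trunc_normal(rng, params.increase_mean, params.increase_sd,
                                 params.increase_lo, params.increase_hi)
        start = peak - increase
        f_rise = min(params.rise_time_s / dur_true_s, 0.15)
        fracs, sats = [], []
        prev_f, prev_s = f_rise, peak
        ok = True
        for f0, s0, sd in zip(params.landmark_fracs, params.landmark_sats,
                              params.landmark_sat_sds):
            f = f0 + rng.uniform(-params.landmark_frac_jitter,
                                 params.landmark_frac_jitter)
            s = _trunc_normal(rng, s0, sd, s0 - 3 * sd, s0 + 3 * sd)
            if f <= prev_f + 0.02 or s >= prev_s - 0.05:
                ok = False
                break
            fracs.append(f)
            sats.append(s)
            prev_f, prev_s = f, s
        if not ok:
            continue
        end = _trunc_normal(rng, params.end_mean, params.end_sd,
                            params.end_lo, min(params.end_hi, prev_s - 0.5))
        knots = [(0.0, start), (f_rise, peak)]
        knots += list(zip(fracs, sats))
        knots += [(1.0, end)]
        truth = {
            "start_sat": start, "peak_sat": peak, "end_sat": end,
            "frac_peak": f_rise,
            "landmark_fracs": tuple(fracs), "landmark_sats": tuple(sats),
        }
        return knots, truth
    raise GeneratorError("no feasible arterial trajectory draw")


# --------------------------------------------------------------------------
# Type B interruptions (additive deltas on the dense trajectory)
# --------------------------------------------------------------------------


def _cos_up(u):
    return (1.0 - np.cos(np.pi * u)) / 2.0


def _placement_window(place, t_s, t_e, geometry, t_grid, d_grid, max_depth):
    """Candidate onset times for one placement category."""
    bot0, bot1 = geometry
    end_guard = t_e - 60.0
    if place == "descent":
        lo, hi = t_s + 5.0, min(bot0, end_guard)
        mask = (t_grid >= lo) & (t_grid <= hi)
    elif place == "ascent":
        lo, hi = max(bot1, t_s + 5.0), end_guard
        mask = (t_grid >= lo) & (t_grid <= hi)
    else:  # max_depth
        mask = (d_grid >= 0.9 * max_depth) & (t_grid >= t_s + 5.0) & (t_grid <= end_guard)
    return t_grid[mask]


def _plant_interruptions(
    params: TypeBTrajectory,
    rng,
    t_grid,
    base,
    t_s,
    t_e,
    geometry,
    d_grid,
    max_depth,
    peak,
    interval_s,
    retries,
    reserved=(),
):
    """Draw, place and verify interruptions; returns (delta, planted list).

    ``reserved`` time intervals (e.g. the peak crest) are kept free of
    interruption windows so planted events cannot erode the drawn peak.
    """
    if rng.random() >= params.p_any_interruption:
        n = 0
    else:
        p = np.array(params.count_probs, dtype=float)
        n = int(rng.choice([1, 2, 3], p=p / p.sum()))

    placements = ["descent", "ascent", "max_depth"]
    pp = np.array(params.placement_probs, dtype=float)
    occupied = [tuple(iv) for iv in reserved]  # (w0, w1) intervals
    windows = []  # intervals of planted events only, aligned with `deltas`
    deltas, planted = [], []

    def overlaps(w0, w1):
        # 18 s separation guarantees at least one blood-gas sample between
        # adjacent events, so detection never merges them
        return any(w0 < b + 18.0 and w1 + 18.0 > a for a, b in occupied)

    for _ in range(n):
        kind = "inflection" if rng.random() < params.p_inflection else "plateau"
        drawn_place = placements[int(rng.choice(3, p=pp / pp.sum()))]
        made = False
        for _try in range(retries):
            # persist with the drawn phase before falling back to any phase,
            # so the placement mix is not skewed toward the widest window
            if _try < 25:
                place = drawn_place
            else:
                place = placements[int(rng.choice(3, p=pp / pp.sum()))]
            cand = _placement_window(place, t_s, t_e, geometry, t_grid, d_grid, max_depth)
            if cand.size == 0:
                continue
            t_on = float(rng.choice(cand))
            if kind == "inflection":
                ttp = _trunc_normal(rng, params.inflection_ttp_mean,
                                    params.inflection_ttp_sd,
                                    params.inflection_ttp_lo, params.inflection_ttp_hi)
                fall = rng.uniform(params.inflection_fall_lo, params.inflection_fall_hi)
                # the falling leg may be compressed against the dive start
                # (early-descent interruptions follow a brief sharp decline)
                fall = min(fall, t_on - (t_s + 2.0))
                if fall < 12.0:
                    continue
                w0, w1 = t_on - fall, t_on + ttp
                if w0 < t_s + 2.0 or w1 > t_e - 30.0 or overlaps(w0, w1):
                    continue
                b_on = float(np.interp(t_on, t_grid, base))
                b_apex = float(np.interp(w1, t_grid, base))
                drop = max(0.0, b_on - b_apex)
                mag = _trunc_normal(rng, params.inflection_mag_mean,
                                    params.inflection_mag_sd,
                                    params.inflection_mag_lo, params.inflection_mag_hi)
                m_eff = max(mag, drop + 8.0)
                if m_eff > b_on - 2.0:
                    continue
                delta = np.zeros_like(base)
                rise_mask = (t_grid >= w0) & (t_grid < t_on)
                rec_mask = (t_grid >= t_on) & (t_grid <= w1)
                delta[rise_mask] = -m_eff * _cos_up((t_grid[rise_mask] - w0) / fall)
                delta[rec_mask] = -m_eff * (1.0 - _cos_up((t_grid[rec_mask] - t_on) / ttp))
                deltas.append(delta)
                planted.append(
                    Interruption(kind="inflection", t_onset_s=t_on,
                                 magnitude_pp=m_eff - drop, time_to_peak_s=ttp,
                                 phase_label=place)
                )
                occupied.append((w0, w1))
                windows.append((w0, w1))
                made = True
                break
            else:  # plateau
                dur = _trunc_normal(rng, params.plateau_dur_mean, params.plateau_dur_sd,
                                    params.plateau_dur_lo, params.plateau_dur_hi)
                rise = _trunc_normal(rng, params.plateau_rise_mean, params.plateau_rise_sd,
                                     params.plateau_rise_lo, params.plateau_rise_hi)
                rejoin = params.plateau_rejoin_s
                w0, w1 = t_on, t_on + dur + rejoin
                if w1 > t_e - 30.0 or overlaps(w0, w1):
                    continue
                level = float(np.interp(t_on, t_grid, base))
                if level > peak - 3.0:
                    # too close to the peak: the plateau's rise would stack
                    # on the initial rise into a spurious >4 pp inflection
                    continue
                top = level + rise
                frac_end = (w1 - t_s) / (t_e - t_s)
                if frac_end > params.late_cap_frac and top > peak - params.late_cap_below_peak_pp:
                    continue
                delta = np.zeros_like(base)
                flat = (t_grid >= t_on) & (t_grid <= t_on + dur)
                rej = (t_grid > t_on + dur) & (t_grid <= w1)
                target = level + rise * (t_grid[flat] - t_on) / dur
                delta[flat] = target - base[flat]
                delta[rej] = (top - base[rej]) * (
                    1.0 - _cos_up((t_grid[rej] - t_on - dur) / rejoin)
                )
                deltas.append(delta)
                planted.append(
                    Interruption(kind="plateau", t_onset_s=t_on,
                                 magnitude_pp=rise, duration_s=dur,
                                 phase_label=place)
                )
                occupied.append((w0, w1))
                windows.append((w0, w1))
                made = True
                break
        if not made:
            continue  # this interruption could not be sited; dive keeps fewer

    # verify each planted event against the noise-free sampled grid so the
    # planted ground truth and zero-noise detection agree exactly
    if planted:
        keep_d, keep_p = [], []
        total_delta = np.sum(deltas, axis=0)
        t_samp = np.arange(t_grid[0], t_grid[-1] + 1e-9, interval_s)
        for delta, intr, (w0, w1) in zip(deltas, planted, windows):
            final = base + total_delta
            s_samp = np.interp(t_samp, t_grid, final)
            wmask = (t_samp >= w0 - interval_s) & (t_samp <= w1 + interval_s)
            seg = s_samp[wmask]
            recoverable = False
            if seg.size >= 3:
                if intr.kind == "inflection":
                    i_min = int(np.argmin(seg))
                    if i_min < seg.size - 1:
                        recoverable = float(np.max(seg[i_min:]) - seg[i_min]) > 4.6
                else:
                    inwin = (t_samp >= w0) & (t_samp <= w1 - params.plateau_rejoin_s)
                    seg2 = s_samp[inwin]
                    if seg2.size >= 3:
                        steps = np.diff(seg2)
                        recoverable = (
                            -0.9 < seg2[-1] - seg2[0] <= 3.9
                            and (steps >= -0.9).all()
                        )
            if recoverable:
                keep_d.append(delta)
                keep_p.append(intr)
            else:
                total_delta = total_delta - delta  # withdraw the bump entirely
        deltas, planted = keep_d, keep_p

    delta_sum = np.sum(deltas, axis=0) if deltas else np.zeros_like(base)
    planted.sort(key=lambda it: it.t_onset_s)
    return delta_sum, planted


# --------------------------------------------------------------------------
# record assembly
# --------------------------------------------------------------------------


def _bird_and_year(config: GeneratorConfig, group: str, rng):
    if group == "arterial":
        idx = int(rng.integers(config.n_arterial_birds))
        return f"EPA{idx + 1:02d}", 2007 + (idx % 2)
    idx = int(rng.integers(config.n_venous_birds))
    return f"EPV{idx + 1:02d}", (2001, 2003, 2004, 2005, 2008)[idx % 5]


def generate_dive(config: GeneratorConfig, group: str, rng, record_id: int = 0) -> SyntheticRecord:
    """Generate one labelled dive for ``group`` from an explicit RNG."""
    if group not in GROUPS:
        raise InputDomainError(f"unknown group {group!r}; expected one of {GROUPS}")
    shape = config.shapes[group]
    pad = config.surface_pad_s
    for _ in range(config.max_retries):
        t_grid, d_grid, max_depth, dur_s, bottom_span = _draw_geometry(
            shape, pad, rng, config.max_retries
        )
        if group != "venousA":
            break
        # a Type A dive needs an ascent long enough (>= ~12% of the dive) to
        # host a late saturation decline; shallow-but-long geometry cannot
        if (bottom_span[1] - pad) / dur_s <= 0.88:
            break
    else:
        raise GeneratorError("no feasible dive geometry for group " + group)
    if config.depth_noise_sd_m > 0:
        d_grid = np.clip(d_grid + rng.normal(0.0, config.depth_noise_sd_m, d_grid.size), 0.0, None)

    wet = np.flatnonzero(d_grid > 2.0)
    t_s, t_e = float(t_grid[wet[0]]), float(t_grid[wet[-1]])
    frac = np.clip((t_grid - t_s) / (t_e - t_s), 0.0, 1.0)
    dur_true = t_e - t_s

    planted: list = []
    if group == "venousA":
        asc_start_t = bottom_span[1]
        f_asc = (asc_start_t - t_s) / dur_true
        knots, truth = _build_type_a(config.type_a, rng, dur_true, f_asc, config.max_retries)
        sat = _piecewise_linear(frac, knots)
    elif group == "venousB":
        knots, truth = _build_type_b_base(config.type_b, rng, dur_true, config.max_retries)
        sat = _piecewise_linear(frac, knots)
        crest0 = t_s + truth["frac_peak"] * dur_true
        crest1 = t_s + truth["crest_frac"] * dur_true
        delta, planted = _plant_interruptions(
            config.type_b, rng, t_grid, sat, t_s, t_e, bottom_span,
            d_grid, max_depth, truth["peak_sat"], config.sampling_interval_s,
            config.max_retries, reserved=[(t_s, crest1 + 5.0)],
        )
        sat = sat + delta
    else:
        knots, truth = _build_arterial(config.arterial, rng, dur_true, config.max_retries)
        sat = _piecewise_linear(frac, knots)
    sat = np.clip(sat, 0.5, 99.5)

    t_samp = np.arange(0.0, t_grid[-1] + 1e-9, config.sampling_interval_s)
    sat_samp = np.interp(t_samp, t_grid, sat)
    po2 = po2_from_saturation(sat_samp, config.odc)
    if config.po2_noise_sd_mmHg > 0:
        po2 = po2 + rng.normal(0.0, config.po2_noise_sd_mmHg, po2.size)
    po2 = np.clip(po2, 0.05, None)

    bird, year = _bird_and_year(config, group, rng)
    site = "arterial" if group == "arterial" else "venous"
    return SyntheticRecord(
        record_id=record_id,
        bird_id=bird,
        year=year,
        group=group,
        true_label=_TRUE_LABEL[group],
        depth=DepthProfile(t_grid, d_grid, 1.0),
        po2=PO2Profile(site, t_samp, po2, config.sampling_interval_s, bird, year),
        traj_time_s=t_grid,
        traj_sat_percent=sat,
        dive_start_s=t_s,
        dive_end_s=t_e,
        max_depth_m=max_depth,
        truth=truth,
        planted_interruptions=planted,
    )


def _record_rng(seed: int, index: int):
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_record(config: GeneratorConfig, index: int) -> SyntheticRecord:
    """Generate the ``index``-th record of a dataset, independently of the
    other records (substream seeded by ``(seed, index)``)."""
    rng = _record_rng(config.seed, index)
    groups = sorted(config.group_mix)
    probs = np.array([config.group_mix[g] for g in groups])
    group = groups[int(rng.choice(len(groups), p=probs / probs.sum()))]
    return generate_dive(config, group, rng, record_id=index)


def generate_dataset(config: GeneratorConfig):
    """Generate ``config.n_dives`` records plus a ground-truth manifest."""
    records = [generate_record(config, i) for i in range(config.n_dives)]
    rows = []
    for r in records:
        rows.append(
            {
                "record_id": r.record_id,
                "bird_id": r.bird_id,
                "year": r.year,
                "site": r.site,
                "group": r.group,
                "true_label": r.true_label,
                "dive_start_s": r.dive_start_s,
                "dive_end_s": r.dive_end_s,
                "duration_min": r.duration_min,
                "max_depth_m": r.max_depth_m,
                "start_sat": r.truth["start_sat"],
                "peak_sat": r.truth["peak_sat"],
                "end_sat": r.truth["end_sat"],
                "frac_peak": r.truth["frac_peak"],
                "n_interruptions": len(r.planted_interruptions),
                "n_inflections": sum(
                    1 for it in r.planted_interruptions
                    if it.kind == "inflection" and it.magnitude_pp > 4.0
                ),
            }
        )
    manifest = pd.DataFrame(rows)
    return records, manifest


def write_dataset(records, manifest: pd.DataFrame, outdir) -> None:
    """Write depth CSVs, P_O2 CSVs and the ground-truth manifest."""
    from pathlib import Path

    out = Path(outdir)
    (out / "depth").mkdir(parents=True, exist_ok=True)
    (out / "po2").mkdir(parents=True, exist_ok=True)
    for r in records:
        r.depth.to_csv(out / "depth" / f"rec{r.record_id:04d}.csv")
        r.po2.to_csv(out / "po2" / f"rec{r.record_id:04d}.csv")
    manifest.to_csv(out / "manifest.csv", index=False, float_format="%.4f")
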