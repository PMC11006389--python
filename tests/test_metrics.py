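"""Per-dive saturation metrics, landmarks and interruption detection."""

import numpy as np
import pytest

from divesat import (
    GeneratorConfig,
    SaturationProfile,
    align_to_dive,
    compute_metrics,
    detect_dives,
    detect_interruptions,
    generate_dataset,
    saturation_profile_from_po2,
    segment_phases,
)
from divesat.dives import Dive
from divesat.errors import EmptyProfileError, InsufficientDataError


def make_dive(start=0.0, end=300.0, max_depth=40.0, t_max=150.0):
    return Dive(start_s=start, end_s=end, max_depth_m=max_depth, t_max_depth_s=t_max)


def venous(time_s, sats, interval=15.0):
    return SaturationProfile("venous", np.asarray(time_s, float), np.asarray(sats, float), interval)


class TestAlignment:
    def test_sample_exactly_at_start_is_start_of_dive(self):
        dive = make_dive(start=10.0, end=310.0)
        prof = venous(np.arange(10.0, 320.0, 15.0), np.linspace(90, 60, 21))
        aligned = align_to_dive(prof, dive)
        m = compute_metrics(aligned, dive)
        assert m.start_sat == prof.sat_percent[0]

    def test_nearest_sample_rule_reaches_before_dive_start(self):
        # 15 s cadence: samples at 7 s and 22 s around a dive starting at 10 s
        # -> the 7 s sample is nearer and becomes start-of-dive
        dive = make_dive(start=10.0, end=310.0)
        t = np.array([7.0, 22.0, 37.0, 52.0, 67.0])
        s = np.array([88.0, 86.0, 84.0, 82.0, 80.0])
        aligned = align_to_dive(venous(t, s), dive)
        assert aligned.time_s[0] == 7.0
        m = compute_metrics(aligned, dive)
        assert m.start_sat == 88.0

    def test_profile_outside_dive_is_an_error(self):
        dive = make_dive(start=1000.0, end=1300.0)
        with pytest.raises(EmptyProfileError):
            align_to_dive(venous([0.0, 15.0, 30.0], [90, 90, 90]), dive)


class TestComputeMetrics:
    def test_constant_profile(self):
        dive = make_dive(end=60.0)
        prof = venous(np.arange(0.0, 61.0, 15.0), [90.0] * 5)
        m = compute_metrics(prof, dive)
        assert m.start_sat == m.peak_sat == m.end_sat == m.mean_sat == 90.0
        assert m.increase_start_to_peak == 0.0
        assert m.landmarks == {}

    def test_hand_profile(self):
        # peak 100 at t=0; 10-pp landmark falls on the 90 sample; mean 92.6
        dive = make_dive(end=60.0)
        prof = venous([0.0, 15.0, 30.0, 45.0, 60.0], [100.0, 98.0, 95.0, 90.0, 80.0])
        m = compute_metrics(prof, dive)
        assert m.peak_sat == 100.0
        assert m.t_peak_min == 0.0
        assert m.mean_sat == pytest.approx(92.6)
        lm10 = m.landmarks[10.0]
        assert lm10.sat_percent == 90.0
        assert lm10.t_min == pytest.approx(45.0 / 60.0)
        assert lm10.fraction == pytest.approx(0.75)
        # 5-pp landmark: exact 95 sample; 2.5-pp: 98 is nearest to 97.5
        assert m.landmarks[5.0].sat_percent == 95.0
        assert m.landmarks[2.5].sat_percent == 98.0

    def test_shallow_decline_leaves_10pp_landmark_absent(self):
        dive = make_dive(end=60.0)
        prof = venous(np.arange(0.0, 61.0, 15.0), [95.0, 93.0, 91.0, 89.0, 86.0])
        m = compute_metrics(prof, dive)  # declines 9 pp from peak
        assert 10.0 not in m.landmarks
        assert 5.0 in m.landmarks

    def test_landmark_times_are_ordered(self):
        cfg = GeneratorConfig(n_dives=12, seed=9)
        records, _ = generate_dataset(cfg)
        for rec in records:
            (dive,) = detect_dives(rec.depth)
            prof = align_to_dive(saturation_profile_from_po2(rec.po2), dive)
            m = compute_metrics(prof, dive)
            present = [m.landmarks[d].t_min for d in (2.5, 5.0, 10.0) if d in m.landmarks]
            assert present == sorted(present)
            # exact metric identities
            assert m.increase_start_to_peak + m.start_sat == pytest.approx(m.peak_sat)
            assert m.net_peak_to_end_decrease + m.end_sat == pytest.approx(m.peak_sat)
            assert 0.0 <= m.frac_peak <= 1.0

    def test_too_few_samples_rejected(self):
        dive = make_dive(end=30.0)
        with pytest.raises(InsufficientDataError):
            compute_metrics(venous([0.0, 15.0], [90.0, 85.0]), dive)


class TestDetectInterruptions:
    def test_strictly_decreasing_profile_has_none(self):
        dive = make_dive(end=300.0)
        t = np.arange(0.0, 301.0, 15.0)
        prof = venous(t, np.linspace(80, 30, t.size))
        assert detect_interruptions(prof, dive) == []

    def test_planted_bump_found_with_its_magnitude(self):
        dive = make_dive(end=300.0)
        t = np.arange(0.0, 301.0, 15.0)
        s = np.linspace(80, 30, t.size)
        s[8:12] += np.array([5.0, 15.0, 10.0, 2.0])  # 15-pp bump on the decline
        prof = venous(t, s)
        out = detect_interruptions(prof, dive)
        infl = [i for i in out if i.kind == "inflection"]
        assert len(infl) == 1
        assert infl[0].magnitude_pp == pytest.approx(
            s[9] - s[7]
        )  # rise from the local minimum before the bump
        assert infl[0].t_onset_s == t[7]

    def test_rise_of_exactly_four_points_is_not_an_inflection(self):
        dive = make_dive(end=300.0)
        t = np.arange(0.0, 301.0, 15.0)
        s = np.linspace(80, 30, t.size)
        base = s.copy()
        s[10] = base[9] + 4.0  # rise of exactly 4.0 pp from the previous sample
        prof = venous(t, s)
        assert [i for i in detect_interruptions(prof, dive) if i.kind == "inflection"] == []

    def test_plateau_detected_with_duration(self):
        dive = make_dive(end=300.0)
        t = np.arange(0.0, 301.0, 15.0)
        s = np.linspace(80, 30, t.size)
        s[8:13] = s[8] + np.array([0.0, 0.4, 0.8, 1.2, 1.6])  # 60 s near-flat run
        prof = venous(t, s)
        plateaus = [i for i in detect_interruptions(prof, dive) if i.kind == "plateau"]
        assert len(plateaus) == 1
        assert plateaus[0].duration_s >= 30.0
        assert -1.0 < plateaus[0].magnitude_pp <= 4.0

    def test_interruptions_sorted_and_phase_labelled(self):
        cfg = GeneratorConfig(n_dives=15, group_mix={"venousB": 1.0}, seed=3)
        records, _ = generate_dataset(cfg)
        for rec in records:
            (dive,) = detect_dives(rec.depth)
            dive = segment_phases(dive, rec.depth)
            prof = align_to_dive(saturation_profile_from_po2(rec.po2), dive)
            out = detect_interruptions(prof, dive, rec.depth)
            onsets = [i.t_onset_s for i in out]
            assert onsets == sorted(onsets)
            assert all(i.phase_label in ("descent", "ascent", "max_depth") for i in out)

    def test_planted_inflections_recovered_exactly_without_noise(self):
        cfg = GeneratorConfig(
            n_dives=40, group_mix={"venousB": 1.0}, seed=17, po2_noise_sd_mmHg=0.0
        )
        records, _ = generate_dataset(cfg)
        for rec in records:
            (dive,) = detect_dives(rec.depth)
            dive = segment_phases(dive, rec.depth)
            prof = align_to_dive(saturation_profile_from_po2(rec.po2), dive)
            detected = [
                i for i in detect_interruptions(prof, dive, rec.depth)
                if i.kind == "inflection"
            ]
            planted = [
                i for i in rec.planted_interruptions
                if i.kind == "inflection" and i.magnitude_pp > 4.0
            ]
            assert len(detected) == len(planted)
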