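"""Dive detection, phase segmentation and dive-fraction arithmetic."""

import numpy as np
import pytest

from divesat import (
    DepthProfile,
    GeneratorConfig,
    detect_dives,
    fraction_of_dive,
    generate_dataset,
    segment_phases,
)
from divesat.errors import DegenerateDiveError, FormatError, InputDomainError


def v_dive(depth_m=50.0, rate=1.0, pad_s=20, bottom_s=0):
    """Symmetric trapezoid/V dive trace at 1 Hz with surface pads."""
    leg = depth_m / rate
    total = int(2 * pad_s + 2 * leg + bottom_s)
    t = np.arange(total + 1, dtype=float)
    knots_t = [0, pad_s, pad_s + leg, pad_s + leg + bottom_s, pad_s + 2 * leg + bottom_s, total]
    knots_d = [0, 0, depth_m, depth_m, 0, 0]
    return DepthProfile(t, np.interp(t, knots_t, knots_d))


class TestDetectDives:
    def test_flat_surface_trace_yields_nothing(self):
        t = np.arange(600.0)
        assert detect_dives(DepthProfile(t, np.zeros_like(t))) == []

    def test_two_minute_rule_is_strict(self):
        # a 50 m V-dive submerged ~115 s is excluded...
        prof = v_dive(depth_m=50.0, rate=1.0, bottom_s=19)
        assert detect_dives(prof, 2.0, 2.0) == []
        # ...while one a few seconds over the threshold is kept
        prof2 = v_dive(depth_m=50.0, rate=1.0, bottom_s=30)
        dives = detect_dives(prof2, 2.0, 2.0)
        assert len(dives) == 1
        assert dives[0].duration_min > 2.0
        assert dives[0].max_depth_m == pytest.approx(50.0)

    def test_non_monotone_time_is_a_format_error(self):
        with pytest.raises(FormatError):
            DepthProfile(np.array([0.0, 1.0, 1.0]), np.array([0.0, 5.0, 5.0]))

    def test_generator_ground_truth_recovered(self):
        cfg = GeneratorConfig(n_dives=6, seed=11)
        records, _ = generate_dataset(cfg)
        for rec in records:
            dives = detect_dives(rec.depth)
            assert len(dives) == 1
            d = dives[0]
            assert abs(d.start_s - rec.dive_start_s) <= 1.0
            assert abs(d.end_s - rec.dive_end_s) <= 1.0
            assert d.max_depth_m == pytest.approx(
                rec.depth.depth_m.max(), abs=1e-9
            )

    def test_detection_idempotent_on_restricted_trace(self):
        cfg = GeneratorConfig(n_dives=3, seed=5)
        records, _ = generate_dataset(cfg)
        for rec in records:
            (dive,) = detect_dives(rec.depth)
            sub = rec.depth.window(dive.start_s, dive.end_s)
            (again,) = detect_dives(sub)
            assert again.start_s == dive.start_s
            assert again.end_s == dive.end_s


class TestSegmentPhases:
    def test_symmetric_v_dive_splits_in_half(self):
        prof = v_dive(depth_m=150.0, rate=1.0)
        (dive,) = detect_dives(prof)
        dive = segment_phases(dive, prof)
        names = [p.name for p in dive.phases]
        assert names[0] == "descent" and names[-1] == "ascent"
        desc = dive.phase_named("descent")
        asc = dive.phase_named("ascent")
        half = (dive.end_s - dive.start_s) / 2
        assert desc.duration_s == pytest.approx(half, abs=4.0)
        assert asc.duration_s == pytest.approx(half, abs=4.0)
        bottom = dive.phase_named("bottom")
        if bottom is not None:  # at most a sliver around the apex
            assert bottom.duration_s <= 6.0
        assert len(dive.direction_changes) == 1

    def test_square_u_dive_has_three_phases(self):
        prof = v_dive(depth_m=60.0, rate=1.0, bottom_s=120)
        (dive,) = detect_dives(prof)
        dive = segment_phases(dive, prof)
        assert [p.name for p in dive.phases] == ["descent", "bottom", "ascent"]
        bottom = dive.phase_named("bottom")
        assert bottom.duration_s == pytest.approx(120.0, abs=8.0)

    def test_phases_tile_the_dive_exactly(self):
        cfg = GeneratorConfig(n_dives=10, seed=21)
        records, _ = generate_dataset(cfg)
        for rec in records:
            (dive,) = detect_dives(rec.depth)
            dive = segment_phases(dive, rec.depth)
            phases = dive.phases
            assert phases[0].t_start_s == dive.start_s
            assert phases[-1].t_end_s == dive.end_s
            for a, b in zip(phases, phases[1:]):
                assert a.t_end_s == b.t_start_s  # disjoint and gap-free

    def test_excursion_reported_as_direction_changes(self):
        # force a sub-ice excursion: deep V-dive with a mid-bottom ascent
        pad, depth = 20, 80.0
        t = np.arange(0, 521, dtype=float)
        knots_t = [0, pad, pad + 80, pad + 180, pad + 220, pad + 226, pad + 266, pad + 420, 500, 520]
        knots_d = [0, 0, depth, depth, depth * 0.5, depth * 0.5, depth, depth, 0, 0]
        prof = DepthProfile(t, np.interp(t, knots_t, knots_d))
        (dive,) = detect_dives(prof)
        dive = segment_phases(dive, prof)
        # down, up (excursion), down (return), up (final) -> 3 changes
        assert len(dive.direction_changes) == 3

    def test_degenerate_dive_rejected(self):
        from divesat.dives import Dive

        tiny = DepthProfile(np.array([0.0, 1.0]), np.array([5.0, 5.0]))
        dive = Dive(start_s=0.0, end_s=1.0, max_depth_m=5.0, t_max_depth_s=0.0)
        with pytest.raises(DegenerateDiveError):
            segment_phases(dive, tiny)


class TestFractionOfDive:
    @pytest.mark.parametrize(
        "t, start, end, expected",
        [
            (60.0, 0.0, 600.0, 0.1),  # 1 min into a 10 min dive
            (30.0, 0.0, 300.0, 0.1),  # 30 s into a 5 min dive
            (300.0, 0.0, 300.0, 1.0),
        ],
    )
    def test_examples(self, t, start, end, expected):
        from divesat.dives import Dive

        dive = Dive(start_s=start, end_s=end, max_depth_m=10.0, t_max_depth_s=end / 2)
        assert fraction_of_dive(t, dive) == pytest.approx(expected)

    def test_outside_dive_rejected(self):
        from divesat.dives import Dive

        dive = Dive(start_s=100.0, end_s=400.0, max_depth_m=10.0, t_max_depth_s=200.0)
        with pytest.raises(InputDomainError):
            fraction_of_dive(99.0, dive)
        with pytest.raises(InputDomainError):
            fraction_of_dive(401.0, dive)
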