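"""Synthetic-data generator: determinism, mixing, and self-consistency."""

import numpy as np
import pytest

from divesat import (
    GeneratorConfig,
    align_to_dive,
    compute_metrics,
    detect_dives,
    generate_dataset,
    generate_record,
    saturation_profile_from_po2,
)
from divesat.errors import InputDomainError


class TestReproducibility:
    def test_same_seed_gives_identical_records(self):
        cfg = GeneratorConfig(n_dives=4, seed=13)
        a, ma = generate_dataset(cfg)
        b, mb = generate_dataset(cfg)
        assert ma.equals(mb)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.depth.depth_m, rb.depth.depth_m)
            np.testing.assert_array_equal(ra.po2.po2_mmHg, rb.po2.po2_mmHg)
            np.testing.assert_array_equal(ra.traj_sat_percent, rb.traj_sat_percent)

    def test_records_are_insertion_order_independent(self):
        cfg = GeneratorConfig(n_dives=6, seed=42)
        records, _ = generate_dataset(cfg)
        solo = generate_record(cfg, 4)
        assert solo.group == records[4].group
        np.testing.assert_array_equal(solo.po2.po2_mmHg, records[4].po2.po2_mmHg)

    def test_different_seeds_differ(self):
        r1 = generate_record(GeneratorConfig(n_dives=1, seed=1), 0)
        r2 = generate_record(GeneratorConfig(n_dives=1, seed=2), 0)
        assert not np.array_equal(r1.po2.po2_mmHg, r2.po2.po2_mmHg)


class TestConfigValidation:
    def test_zero_dives_rejected(self):
        with pytest.raises(InputDomainError):
            GeneratorConfig(n_dives=0)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(InputDomainError):
            GeneratorConfig(group_mix={"arterial": 0.7, "venousB": 0.7})

    def test_cadence_must_be_5_or_15(self):
        with pytest.raises(InputDomainError):
            GeneratorConfig(sampling_interval_s=10.0)
        GeneratorConfig(sampling_interval_s=5.0)  # fine


class TestPopulationStructure:
    def test_group_mix_respected_within_binomial_ci(self):
        n = 600
        cfg = GeneratorConfig(n_dives=n, seed=2)
        _, manifest = generate_dataset(cfg)
        for group, p in cfg.group_mix.items():
            k = (manifest.group == group).sum()
            half = 2.58 * np.sqrt(n * p * (1 - p))  # 99% CI
            assert abs(k - n * p) <= half, (group, k)

    def test_type_b_dives_longer_and_deeper_than_type_a(self):
        cfg = GeneratorConfig(n_dives=150, seed=6)
        _, manifest = generate_dataset(cfg)
        a = manifest[manifest.group == "venousA"]
        b = manifest[manifest.group == "venousB"]
        assert b.duration_min.mean() > a.duration_min.mean() + 2.0
        assert b.max_depth_m.mean() > a.max_depth_m.mean() + 10.0

    def test_all_durations_exceed_inclusion_floor(self):
        cfg = GeneratorConfig(n_dives=80, seed=31)
        _, manifest = generate_dataset(cfg)
        assert (manifest.duration_min > 2.0).all()

    def test_interruption_count_split_roughly_matches_targets(self):
        cfg = GeneratorConfig(n_dives=400, group_mix={"venousB": 1.0}, seed=12)
        _, manifest = generate_dataset(cfg)
        with_any = manifest[manifest.n_interruptions > 0]
        assert len(with_any) / len(manifest) > 0.9
        ones = (with_any.n_interruptions == 1).mean()
        assert 0.35 <= ones <= 0.75  # around the 53.8% target


class TestSelfConsistency:
    def test_zero_noise_roundtrip_reproduces_trajectory_values(self):
        # forward ODC after inverse ODC cancels: recovered start/peak/end
        # equal the truth trajectory at the sampled instants
        cfg = GeneratorConfig(n_dives=20, seed=19, po2_noise_sd_mmHg=0.0)
        records, _ = generate_dataset(cfg)
        for rec in records:
            (dive,) = detect_dives(rec.depth)
            prof = align_to_dive(saturation_profile_from_po2(rec.po2), dive)
            m = compute_metrics(prof, dive)
            truth = rec.true_sat_at(prof.time_s)
            assert m.peak_sat == pytest.approx(truth.max(), abs=1e-9)
            i_end = int(np.argmin(np.abs(prof.time_s - dive.end_s)))
            assert m.end_sat == pytest.approx(truth[i_end], abs=1e-9)
            i_start = int(np.argmin(np.abs(prof.time_s - dive.start_s)))
            assert m.start_sat == pytest.approx(truth[i_start], abs=1e-9)

    def test_type_a_plateau_holds_near_drawn_peak(self):
        cfg = GeneratorConfig(
            n_dives=12, group_mix={"venousA": 1.0}, seed=23, po2_noise_sd_mmHg=0.0
        )
        records, _ = generate_dataset(cfg)
        for rec in records:
            peak = rec.truth["peak_sat"]
            f_on = rec.truth["decline_onset_frac"]
            t0 = rec.dive_start_s + rec.truth["frac_peak"] * (rec.dive_end_s - rec.dive_start_s)
            t1 = rec.dive_start_s + f_on * (rec.dive_end_s - rec.dive_start_s)
            ts = np.linspace(t0, t1, 20)
            assert np.all(np.abs(rec.true_sat_at(ts) - peak) < 1.0)

    def test_planted_po2_matches_inverse_of_trajectory_without_noise(self):
        from divesat import po2_from_saturation

        cfg = GeneratorConfig(n_dives=5, seed=3, po2_noise_sd_mmHg=0.0)
        records, _ = generate_dataset(cfg)
        for rec in records:
            want = po2_from_saturation(
                np.clip(rec.true_sat_at(rec.po2.time_s), 0.5, 99.5), cfg.odc
            )
            np.testing.assert_allclose(rec.po2.po2_mmHg, np.clip(want, 0.05, None), atol=1e-9)


def test_write_dataset_roundtrip(tmp_path):
    from divesat import DepthProfile, PO2Profile, write_dataset

    cfg = GeneratorConfig(n_dives=3, seed=27)
    records, manifest = generate_dataset(cfg)
    write_dataset(records, manifest, tmp_path)
    depth = DepthProfile.from_csv(tmp_path / "depth" / "rec0001.csv")
    po2 = PO2Profile.from_csv(tmp_path / "po2" / "rec0001.csv", site=records[1].site)
    assert len(depth) == len(records[1].depth)
    assert len(po2) == len(records[1].po2)
    assert (tmp_path / "manifest.csv").exists()
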