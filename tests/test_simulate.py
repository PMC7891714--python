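"""Synthetic cohort generator: mixing model, determinism, TLX link."""

from dataclasses import replace

import numpy as np
import pytest

from nirsload.synthetic import (
    PhysioConfig,
    StudyConfig,
    SubjectProfile,
    build_layout,
    draw_profile,
    forward_mbll,
    generate_tlx,
    make_schedule,
    simulate_cohort,
    simulate_subject,
)

ZERO_PHYSIO = PhysioConfig(
    drift_amp_um=0.0, noise_sd_um=0.0, hbr_noise_sd_um=0.0, accel_noise_sd=0.0
)


def silent_profile(subject_id="S01", group="student", amp=0.0, sup=0.0, motion=0.0):
    amps = {
        (r, h): amp
        for r in ("dorsolateral", "ventrolateral", "medial", "orbitofrontal")
        for h in ("L", "R")
    }
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        latent_load=0.0,
        cerebral_amplitude=amps,
        superficial_amplitude=sup,
        motion_rate_per_min=motion,
    )


class TestSchedule:
    def test_default_structure(self):
        sched = make_schedule()
        assert [e.name for e in sched.episodes] == ["rest1", "task1", "rest2", "task2"]
        assert all(e.duration_s == 60.0 for e in sched.episodes if e.name.startswith("rest"))

    def test_task_longer_than_6min_rejected(self):
        with pytest.raises(Exception):
            make_schedule(task_s=400.0)

    def test_sampling_rate_default(self):
        assert make_schedule().fs == 8.138


class TestSimulateSubject:
    def test_all_zero_config_gives_zero_od(self, small_layout, short_schedule):
        rec = simulate_subject(
            silent_profile(), small_layout, short_schedule, ZERO_PHYSIO, seed=3
        )
        assert np.all(rec.od == 0)
        assert np.all(rec.motion == 0)

    def test_cerebral_component_is_linear_in_amplitude(self, small_layout, short_schedule):
        base = silent_profile(amp=0.5)
        double = silent_profile(amp=1.0)
        r1 = simulate_subject(base, small_layout, short_schedule, ZERO_PHYSIO, seed=5)
        r2 = simulate_subject(double, small_layout, short_schedule, ZERO_PHYSIO, seed=5)
        np.testing.assert_allclose(
            r2.ground_truth.cerebral_hbo, 2.0 * r1.ground_truth.cerebral_hbo,
            rtol=1e-12, atol=0
        )

    def test_depth_variance_ratio_increases_with_separation(
        self, small_layout, short_schedule, small_study_config
    ):
        # expected cerebral-to-superficial variance ratio non-decreasing in class
        ratios = {s: [] for s in (1.5, 2.12, 3.0, 3.35)}
        for seed in range(20):
            prof = draw_profile(
                "student", f"S{seed:02d}", small_study_config,
                np.random.default_rng(100 + seed)
            )
            rec = simulate_subject(prof, small_layout, short_schedule, seed=seed)
            gt = rec.ground_truth
            for s, acc in ratios.items():
                idx = small_layout.class_indices(s)
                acc.append(
                    gt.cerebral_hbo[:, idx].var(axis=0).mean()
                    / gt.superficial_hbo[:, idx].var(axis=0).mean()
                )
        means = [np.mean(ratios[s]) for s in (1.5, 2.12, 3.0, 3.35)]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_mixing_equation_conservation(self, simulated_subject, small_layout):
        gt = simulated_subject.ground_truth
        clean_hbo = gt.cerebral_hbo + gt.superficial_hbo + gt.drift_hbo
        clean_hbr = -gt.hbr_ratio * gt.cerebral_hbo
        explained = forward_mbll(clean_hbo, clean_hbr, small_layout.separations)
        residual = simulated_subject.od - explained
        expected = forward_mbll(gt.noise_hbo, gt.noise_hbr, small_layout.separations)
        expected = expected + gt.motion_od
        np.testing.assert_allclose(residual, expected, rtol=1e-9, atol=1e-12)

    def test_component_frequencies_below_nyquist(self):
        phys = PhysioConfig()
        assert all(f < 8.138 / 2 for f in phys.osc_freqs_hz)
        with pytest.raises(Exception):
            PhysioConfig(osc_freqs_hz=(0.1, 5.0)).validate(8.138)

    def test_nonfinite_config_rejected(self, small_layout, short_schedule):
        bad = PhysioConfig(noise_sd_um=float("nan"))
        with pytest.raises(Exception):
            simulate_subject(silent_profile(), small_layout, short_schedule, bad, seed=0)

    def test_motion_events_visible_in_both_od_and_sensors(
        self, small_layout, short_schedule
    ):
        prof = silent_profile(motion=6.0)
        rec = simulate_subject(prof, small_layout, short_schedule, ZERO_PHYSIO, seed=11)
        assert np.any(rec.ground_truth.motion_od != 0)
        assert np.any(rec.motion != 0)
        # events are concurrent: OD excursions and sensor bumps share samples
        od_active = np.abs(rec.ground_truth.motion_od).max(axis=(1, 2)) > 0
        sensor_active = np.abs(rec.motion).max(axis=1) > 0
        overlap = (od_active & sensor_active).sum() / max(od_active.sum(), 1)
        assert overlap > 0.5


class TestGenerateTLX:
    def test_monotone_link_preserves_order(self):
        profiles = [
            replace(silent_profile(f"S{i}"), latent_load=load)
            for i, load in enumerate([-1.0, 0.0, 1.0])
        ]
        from nirsload.synthetic import TLXLink

        link = TLXLink(noise_sd=0.0)
        scores = [generate_tlx(p, "task1", seed=0, link=link).mean_score
                  for p in profiles]
        assert scores[0] < scores[1] < scores[2]

    def test_clipping_to_scale_bounds(self):
        p = replace(silent_profile(), latent_load=100.0)
        rec = generate_tlx(p, "task1", seed=0)
        assert rec.subscales == tuple([20.0] * 6)
        assert rec.mean_score == 20.0
        p = replace(silent_profile(), latent_load=-100.0)
        rec = generate_tlx(p, "task1", seed=0)
        assert rec.subscales == tuple([1.0] * 6)

    def test_subscales_within_bounds(self):
        for seed in range(30):
            p = replace(silent_profile(), latent_load=float(np.random.default_rng(seed).normal()))
            rec = generate_tlx(p, "task1", seed=seed)
            assert all(1.0 <= s <= 20.0 for s in rec.subscales)
            assert rec.mean_score == pytest.approx(np.mean(rec.subscales))

    @pytest.mark.parametrize("group,sign", [("student", 1), ("attending", -1)])
    def test_cohort_level_correlation_sign(self, group, sign):
        cfg = StudyConfig()
        amps, scores = [], []
        for i in range(200):
            p = draw_profile(group, f"X{i}", cfg, np.random.default_rng(3000 + i))
            t = generate_tlx(p, "task1", seed=4000 + i, link=cfg.tlx)
            amps.append(p.mean_cerebral_amplitude)
            scores.append(t.mean_score)
        r = np.corrcoef(amps, scores)[0, 1]
        assert sign * r > 0.3
        assert p.tlx_link_sign == sign


class TestSimulateCohort:
    def test_default_counts(self, small_study_config):
        cohort = simulate_cohort(small_study_config, seed=0)
        assert len(cohort.recordings) == 8
        assert len(cohort.tlx) == 16  # two task episodes per subject
        cfg = StudyConfig()
        assert cfg.n_students == 17 and cfg.n_attendings == 11

    def test_same_seed_is_deterministic(self, small_study_config):
        c1 = simulate_cohort(small_study_config, seed=9)
        c2 = simulate_cohort(small_study_config, seed=9)
        for r1, r2 in zip(c1.recordings, c2.recordings):
            np.testing.assert_array_equal(r1.od, r2.od)
            np.testing.assert_array_equal(r1.motion, r2.motion)
        assert c1.truth.equals(c2.truth)
        assert [t.subscales for t in c1.tlx] == [t.subscales for t in c2.tlx]

    def test_different_seed_differs(self, small_study_config):
        c1 = simulate_cohort(small_study_config, seed=1)
        c2 = simulate_cohort(small_study_config, seed=2)
        assert not np.array_equal(c1.recordings[0].od, c2.recordings[0].od)

    def test_small_group_warns(self, small_study_config):
        cfg = replace(small_study_config, n_attendings=1)
        with pytest.warns(UserWarning, match="group size"):
            simulate_cohort(cfg, seed=0)

    def test_student_mean_amplitude_exceeds_attending(self, small_study_config):
        cohort = simulate_cohort(replace(small_study_config, n_students=8,
                                         n_attendings=8), seed=4)
        t = cohort.truth
        s = t[t.group == "student"]["mean_cerebral_amplitude_um"].mean()
        a = t[t.group == "attending"]["mean_cerebral_amplitude_um"].mean()
        assert s > a

    def test_left_lateralized_student_amplitude(self, small_study_config):
        prof = draw_profile("student", "S01", small_study_config,
                            np.random.default_rng(0))
        left = np.mean([v for (r, h), v in prof.cerebral_amplitude.items() if h == "L"])
        right = np.mean([v for (r, h), v in prof.cerebral_amplitude.items() if h == "R"])
        assert left > right
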