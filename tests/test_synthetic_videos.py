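"""Surrogate clip generator: motion statistics, determinism, cohort layout."""

import numpy as np
import pytest

from gaborgist import (
    SynthConfig,
    generate_abnormal_clip,
    generate_cohort,
    generate_normal_clip,
)


def heading_changes(traj):
    """Absolute wrapped frame-to-frame heading change from the trajectory log."""
    dh = np.diff(traj.heading.to_numpy())
    return np.abs(np.angle(np.exp(1j * dh)))


class TestNormalClip:
    def test_static_scene_when_motionless(self):
        cfg = SynthConfig(frame_size=(48, 64), n_frames=12, speed=0.0,
                          noise_sd=0.0, heading_sd=0.0, illum_drift=0.0)
        vol = generate_normal_clip(cfg, seed=4)
        assert np.abs(np.diff(vol.data, axis=2)).max() == 0.0

    def test_same_seed_reproduces_volume(self, small_config):
        v1 = generate_normal_clip(small_config, seed=11)
        v2 = generate_normal_clip(small_config, seed=11)
        np.testing.assert_array_equal(v1.data, v2.data)

    def test_different_seeds_differ(self, small_config):
        v1 = generate_normal_clip(small_config, seed=11)
        v2 = generate_normal_clip(small_config, seed=12)
        assert not np.array_equal(v1.data, v2.data)

    @pytest.mark.parametrize("seed", [3, 7, 21])
    def test_heading_change_bounded_by_cap(self, seed):
        cfg = SynthConfig(frame_size=(128, 160), n_frames=200)
        clip = generate_normal_clip(cfg, seed=seed, with_log=True)
        t = clip.trajectory
        smooth = ~(t.jerk | t.frozen | t.clamped).to_numpy()[1:]
        assert heading_changes(t)[smooth].max() <= cfg.heading_cap + 1e-9

    def test_volume_satisfies_invariants(self, small_config):
        vol = generate_normal_clip(small_config, seed=2)
        assert vol.shape == (*small_config.frame_size, small_config.n_frames)
        assert np.all(np.isfinite(vol.data))
        assert vol.data.min() >= 0.0 and vol.data.max() <= 1.0


class TestAbnormalClip:
    def test_degenerates_to_normal_without_jerks_and_freezes(self):
        cfg = SynthConfig(frame_size=(48, 64), n_frames=60,
                          jerk_rate=0.0, freeze_prob=0.0)
        v_norm = generate_normal_clip(cfg, seed=9)
        v_abn = generate_abnormal_clip(cfg, seed=9)
        np.testing.assert_array_equal(v_norm.data, v_abn.data)

    @pytest.mark.parametrize("seed", [1, 5, 13])
    def test_contains_abrupt_reversal(self, seed):
        cfg = SynthConfig(frame_size=(128, 160), n_frames=200, jerk_rate=20.0)
        clip = generate_abnormal_clip(cfg, seed=seed, with_log=True)
        t = clip.trajectory
        assert t.jerk.sum() >= 1
        # on some jerk frame the logged heading jumps by at least 90 degrees
        dh = heading_changes(t)
        jerk_frames = np.flatnonzero(t.jerk.to_numpy()[1:])
        assert dh[jerk_frames].max() >= np.pi / 2 - 1e-9

    def test_frozen_runs_have_constant_position(self):
        cfg = SynthConfig(frame_size=(128, 160), n_frames=300,
                          freeze_prob=0.1, freeze_len_frames=10)
        clip = generate_abnormal_clip(cfg, seed=8, with_log=True)
        t = clip.trajectory
        assert t.frozen.sum() > 0
        frozen = t.frozen.to_numpy()
        x, y = t.x.to_numpy(), t.y.to_numpy()
        # every frozen frame keeps the position of the preceding frame
        idx = np.flatnonzero(frozen[1:]) + 1
        np.testing.assert_array_equal(x[idx], x[idx - 1])
        np.testing.assert_array_equal(y[idx], y[idx - 1])

    def test_jerk_and_freeze_rates_match_configuration(self):
        """Monte-Carlo check of the logged event statistics (3 sigma)."""
        cfg = SynthConfig(frame_size=(128, 160), n_frames=400,
                          jerk_rate=10.0, freeze_prob=0.03, freeze_len_frames=8)
        jerks, moving_frames, entries, eligible = 0, 0, 0, 0
        for seed in range(12):
            t = generate_abnormal_clip(cfg, seed=seed, with_log=True).trajectory
            frozen = t.frozen.to_numpy()
            jerks += int(t.jerk.sum())
            moving_frames += int((~frozen).sum())
            starts = np.flatnonzero(frozen[1:] & ~frozen[:-1]) + 1
            entries += len(starts) + int(frozen[0])
            eligible += int((~frozen).sum())
        p_jerk = jerks / moving_frames
        assert abs(p_jerk - 0.10) < 3 * np.sqrt(0.1 * 0.9 / moving_frames)
        p_freeze = entries / eligible
        assert abs(p_freeze - 0.03) < 3 * np.sqrt(0.03 * 0.97 / eligible)

    def test_abnormal_motion_is_more_localized(self):
        """Reversals and freezes anchor the abnormal blob near its rest point."""
        cfg = SynthConfig(frame_size=(128, 160), n_frames=250)
        rg = {}
        for name, gen in (("normal", generate_normal_clip),
                          ("abnormal", generate_abnormal_clip)):
            spreads = []
            for seed in range(5):
                t = gen(cfg, seed=seed, with_log=True).trajectory
                spreads.append(np.sqrt(t.x.var() + t.y.var()))
            rg[name] = np.mean(spreads)
        assert rg["abnormal"] < 0.6 * rg["normal"]


class TestNuisanceFactors:
    def test_illumination_drift_moves_background(self):
        base = dict(frame_size=(48, 64), n_frames=40, speed=0.0,
                    noise_sd=0.0, heading_sd=0.0)
        flat = generate_normal_clip(SynthConfig(**base), seed=3)
        lit = generate_normal_clip(SynthConfig(**base, illum_drift=0.1), seed=3)
        corner = (slice(0, 4), slice(0, 4))  # away from the central blob
        assert np.ptp(lit.data[corner]) > 0.05
        assert np.ptp(flat.data[corner]) == 0.0

    def test_distractors_add_extra_bright_regions(self):
        cfg = SynthConfig(frame_size=(96, 128), n_frames=10, noise_sd=0.0)
        with_d = generate_normal_clip(
            SynthConfig(frame_size=(96, 128), n_frames=10, noise_sd=0.0,
                        n_distractors=2), seed=6)
        without = generate_normal_clip(cfg, seed=6)
        assert with_d.data.sum() > without.data.sum()


class TestCohort:
    def test_counts_and_patient_ids(self, small_config):
        cohort = generate_cohort(9, 5, 0.5, small_config, seed=1)
        assert len(cohort) == 45
        assert len({c.volume.patient_id for c in cohort}) == 9

    def test_abnormal_fraction(self, small_config):
        cohort = generate_cohort(4, 6, 0.5, small_config, seed=2)
        n_abn = sum(c.annotation.label == "abnormal" for c in cohort)
        assert n_abn == round(0.5 * len(cohort))
        # balanced within each patient as well
        for pid in {c.volume.patient_id for c in cohort}:
            labels = [c.annotation.label for c in cohort if c.volume.patient_id == pid]
            assert labels.count("abnormal") == 3

    def test_deterministic_given_seed(self, small_config):
        c1 = generate_cohort(2, 3, 0.5, small_config, seed=5)
        c2 = generate_cohort(2, 3, 0.5, small_config, seed=5)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.volume.data, b.volume.data)
            assert a.annotation == b.annotation

    def test_per_patient_appearance_varies(self, small_config):
        cohort = generate_cohort(4, 2, 0.0, small_config, seed=3)
        backgrounds = {
            round(float(np.median(c.volume.data)), 4) for c in cohort
        }
        assert len(backgrounds) > 1

    def test_invalid_fraction_rejected(self, small_config):
        with pytest.raises(ValueError, match="fraction"):
            generate_cohort(2, 2, 1.5, small_config, seed=0)

    def test_single_clip_patient_rejected(self, small_config):
        with pytest.raises(ValueError, match="clips_per_patient"):
            generate_cohort(2, 1, 0.5, small_config, seed=0)


class TestSaveCohort:
    def test_writes_frames_annotations_and_trajectories(self, tmp_path):
        cfg = SynthConfig(frame_size=(24, 32), n_frames=4, blob_radius=4.0)
        cohort = generate_cohort(2, 2, 0.5, cfg, seed=7)
        from gaborgist import save_cohort

        save_cohort(cohort, tmp_path)
        assert (tmp_path / "annotations.csv").exists()
        for clip in cohort:
            d = tmp_path / clip.volume.clip_id
            assert len(list(d.glob("frame*.png"))) == 4
            assert (d / "trajectory.csv").exists()

    def test_saved_cohort_reloads_through_video_io(self, tmp_path):
        from gaborgist import load_video, read_annotations, save_cohort

        cfg = SynthConfig(frame_size=(24, 32), n_frames=3, blob_radius=4.0)
        cohort = generate_cohort(1, 2, 0.5, cfg, seed=7)
        save_cohort(cohort, tmp_path)
        records = read_annotations(tmp_path / "annotations.csv")
        assert len(records) == 2
        vol = load_video(tmp_path / records[0].clip, target_size=(24, 32))
        np.testing.assert_allclose(
            vol.data, cohort[0].volume.data, atol=1 / 255 + 1e-12
        )
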