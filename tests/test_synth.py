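"""Generator properties: determinism, protocol regime, ground-truth fidelity."""

import numpy as np
import pytest
from scipy import stats

from gaitshift.io import G
from gaitshift.pipeline import load_cohort_dir
from gaitshift.synth import (SynthSubjectConfig, make_cohort, make_cycle_bank,
                             make_koos, make_subject, write_cohort)


class TestDeterminism:
    def test_same_seed_gives_bit_identical_subject(self):
        cfg = SynthSubjectConfig(seed=5, shift_delta=0.1)
        s1, k1, t1 = make_subject(cfg)
        s2, k2, t2 = make_subject(cfg)
        for kind in s1:
            np.testing.assert_array_equal(
                s1[kind].recordings["shank"].accel,
                s2[kind].recordings["shank"].accel)
            np.testing.assert_array_equal(
                s1[kind].recordings["foot"].gyro, s2[kind].recordings["foot"].gyro)
        assert k1 == k2
        np.testing.assert_array_equal(t1.ic_idx["post"], t2.ic_idx["post"])

    def test_same_seed_gives_identical_cycle_bank(self):
        cfg = SynthSubjectConfig(seed=5)
        a = make_cycle_bank(cfg, "baseline1", 20)
        b = make_cycle_bank(cfg, "baseline1", 20)
        np.testing.assert_array_equal(a.X, b.X)

    def test_different_sessions_differ(self):
        cfg = SynthSubjectConfig(seed=5)
        sessions, _, _ = make_subject(cfg)
        assert not np.array_equal(sessions["baseline1"].recordings["back"].accel,
                                  sessions["baseline2"].recordings["back"].accel)


class TestProtocolRegime:
    def test_session_has_about_135_strides(self, default_subject):
        _, _, _, truth = default_subject
        for kind in ("baseline1", "baseline2", "post"):
            n = len(truth.ic_idx[kind]) - 1
            assert 125 <= n <= 145

    def test_ground_truth_stance_fraction_near_sixty_percent(self, default_subject):
        _, _, _, truth = default_subject
        sf = truth.stance_fracs["baseline1"]
        assert abs(np.mean(sf) - 0.60) < 0.02

    def test_static_window_is_at_rest_near_one_g(self, default_subject):
        _, sessions, _, _ = default_subject
        rec = sessions["baseline1"].recordings["shank"]
        mean = rec.accel[10:190].mean(axis=0)
        assert np.linalg.norm(mean) == pytest.approx(G, rel=0.02)

    def test_mounting_tilt_is_applied(self, default_subject):
        _, sessions, _, _ = default_subject
        rec = sessions["baseline1"].recordings["shank"]
        mean = rec.accel[10:190].mean(axis=0)
        tilt = np.degrees(np.arccos(mean[2] / np.linalg.norm(mean)))
        assert 0.5 < tilt < 15.0

    def test_event_truth_is_strictly_increasing(self, default_subject):
        _, _, _, truth = default_subject
        for kind, idx in truth.ic_idx.items():
            assert np.all(np.diff(idx) > 0)


class TestInterventionEffect:
    def test_shift_increases_distance_from_baseline_monotonically(self):
        base_mean = make_cycle_bank(SynthSubjectConfig(seed=8), "baseline1",
                                    80).X.mean(axis=0)
        dists = []
        for delta in [0.0, 0.1, 0.2, 0.4]:
            cfg = SynthSubjectConfig(seed=8, shift_delta=delta)
            post = make_cycle_bank(cfg, "post", 80)
            dists.append(np.mean(np.linalg.norm(post.X - base_mean, axis=1)))
        assert all(b > a for a, b in zip(dists, dists[1:]))

    def test_null_post_cycles_exchangeable_with_baseline(self):
        # per-cycle distance to the pooled centroid should not separate the
        # groups when no shift is injected (day effects are far below noise)
        rejections = 0
        for seed in range(5):
            cfg = SynthSubjectConfig(seed=4000 + seed, shift_delta=0.0)
            base = make_cycle_bank(cfg, "baseline1", 100).X
            post = make_cycle_bank(cfg, "post", 100).X
            centroid = np.vstack([base, post]).mean(axis=0)
            db = np.linalg.norm(base - centroid, axis=1)
            dp = np.linalg.norm(post - centroid, axis=1)
            if stats.mannwhitneyu(db, dp).pvalue < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_koos_gain_tracks_shift_and_stays_in_range(self):
        pre0, post0 = make_koos(SynthSubjectConfig(seed=3, shift_delta=0.0))
        pre1, post1 = make_koos(SynthSubjectConfig(seed=3, shift_delta=0.25))
        gain0 = np.mean(post0.subscales() - pre0.subscales())
        gain1 = np.mean(post1.subscales() - pre1.subscales())
        assert gain1 > gain0 + 10
        for r in (pre0, post0, pre1, post1):
            assert np.all((r.subscales() >= 0) & (r.subscales() <= 100))


class TestCohort:
    def test_cohort_is_deterministic_and_graded(self):
        a = make_cohort(n_subjects=4, deltas=[0, 0.1, 0.2, 0.3], seed=9,
                        session_minutes=0.3)
        b = make_cohort(n_subjects=4, deltas=[0, 0.1, 0.2, 0.3], seed=9,
                        session_minutes=0.3)
        np.testing.assert_array_equal(
            a[2].sessions["post"].recordings["back"].accel,
            b[2].sessions["post"].recordings["back"].accel)
        assert [x.truth.shift_delta for x in a] == [0, 0.1, 0.2, 0.3]

    def test_mismatched_deltas_rejected(self):
        with pytest.raises(ValueError, match="deltas"):
            make_cohort(n_subjects=3, deltas=[0.0, 0.1])

    def test_write_and_reload_cohort_directory(self, tmp_path):
        bundles = make_cohort(n_subjects=1, deltas=[0.1], seed=2,
                              session_minutes=0.3)
        write_cohort(bundles, tmp_path / "cohort")
        sessions, koos = load_cohort_dir(tmp_path / "cohort")
        sid = bundles[0].koos_pre.subject_id
        assert set(sessions[sid]) == {"baseline1", "baseline2", "post"}
        np.testing.assert_allclose(
            sessions[sid]["post"].recordings["foot"].gyro,
            bundles[0].sessions["post"].recordings["foot"].gyro,
            rtol=1e-6, atol=1e-6)
        assert koos[sid][0] == bundles[0].koos_pre
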