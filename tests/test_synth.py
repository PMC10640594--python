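"""Synthetic generators: determinism, calibration, and ground truth."""

import numpy as np
import pytest

from graftdyn.preprocess import segment_trials
from graftdyn.synth import (FlowVideoSpec, TaskSessionSpec, gen_acs_session,
                            gen_behavior_summary, gen_cell_positions,
                            gen_flow_video, gen_multisession,
                            gen_task_session, vessel_lumen_mask)


class TestTaskSession:
    def test_deterministic_under_seed(self):
        spec = TaskSessionSpec(n_cells=10, n_trials=5, seed=7)
        a, ga = gen_task_session(spec)
        b, gb = gen_task_session(TaskSessionSpec(n_cells=10, n_trials=5, seed=7))
        np.testing.assert_array_equal(a.traces, b.traces)
        np.testing.assert_array_equal(a.residuals, b.residuals)
        assert a.events.equals(b.events)
        np.testing.assert_array_equal(ga.modulated_ids, gb.modulated_ids)

    def test_no_sources_gives_flat_zero_traces(self):
        spec = TaskSessionSpec(n_cells=1, n_trials=2, frac_modulated=0.0,
                               noise_sd=0.0, resid_sd=0.0)
        rec, _ = gen_task_session(spec)
        np.testing.assert_array_equal(rec.traces, 0.0)

    def test_shared_variance_oracle_eigendecomposition(self):
        # rank-q best approximation of the task-window sample covariance
        spec = TaskSessionSpec(n_cells=50, n_trials=40, shared_frac=0.6, seed=3)
        rec, _ = gen_task_session(spec)
        tens = segment_trials(rec, "pellet_touch", (2.5, 2.5))
        X = tens.data.reshape(50, -1)
        ev = np.sort(np.linalg.eigvalsh(np.cov(X)))[::-1]
        frac = ev[:2].sum() / ev.sum()
        assert 0.55 <= frac <= 0.65

    def test_modulated_scope_requires_modulated_cells(self):
        with pytest.raises(ValueError, match="modulated"):
            gen_task_session(TaskSessionSpec(frac_modulated=0.0,
                                             shared_frac=0.5,
                                             factor_scope="modulated"))

    def test_modulated_cells_peak_in_task_window(self):
        spec = TaskSessionSpec(n_cells=30, frac_modulated=0.5,
                               transient_amp=6.0, seed=1)
        rec, gt = gen_task_session(spec)
        tens = segment_trials(rec, "pellet_touch", (2.5, 2.5))
        avg = tens.data.mean(axis=1)
        mod = gt.modulated_ids
        others = np.setdiff1d(np.arange(30), mod)
        # trial-averaged peak of modulated cells clearly above non-modulated
        assert avg[mod].max(axis=1).min() > avg[others].max(axis=1).mean() + 1.0
        assert np.all(np.abs(gt.latencies_s[mod]) <= 2.5)

    def test_sequential_latencies_spread(self):
        spec = TaskSessionSpec(n_cells=100, frac_modulated=1.0,
                               latency_spread_s=0.4, seed=2)
        _, gt = gen_task_session(spec)
        assert np.std(gt.latencies_s) > 0.1  # cells tile distinct latencies

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TaskSessionSpec(frac_modulated=1.5)
        with pytest.raises(ValueError):
            TaskSessionSpec(n_trials=1)
        with pytest.raises(ValueError):
            TaskSessionSpec(shared_frac=1.0)


class TestACSSession:
    def test_block_and_onset_structure(self):
        session, gt = gen_acs_session(n_cells=5, seed=0)
        assert session.duration_s == 900.0
        assert len(session.stim_onsets_s) == 20
        np.testing.assert_allclose(np.diff(session.stim_onsets_s), 15.0)
        assert session.stim_onsets_s[0] == 300.0
        assert session.stim_onsets_s[-1] + 15.0 <= 600.0

    def test_no_responders_flat_onset_average(self):
        session, _ = gen_acs_session(n_cells=20, frac_responsive=0.0,
                                     frac_post_suppressed=0.0,
                                     bg_event_rate_hz=0.0, seed=1)
        idx = (session.stim_onsets_s[:, None] * 10).astype(int) + np.arange(50)
        on = session.traces[:, idx].mean()
        off = session.traces.mean()
        assert abs(on - off) < 0.05

    def test_deterministic(self):
        a, _ = gen_acs_session(n_cells=8, seed=9)
        b, _ = gen_acs_session(n_cells=8, seed=9)
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_post_suppression_reduces_events(self):
        _, gt = gen_acs_session(n_cells=30, frac_responsive=0.0,
                                frac_post_suppressed=1.0, seed=2)
        pre = np.mean([np.sum(t < 300) for t in gt.event_times])
        post = np.mean([np.sum(t >= 600) for t in gt.event_times])
        assert post < 0.5 * pre


class TestMultisession:
    def test_identity_when_no_jitter_full_retention(self, rng):
        base = rng.uniform(10, 90, (20, 2))
        maps, gt = gen_multisession(base, 3, jitter_px=0.0, retention_frac=1.0,
                                    new_frac=0.0, fov_shape=(100, 100), seed=0)
        for s, m in enumerate(maps):
            ident = gt.session_identity[s]
            np.testing.assert_allclose(m.centroids[ident], base)

    def test_three_session_retention_binomial(self, rng):
        base = rng.uniform(10, 190, (400, 2))
        _, gt = gen_multisession(base, 3, retention_frac=0.3,
                                 fov_shape=(200, 200), seed=1)
        present = np.all([ident >= 0 for ident in gt.session_identity], axis=0)
        p = 0.3 ** 3
        se = np.sqrt(p * (1 - p) / 400)
        assert abs(present.mean() - p) < 3.5 * se

    def test_seeded_reproducible(self, rng):
        base = rng.uniform(10, 90, (15, 2))
        a, _ = gen_multisession(base, 2, seed=4, fov_shape=(100, 100))
        b, _ = gen_multisession(base, 2, seed=4, fov_shape=(100, 100))
        np.testing.assert_array_equal(a[1].centroids, b[1].centroids)


class TestFlowVideo:
    def test_zero_speed_frames_identical(self):
        spec = FlowVideoSpec(speed_um_per_s=0.0, n_frames=5, noise_sd=0.0,
                             shape_px=(20, 60))
        frames, _ = gen_flow_video(spec)
        for f in range(1, 5):
            np.testing.assert_array_equal(frames[f], frames[0])

    def test_displacement_kinematics(self):
        spec = FlowVideoSpec(speed_um_per_s=1000.0, rate_hz=60.0,
                             pixel_size_um=2.0, n_frames=2)
        _, gt = gen_flow_video(spec)
        assert abs(gt.displacement_px_per_frame - 1000.0 / 60.0 / 2.0) < 1e-12

    def test_deterministic(self):
        spec = FlowVideoSpec(n_frames=3, shape_px=(20, 60), seed=5)
        a, _ = gen_flow_video(spec)
        b, _ = gen_flow_video(FlowVideoSpec(n_frames=3, shape_px=(20, 60), seed=5))
        np.testing.assert_array_equal(a, b)

    def test_polyline_must_fit_frame(self):
        with pytest.raises(ValueError, match="polyline"):
            FlowVideoSpec(shape_px=(20, 60),
                          vessel_polyline=np.array([[0.0, 10.0], [100.0, 10.0]]))

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            FlowVideoSpec(speed_um_per_s=-1.0)


class TestCellPositions:
    @staticmethod
    def _mask():
        mask = np.zeros((300, 475), dtype=bool)
        mask[148:153, :] = True
        return mask

    def test_zero_distance_on_mask(self):
        cents, gt = gen_cell_positions(30, self._mask(), 0.0, 2.0, seed=0)
        assert gt.distances_um.max() <= 2.0 * 0.75  # within sub-pixel jitter

    def test_uniform_order_statistics(self):
        cents, gt = gen_cell_positions(500, self._mask(), 76.2, 2.0, seed=1)
        p95 = np.percentile(gt.distances_um, 95)
        assert abs(p95 - 0.95 * 76.2) < 5.0

    def test_unreachable_distance_errors(self):
        small = np.zeros((20, 20), dtype=bool)
        small[10, 10] = True
        with pytest.raises(ValueError, match="larger field"):
            gen_cell_positions(5, small, 500.0, 2.0)

    def test_seeded_reproducible(self):
        a, _ = gen_cell_positions(10, self._mask(), 30.0, 2.0, seed=3)
        b, _ = gen_cell_positions(10, self._mask(), 30.0, 2.0, seed=3)
        np.testing.assert_array_equal(a, b)


def test_behavior_summary_ranges():
    df = gen_behavior_summary(n_mice=4, n_sessions=6, seed=0)
    assert len(df) == 24
    for col in ("success_rate", "attempt_rate", "proportion_modulated"):
        assert df[col].between(0, 1).all()


def test_lumen_mask_width():
    spec = FlowVideoSpec(shape_px=(40, 200), vessel_width_um=10.0,
                         pixel_size_um=2.0)
    mask = vessel_lumen_mask(spec)
    cols = mask.sum(axis=0)
    assert 4 <= np.median(cols) <= 6  # ~10 um / 2 um per px
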