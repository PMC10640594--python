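"""Trial segmentation, baseline correction, normalization and binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftdyn.preprocess import (SessionRecording, TrialTensor,
                                 baseline_correct, bin_trials,
                                 minmax_normalize, segment_residuals,
                                 segment_trials)
from graftdyn.synth import TaskSessionSpec, gen_task_session


def make_rec(n_cells=3, n_trials=4, rate=10.0, spacing=15.0, seed=0):
    rng = np.random.default_rng(seed)
    touch = 10.0 + spacing * np.arange(n_trials)
    T = int((touch[-1] + 10.0) * rate)
    rows = []
    for k, t in enumerate(touch):
        rows += [(k, "door_open", t - 1.0), (k, "pellet_touch", t),
                 (k, "door_close", t + 2.0)]
    return SessionRecording(
        traces=rng.normal(size=(n_cells, T)),
        residuals=rng.normal(size=(n_cells, T)), rate_hz=rate,
        events=pd.DataFrame(rows, columns=["trial", "event", "time_s"]))


class TestSegmentTrials:
    def test_sample_count_from_rate_and_window(self):
        tens = segment_trials(make_rec(), "pellet_touch", (5.0, 5.0))
        assert tens.data.shape == (3, 4, 100)

    def test_out_of_bounds_trial_dropped(self):
        rec = make_rec()
        rec.events.loc[rec.events.trial == 0, "time_s"] -= 8.0  # touch at 2 s
        tens = segment_trials(rec, "pellet_touch", (5.0, 5.0))
        assert tens.data.shape[1] == 3
        assert 0 not in tens.trial_ids

    def test_75_trial_session(self):
        tens = segment_trials(make_rec(n_trials=75), "pellet_touch", (2.5, 2.5))
        assert tens.data.shape[1] == 75

    def test_no_usable_trials_errors_naming_event(self):
        rec = make_rec(n_trials=2)
        with pytest.raises(ValueError, match="pellet_touch"):
            segment_trials(rec, "pellet_touch", (50.0, 50.0))

    def test_alignment_is_exact(self):
        rec = make_rec()
        t0 = float(rec.event_times("pellet_touch").iloc[0])
        tens = segment_trials(rec, "pellet_touch", (1.0, 1.0))
        i0 = int(t0 * rec.rate_hz)
        np.testing.assert_array_equal(tens.data[:, 0, :],
                                      rec.traces[:, i0 - 10:i0 + 10])


def _tensor(data, rate=10.0, window=(5.0, 5.0)):
    return TrialTensor(data=data, align_event="pellet_touch",
                       window_s=window, rate_hz=rate)


class TestBaselineCorrect:
    def test_unit_residual_sd_is_identity(self):
        data = np.arange(2 * 3 * 100, dtype=float).reshape(2, 3, 100)
        resid = np.tile([1.0, -1.0], 50)[None, None, :] * np.ones((2, 3, 100))
        out = baseline_correct(_tensor(data), _tensor(resid))
        np.testing.assert_allclose(out.data, data)

    def test_scalar_division(self):
        data = np.full((1, 2, 100), 4.0)
        resid = np.tile([2.0, -2.0], 50)[None, None, :] * np.ones((1, 2, 100))
        out = baseline_correct(_tensor(data), _tensor(resid))
        np.testing.assert_allclose(out.data, 2.0)

    def test_zero_residual_errors_with_cells(self):
        data = np.ones((2, 2, 100))
        resid = np.ones((2, 2, 100))  # constant -> SD 0
        with pytest.raises(ValueError, match="cells"):
            baseline_correct(_tensor(data), _tensor(resid))

    def test_linear_in_trace(self, rng):
        data = rng.normal(size=(3, 4, 100))
        resid = rng.normal(size=(3, 4, 100))
        a = baseline_correct(_tensor(data), _tensor(resid)).data
        b = baseline_correct(_tensor(3.5 * data), _tensor(resid)).data
        np.testing.assert_allclose(b, 3.5 * a, rtol=1e-12)

    @pytest.mark.parametrize("trial_pooled", [True, False])
    def test_matches_nested_loop_oracle(self, trial_pooled):
        spec = TaskSessionSpec(n_cells=10, n_trials=6, seed=5)
        rec, _ = gen_task_session(spec)
        tens = segment_trials(rec, "pellet_touch", (5.0, 5.0))
        resid = segment_residuals(rec, "pellet_touch", (5.0, 5.0))
        out = baseline_correct(tens, resid, trial_pooled=trial_pooled).data

        times = tens.times_s
        sel = [k for k in range(len(times)) if -5.0 <= times[k] < -4.0]
        n, n_tr, m = tens.data.shape
        expected = np.empty_like(tens.data)
        for c in range(n):
            sds = []
            for tr in range(n_tr):
                vals = [resid.data[c, tr, k] for k in sel]
                mu = sum(vals) / len(vals)
                sds.append(np.sqrt(sum((v - mu) ** 2 for v in vals) / len(vals)))
            for tr in range(n_tr):
                b = sum(sds) / len(sds) if trial_pooled else sds[tr]
                for k in range(m):
                    expected[c, tr, k] = tens.data[c, tr, k] / b
        assert np.max(np.abs(out - expected)) < 1e-12

    def test_baseline_window_must_fit(self):
        data = np.ones((1, 2, 20))
        with pytest.raises(ValueError, match="baseline window"):
            baseline_correct(_tensor(data, window=(1.0, 1.0)),
                             _tensor(data, window=(1.0, 1.0)))


class TestMinmaxNormalize:
    def test_basic(self):
        np.testing.assert_allclose(minmax_normalize(np.array([[1.0, 2.0, 3.0]])),
                                   [[0.0, 0.5, 1.0]])

    def test_constant_cell_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(np.array([[5.0, 5.0, 5.0]]))
        np.testing.assert_array_equal(out, [[0.0, 0.0, 0.0]])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent(self, seed):
        x = np.random.default_rng(seed).normal(size=(3, 17))
        once = minmax_normalize(x)
        np.testing.assert_allclose(minmax_normalize(once), once, atol=1e-12)

    def test_range_is_unit(self, rng):
        out = minmax_normalize(rng.normal(size=(4, 50)))
        np.testing.assert_allclose(out.min(axis=1), 0.0)
        np.testing.assert_allclose(out.max(axis=1), 1.0)


class TestBinTrials:
    def test_five_samples_per_bin_at_10hz(self, rng):
        data = rng.normal(size=(2, 3, 100))
        out = bin_trials(_tensor(data), 0.5)
        assert out.data.shape == (2, 3, 20)
        np.testing.assert_allclose(out.data[0, 0, 0], data[0, 0, :5].mean())

    def test_constant_trace_constant_bins(self):
        out = bin_trials(_tensor(np.full((1, 2, 100), 7.0)), 0.5)
        np.testing.assert_allclose(out.data, 7.0)

    def test_nested_loop_oracle(self, rng):
        data = rng.normal(size=(3, 4, 100))
        out = bin_trials(_tensor(data), 0.5).data
        for c in range(3):
            for tr in range(4):
                for b in range(20):
                    expected = sum(data[c, tr, 5 * b + k] for k in range(5)) / 5
                    assert abs(out[c, tr, b] - expected) < 1e-12

    def test_mean_preserved_exactly(self, rng):
        data = rng.normal(size=(2, 3, 100))
        out = bin_trials(_tensor(data), 0.5)
        np.testing.assert_allclose(out.data.mean(axis=2), data.mean(axis=2),
                                   rtol=1e-12)

    def test_indivisible_window_errors(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            bin_trials(_tensor(np.zeros((1, 2, 100))), 0.3)

    def test_commutes_with_trial_reorder(self, rng):
        data = rng.normal(size=(2, 5, 100))
        perm = [3, 1, 4, 0, 2]
        a = bin_trials(_tensor(data), 0.5).data[:, perm]
        b = bin_trials(_tensor(data[:, perm]), 0.5).data
        np.testing.assert_array_equal(a, b)
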