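"""Stimulation blocks, modulation tests, deconvolution, event classes."""

import numpy as np
import pytest

from graftdyn.stim import (ACSSession, acs_anova_modulation,
                           amplitude_modulation, analyze_acs_session,
                           classify_event_ratio, count_block_events,
                           deconvolve_events, quadrant_classify,
                           segment_blocks)
from graftdyn.synth import gen_acs_session


def make_session(traces, rate=10.0):
    return ACSSession(traces=traces, rate_hz=rate,
                      stim_onsets_s=300.0 + 15.0 * np.arange(20))


class TestSegmentBlocks:
    def test_three_equal_blocks(self, rng):
        s = make_session(rng.normal(size=(2, 9000)))
        assert segment_blocks(s) == [(0, 3000), (3000, 6000), (6000, 9000)]

    def test_short_session_errors(self, rng):
        s = make_session(rng.normal(size=(2, 5000)))
        with pytest.raises(ValueError, match="shorter"):
            segment_blocks(s)

    def test_fractional_frames_error(self, rng):
        s = ACSSession(traces=rng.normal(size=(1, 9010)), rate_hz=10.0001,
                       stim_onsets_s=[310.0])
        with pytest.raises(ValueError, match="integer"):
            segment_blocks(s)

    def test_onsets_outside_middle_block_rejected(self, rng):
        with pytest.raises(ValueError, match="middle block"):
            ACSSession(traces=rng.normal(size=(1, 9000)), rate_hz=10.0,
                       stim_onsets_s=[100.0])


class TestAnovaModulation:
    def test_responders_flagged(self):
        session, gt = gen_acs_session(n_cells=40, frac_responsive=0.5, seed=1)
        res = acs_anova_modulation(session)
        resp = np.isin(np.arange(40), gt.responsive_ids)
        assert res.modulated[resp].mean() >= 0.9
        assert res.modulated[~resp].mean() <= 0.2

    def test_single_repetition_errors(self, rng):
        s = ACSSession(traces=rng.normal(size=(2, 9000)), rate_hz=10.0,
                       stim_onsets_s=[310.0])
        with pytest.raises(ValueError, match="repetitions"):
            acs_anova_modulation(s)


class TestAmplitudeModulation:
    def test_zero_trace_not_flagged(self, rng):
        traces = rng.normal(size=(3, 9000)) * 0.1
        traces[1] = 0.0
        with pytest.warns(UserWarning, match="flat"):
            out = amplitude_modulation(make_session(traces), n_shuffles=200)
        assert not out["flagged"][1]

    def test_responder_flagged(self):
        session, gt = gen_acs_session(n_cells=20, frac_responsive=0.5, seed=4)
        out = amplitude_modulation(session, n_shuffles=300, seed=5)
        resp = np.isin(np.arange(20), gt.responsive_ids)
        assert out["flagged"][resp].mean() >= 0.9


class TestDeconvolve:
    rate, decay = 10.0, 0.5

    def kernel_trace(self, onsets, amps, T=300, noise=0.0, seed=0):
        g = np.exp(-1 / (self.rate * self.decay))
        tr = np.zeros(T)
        for o, a in zip(onsets, amps):
            tr[o:] += a * g ** (np.arange(o, T) - o)
        if noise:
            tr += np.random.default_rng(seed).normal(0, noise, T)
        return tr

    def test_flat_trace_no_events(self):
        ev = deconvolve_events(np.zeros((1, 500)), self.rate, self.decay)
        assert len(ev.times_s[0]) == 0

    def test_five_transients_recovered(self):
        onsets = [30, 90, 150, 210, 270]
        amps = [1.0, 0.8, 1.2, 1.0, 0.9]
        tr = self.kernel_trace(onsets, amps)          # noiseless
        ev = deconvolve_events(tr, self.rate, self.decay)
        frames = np.round(ev.times_s[0] * self.rate).astype(int)
        assert list(frames) == onsets
        np.testing.assert_allclose(ev.amps[0], amps, rtol=1e-9)

    def test_transients_recovered_in_noise(self):
        onsets = np.array([30, 90, 150, 210, 270])
        amps = np.array([1.0, 0.8, 1.2, 1.0, 0.9])
        tr = self.kernel_trace(onsets, amps, noise=0.03)
        ev = deconvolve_events(tr, self.rate, self.decay)
        biggest = np.argsort(ev.amps[0])[::-1][:5]
        frames = np.sort(np.round(ev.times_s[0][biggest] * self.rate).astype(int))
        np.testing.assert_array_less(np.abs(frames - onsets), 2)
        np.testing.assert_allclose(np.sort(ev.amps[0][biggest]),
                                   np.sort(amps), rtol=0.2)
        extras = np.delete(ev.amps[0], biggest)
        assert np.all(extras < 0.3 * amps.min())

    def test_shift_equivariant(self):
        tr = self.kernel_trace([50, 120], [1.0, 1.0], noise=0.02)
        ev0 = deconvolve_events(tr, self.rate, self.decay)
        ev7 = deconvolve_events(np.roll(tr, 7), self.rate, self.decay)
        np.testing.assert_allclose(np.sort(ev7.times_s[0]),
                                   np.sort(ev0.times_s[0]) + 0.7, atol=1e-9)

    def test_invalid_decay_errors(self):
        with pytest.raises(ValueError):
            deconvolve_events(np.zeros((1, 10)), self.rate, 0.0)
        with pytest.raises(ValueError):
            deconvolve_events(np.zeros((1, 10)), self.rate, np.inf)


class TestEventRatio:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 10, 10), "no_change"),
        ((5, 20, 5), "increased"),       # acs ratio .667 vs .167: +0.5
        ((20, 5, 5), "decreased"),
        ((0, 0, 0), "inactive"),
        ((14, 17, 14), "no_change"),     # diff 0.067 < 0.10
    ])
    def test_hand_computed_classes(self, counts, expected):
        assert classify_event_ratio(np.array(counts)) == expected

    def test_post_comparison(self):
        assert classify_event_ratio(np.array([20, 10, 4]),
                                    compare="post") == "decreased"

    def test_scale_invariance(self, rng):
        counts = rng.integers(0, 30, (20, 3))
        a = classify_event_ratio(counts)
        b = classify_event_ratio(counts * 7)
        np.testing.assert_array_equal(a, b)

    def test_block_counts_from_train(self):
        session, gt = gen_acs_session(n_cells=10, seed=6)
        blocks = segment_blocks(session)
        train = deconvolve_events(session.traces, session.rate_hz, 0.5)
        counts = count_block_events(train, blocks, session.rate_hz)
        assert counts.shape == (10, 3)
        assert (counts.sum(axis=1) > 0).mean() >= 0.9


class TestQuadrants:
    def test_explicit_assignment(self):
        beh = [True, True, False, False]
        acs = [True, False, True, False]
        df = quadrant_classify(beh, acs, [(i, i) for i in range(4)])
        assert list(df.quadrant) == ["Beh+ACS+", "Beh+ACS-",
                                     "Beh-ACS+", "Beh-ACS-"]

    def test_empty_map_errors(self):
        with pytest.raises(ValueError, match="empty"):
            quadrant_classify([True], [True], [])

    def test_independent_flags_quarter_each(self, rng):
        beh = rng.random(400) < 0.5
        acs = rng.random(400) < 0.5
        df = quadrant_classify(beh, acs, [(i, i) for i in range(400)])
        for q, p in df.attrs["proportions"].items():
            assert abs(p - 0.25) < 3.5 * np.sqrt(0.25 * 0.75 / 400)


class TestAnalyzeSession:
    def test_end_to_end_result_consistency(self):
        session, gt = gen_acs_session(n_cells=30, seed=8)
        res = analyze_acs_session(session, n_shuffles=200, seed=9)
        active = ~res.inactive
        ratios = res.block_ratios[active]
        np.testing.assert_allclose(ratios.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(ratios >= 0)
        assert set(np.unique(res.event_class_acs)) <= {
            "increased", "decreased", "no_change", "inactive"}
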