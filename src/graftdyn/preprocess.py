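"""Trial-aligned preprocessing of continuous calcium traces.

A session is a pair of continuous ``cells x time`` arrays — the denoised
activity traces and the corresponding model residuals — plus a behavioral
event table.  Preprocessing turns these into trial tensors aligned to a
behavioral event (by default the moment of pellet touch in the
reach-to-grasp task), normalizes each cell/trial by the noise scale of its
pre-movement residual, and averages the 10 Hz samples into 0.5 s bins for
the downstream modulation tests.

Conventions: trial time is in seconds relative to the alignment event;
windows ``(pre, post)`` denote the half-open interval ``[-pre, +post)``;
bins are labeled by their left edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_NAMES = ("door_open", "pellet_touch", "door_close")


@dataclass
class SessionRecording:
    """Continuous traces plus behavioral events for one session.

    ``traces`` holds denoised activity (a.u.), ``residuals`` the
    denoising residual of the same shape; both sampled at ``rate_hz``.
    ``events`` is a long-format table with columns ``trial``, ``event``
    (one of ``door_open``/``pellet_touch``/``door_close``) and ``time_s``.
    """

    traces: np.ndarray
    residuals: np.ndarray
    rate_hz: float
    events: pd.DataFrame
    success: np.ndarray = None
    attempt: np.ndarray = None
    session_label: str = "early"

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.traces.shape != self.residuals.shape:
            raise ValueError(
                f"traces {self.traces.shape} and residuals "
                f"{self.residuals.shape} must have the same shape"
            )
        required = {"trial", "event", "time_s"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        dur = self.traces.shape[1] / self.rate_hz
        bad = self.events[(self.events.time_s < 0) | (self.events.time_s > dur)]
        if len(bad):
            raise ValueError(
                f"event times outside recording [0, {dur:.1f}] s at rows "
                f"{bad.index.tolist()[:5]}"
            )
        n_trials = self.events.trial.nunique()
        if self.success is None:
            self.success = np.zeros(n_trials, dtype=bool)
        if self.attempt is None:
            self.attempt = np.ones(n_trials, dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.rate_hz

    def event_times(self, name: str) -> pd.Series:
        """Times of one event type indexed by trial."""
        sel = self.events[self.events.event == name]
        return sel.set_index("trial")["time_s"]


@dataclass
class TrialTensor:
    """``cells x trials x samples`` activity aligned to one event."""

    data: np.ndarray
    align_event: str
    window_s: tuple
    rate_hz: float
    trial_ids: np.ndarray = None
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        pre, post = self.window_s
        expected = int(round((pre + post) * self.rate_hz))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window_s} at {self.rate_hz} Hz implies "
                f"{expected} samples, got {self.data.shape[2]}"
            )
        if np.isnan(self.data).any():
            raise ValueError("trial tensor contains NaN")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[1])

    @property
    def n_cells(self):
        return self.data.shape[0]

    @property
    def n_trials(self):
        return self.data.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        """Sample times (left edge) relative to the alignment event."""
        pre, _ = self.window_s
        return (np.arange(self.data.shape[2]) - int(round(pre * self.rate_hz))) / self.rate_hz


@dataclass
class BinnedTensor:
    """``cells x trials x bins`` averages over non-overlapping bins."""

    data: np.ndarray
    align_event: str
    window_s: tuple
    bin_s: float
    trial_ids: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[1])

    @property
    def n_bins(self):
        return self.data.shape[2]

    @property
    def bin_edges_s(self) -> np.ndarray:
        pre, _ = self.window_s
        return -pre + self.bin_s * np.arange(self.data.shape[2])


def segment_trials(rec: SessionRecording, align_event: str = "pellet_touch",
                   window_s: tuple = (5.0, 5.0)) -> TrialTensor:
    """Cut the continuous traces into per-trial windows around one event.

    Trials whose window would run past either end of the recording are
    dropped with a logged warning; if no usable trial remains an error
    names the event.
    """
    return _segment(rec.traces, rec, align_event, window_s)


def segment_residuals(rec: SessionRecording, align_event: str = "pellet_touch",
                      window_s: tuple = (5.0, 5.0)) -> TrialTensor:
    """Same as :func:`segment_trials` but on the residual traces."""
    return _segment(rec.residuals, rec, align_event, window_s)


def _segment(arr, rec, align_event, window_s):
    pre, post = window_s
    times = rec.event_times(align_event)
    if len(times) == 0:
        raise ValueError(f"no '{align_event}' events in session")
    n_samp = int(round((pre + post) * rec.rate_hz))
    pre_samp = int(round(pre * rec.rate_hz))
    T = arr.shape[1]
    segments, kept = [], []
    for trial, t in times.items():
        i0 = int(round(t * rec.rate_hz)) - pre_samp
        if i0 < 0 or i0 + n_samp > T:
            logger.warning(
                "trial %s dropped: window [%0.1f, %0.1f] s around %s at "
                "t=%.2f s exceeds recording bounds", trial, -pre, post,
                align_event, t)
            continue
        segments.append(arr[:, i0:i0 + n_samp])
        kept.append(trial)
    if not segments:
        raise ValueError(
            f"no trial window for event '{align_event}' fits inside the recording")
    data = np.stack(segments, axis=1)
    return TrialTensor(data=data, align_event=align_event, window_s=window_s,
                       rate_hz=rec.rate_hz, trial_ids=np.asarray(kept))


def baseline_correct(tensor: TrialTensor, residual_tensor: TrialTensor,
                     baseline_window_s: tuple = (-5.0, -4.0),
                     ddof: int = 0, trial_pooled: bool = True) -> TrialTensor:
    """Divide each cell/trial trace by its pre-movement residual noise scale.

    The divisor ``b`` for cell ``c`` is the averaged standard deviation of
    the residual samples inside ``baseline_window_s`` (a quiescent window
    well before movement): the SD is taken per trial and averaged across
    trials.  With ``trial_pooled=False`` each trial keeps its own SD; note
    that a 1 s window holds only ~10 samples at 10 Hz, so per-trial
    divisors carry ~25% estimation noise, which propagates into any
    downstream covariance statistic.  The output is strictly ``x / b``
    elementwise, so the operation is linear in the input trace.
    """
    if tensor.data.shape[1:] != residual_tensor.data.shape[1:] or \
            tensor.align_event != residual_tensor.align_event or \
            tensor.window_s != residual_tensor.window_s:
        raise ValueError("trace and residual tensors must be aligned identically")
    lo, hi = baseline_window_s
    pre, post = tensor.window_s
    if lo < -pre or hi > post:
        raise ValueError(
            f"baseline window {baseline_window_s} outside tensor window "
            f"[{-pre}, {post}]")
    t = tensor.times_s
    sel = (t >= lo) & (t < hi)
    if sel.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    b = residual_tensor.data[:, :, sel].std(axis=2, ddof=ddof)
    if trial_pooled:
        b = np.repeat(b.mean(axis=1, keepdims=True), b.shape[1], axis=1)
    zero = np.argwhere(b == 0)
    if len(zero):
        cells = sorted(set(zero[:, 0].tolist()))
        raise ValueError(
            f"degenerate residual (zero baseline SD) for cells {cells[:10]}")
    out = tensor.data / b[:, :, None]
    return replace(tensor, data=out)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Min-max normalize each cell to [0, 1] over all its values.

    Accepts ``cells x samples`` (e.g. a trial average) or
    ``cells x trials x samples``.  A constant cell cannot be scaled and
    maps to all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("minmax_normalize requires finite values")
    flat = x.reshape(x.shape[0], -1)
    lo = flat.min(axis=1)
    hi = flat.max(axis=1)
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant cell(s) mapped to zeros in "
            "min-max normalization")
    span = np.where(const, 1.0, span)
    out = (flat - lo[:, None]) / span[:, None]
    out[const] = 0.0
    return out.reshape(x.shape)


def bin_trials(tensor: TrialTensor, bin_s: float = 0.5,
               window_s: tuple = None) -> BinnedTensor:
    """Average consecutive samples into non-overlapping ``bin_s`` bins.

    ``window_s`` optionally restricts binning to a sub-window (e.g. the
    (−2.5 s, +2.5 s) task window of a wider tensor).  ``bin_s`` must be an
    integer multiple of the sample period and must evenly divide the
    binned window.
    """
    per = bin_s * tensor.rate_hz
    if abs(per - round(per)) > 1e-9 or round(per) < 1:
        raise ValueError(
            f"bin_s={bin_s} is not an integer multiple of the sample period "
            f"1/{tensor.rate_hz}")
    per = int(round(per))
    data = tensor.data
    if window_s is not None:
        pre, post = window_s
        t = tensor.times_s
        sel = (t >= -pre) & (t < post)
        data = data[:, :, sel]
    else:
        window_s = tensor.window_s
    n = data.shape[2]
    if n % per:
        raise ValueError(
            f"window of {n} samples not divisible by bin of {per} samples")
    binned = data.reshape(data.shape[0], data.shape[1], n // per, per).mean(axis=3)
    return BinnedTensor(data=binned, align_event=tensor.align_event,
                        window_s=window_s, bin_s=bin_s,
                        trial_ids=tensor.trial_ids)
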