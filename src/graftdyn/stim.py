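"""Epidural alternating-current stimulation (ACS) session analysis.

A session is 15 min of 10 Hz traces in three 5 min blocks — baseline,
stimulation, post-stimulation — with 20 stimulation repetitions (5 s ON,
10 s OFF) in the middle block.  Two complementary modulation tests flag
ACS-responsive cells: the same ANOVA/Tukey machinery as the task test on
onset-aligned 1 s bins, and an amplitude test comparing the trial-averaged
95th-percentile ON-window amplitude against a circular-shift null.
Calcium events are counted per block from a sparse AR(1) deconvolution,
and each cell's block event ratios classify it as increased / decreased /
no-change relative to baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from graftdyn.modulation import anova_modulation, ModulationResult
from graftdyn.preprocess import BinnedTensor


@dataclass
class ACSSession:
    traces: np.ndarray             # cells x time, 10 Hz
    rate_hz: float
    stim_onsets_s: np.ndarray
    block_s: float = 300.0
    on_s: float = 5.0
    off_s: float = 10.0
    stim_freq_hz: float = 1.0
    stim_amp_ua: float = 200.0

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=float)
        self.stim_onsets_s = np.asarray(self.stim_onsets_s, dtype=float)
        lo, hi = self.block_s, 2 * self.block_s
        if ((self.stim_onsets_s < lo) | (self.stim_onsets_s >= hi)).any():
            raise ValueError("stimulation onsets must lie inside the middle block")

    @property
    def n_cells(self):
        return self.traces.shape[0]

    @property
    def duration_s(self):
        return self.traces.shape[1] / self.rate_hz


@dataclass
class EventTrain:
    """Deconvolved calcium events per cell."""

    times_s: list                  # per cell: event times
    amps: list                     # per cell: event amplitudes
    decay_s: float

    @property
    def n_cells(self):
        return len(self.times_s)


@dataclass
class ACSSessionResult:
    anova_modulated: np.ndarray
    amplitude_modulated: np.ndarray
    block_counts: np.ndarray       # cells x 3
    block_ratios: np.ndarray       # cells x 3, NaN rows for inactive cells
    event_class_acs: np.ndarray    # vs baseline, during stimulation block
    event_class_post: np.ndarray   # vs baseline, post block
    inactive: np.ndarray

    @property
    def responsive(self) -> np.ndarray:
        return self.anova_modulated | self.amplitude_modulated

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": np.arange(len(self.anova_modulated)),
            "anova_modulated": self.anova_modulated,
            "amplitude_modulated": self.amplitude_modulated,
            "responsive": self.responsive,
            "count_baseline": self.block_counts[:, 0],
            "count_acs": self.block_counts[:, 1],
            "count_post": self.block_counts[:, 2],
            "class_acs": self.event_class_acs,
            "class_post": self.event_class_post,
            "inactive": self.inactive,
        })


def segment_blocks(session: ACSSession):
    """Frame ranges of the baseline / stimulation / post blocks."""
    if session.duration_s < 3 * session.block_s:
        raise ValueError(
            f"session of {session.duration_s:.0f} s shorter than three "
            f"{session.block_s:.0f} s blocks")
    per = session.block_s * session.rate_hz
    if abs(per - round(per)) > 1e-9:
        raise ValueError("block duration must be an integer number of frames")
    per = int(round(per))
    return [(i * per, (i + 1) * per) for i in range(3)]


def _onset_tensor(session: ACSSession, pre_s: float, post_s: float):
    """Onset-aligned cells x reps x samples array."""
    n_pre = int(round(pre_s * session.rate_hz))
    n_post = int(round(post_s * session.rate_hz))
    T = session.traces.shape[1]
    segs = []
    for t in session.stim_onsets_s:
        i = int(round(t * session.rate_hz))
        if i - n_pre < 0 or i + n_post > T:
            continue
        segs.append(session.traces[:, i - n_pre:i + n_post])
    if len(segs) < 2:
        raise ValueError("need at least 2 usable stimulation repetitions")
    return np.stack(segs, axis=1)


def acs_anova_modulation(session: ACSSession, bin_s: float = 1.0,
                         pre_s: float = 5.0, post_s: float = None,
                         alpha: float = 0.05) -> ModulationResult:
    """ANOVA/Tukey modulation on onset-aligned 1 s bins.

    The window runs from ``pre_s`` before each onset to 5 s past
    stimulation end (i.e. −5…+10 s around onset for 5 s ON), with
    stimulation repetitions as trials.
    """
    if post_s is None:
        post_s = session.on_s + 5.0
    x = _onset_tensor(session, pre_s, post_s)
    per = int(round(bin_s * session.rate_hz))
    n = x.shape[2] // per
    binned = x[:, :, :n * per].reshape(x.shape[0], x.shape[1], n, per).mean(axis=3)
    bt = BinnedTensor(data=binned, align_event="stim_onset",
                      window_s=(pre_s, post_s), bin_s=bin_s)
    return anova_modulation(bt, alpha=alpha)


def amplitude_modulation(session: ACSSession, n_shuffles: int = 1000,
                         percentile: float = 95.0, seed: int = 0) -> dict:
    """Amplitude-difference modulation against a circular-shift null.

    Statistic: per repetition, the ``percentile``-th amplitude within the
    5 s ON window, averaged over repetitions.  Null: the same statistic
    on circularly time-shifted traces (which preserves each cell's
    autocorrelation and amplitude distribution while decoupling it from
    stimulation timing).  A cell is flagged when its observed statistic
    exceeds the null's 95th percentile.
    """
    rng = np.random.default_rng(seed)
    n_cells, T = session.traces.shape
    on_frames = int(round(session.on_s * session.rate_hz))
    starts = np.round(session.stim_onsets_s * session.rate_hz).astype(int)
    idx = starts[:, None] + np.arange(on_frames)[None, :]

    def statistic(tr):
        return np.percentile(tr[:, idx], percentile, axis=2).mean(axis=1)

    obs = statistic(session.traces)
    flat = session.traces.std(axis=1) == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} flat trace(s) cannot be modulated")
    shifts = rng.integers(1, T, size=n_shuffles)
    null = np.empty((n_shuffles, n_cells))
    for k, s in enumerate(shifts):
        null[k] = statistic(np.roll(session.traces, int(s), axis=1))
    crit = np.percentile(null, 95.0, axis=0)
    flags = (obs > crit) & ~flat
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (n_shuffles + 1)
    return {"flagged": flags, "observed": obs, "null_crit": crit, "p": p}


def deconvolve_events(traces: np.ndarray, rate_hz: float, decay_s: float,
                      thresh_mad: float = 3.0) -> EventTrain:
    """Sparse event inference under an AR(1) calcium model.

    The AR coefficient is ``exp(-1 / (rate * decay))``; applying the
    exact inverse filter ``s_t = y_t − γ·y_{t−1}`` recovers the innovation
    (event) signal, which is rectified and thresholded at ``thresh_mad``
    times its MAD-estimated noise SD.  Events are local maxima of the
    thresholded innovation; amplitudes are the innovation values, which
    for isolated transients equal the transient amplitude.
    """
    if not np.isfinite(decay_s) or decay_s <= 0:
        raise ValueError("decay_s must be positive and finite")
    gamma = np.exp(-1.0 / (rate_hz * decay_s))
    if gamma >= 1:
        raise ValueError("decay implies AR coefficient >= 1")
    y = np.atleast_2d(np.asarray(traces, dtype=float))
    raw = np.zeros_like(y)
    raw[:, 1:] = y[:, 1:] - gamma * y[:, :-1]
    s = np.clip(raw, 0.0, None)
    times, amps = [], []
    for c in range(y.shape[0]):
        sc = s[c]
        # noise scale from the unrectified innovations: rectification
        # zeroes half the samples and would halve the MAD
        med = np.median(raw[c])
        sigma = np.median(np.abs(raw[c] - med)) / 0.6745
        if sigma > 0:
            thr = med + thresh_mad * sigma
        else:
            # noiseless trace: any positive innovation is an event
            thr = 1e-9 * max(sc.max(), 1.0)
        above = sc > thr
        peak = np.zeros_like(above)
        peak[1:-1] = above[1:-1] & (sc[1:-1] > sc[:-2]) & (sc[1:-1] >= sc[2:])
        idx = np.flatnonzero(peak)
        times.append(idx / rate_hz)
        amps.append(sc[idx])
    return EventTrain(times_s=times, amps=amps, decay_s=decay_s)


def count_block_events(train: EventTrain, blocks, rate_hz: float) -> np.ndarray:
    """Event counts per cell per block from frame-range blocks."""
    edges = [b[0] / rate_hz for b in blocks] + [blocks[-1][1] / rate_hz]
    counts = np.zeros((train.n_cells, len(blocks)), dtype=int)
    for c, t in enumerate(train.times_s):
        counts[c] = np.histogram(t, bins=edges)[0]
    return counts


def classify_event_ratio(counts, delta: float = 0.10,
                         compare: str = "acs", relative: bool = False):
    """Classify cells by block event-ratio change versus baseline.

    ``counts`` is ``(baseline, acs, post)`` per cell (1-D triple or
    ``cells x 3``).  Ratios are block counts normalized by the cell's
    total 15 min event count; a cell is ``increased`` /``decreased`` when
    the chosen block's ratio differs from baseline by more than ``delta``
    (absolute difference by default, relative change with
    ``relative=True``), ``no_change`` otherwise, and ``inactive`` when it
    produced no events at all.
    """
    x = np.atleast_2d(np.asarray(counts, dtype=float))
    col = {"acs": 1, "post": 2}[compare]
    total = x.sum(axis=1)
    out = np.full(len(x), "no_change", dtype=object)
    inactive = total == 0
    out[inactive] = "inactive"
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = x / total[:, None]
        diff = ratios[:, col] - ratios[:, 0]
        if relative:
            diff = diff / np.where(ratios[:, 0] == 0, np.nan, ratios[:, 0])
    act = ~inactive
    out[act & (diff > delta)] = "increased"
    out[act & (diff < -delta)] = "decreased"
    if len(np.shape(counts)) == 1:
        return out[0]
    return out


def analyze_acs_session(session: ACSSession, decay_s: float = 0.5,
                        n_shuffles: int = 1000, alpha: float = 0.05,
                        delta: float = 0.10, seed: int = 0) -> ACSSessionResult:
    """Run both modulation tests and the event-ratio classification."""
    blocks = segment_blocks(session)
    anova = acs_anova_modulation(session, alpha=alpha)
    ampl = amplitude_modulation(session, n_shuffles=n_shuffles, seed=seed)
    train = deconvolve_events(session.traces, session.rate_hz, decay_s)
    counts = count_block_events(train, blocks, session.rate_hz)
    total = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(total[:, None] > 0, counts / total[:, None], np.nan)
    return ACSSessionResult(
        anova_modulated=anova.modulated & anova.computable,
        amplitude_modulated=ampl["flagged"],
        block_counts=counts, block_ratios=ratios,
        event_class_acs=classify_event_ratio(counts, delta, "acs"),
        event_class_post=classify_event_ratio(counts, delta, "post"),
        inactive=total == 0)


QUADRANTS = ("Beh+ACS+", "Beh+ACS-", "Beh-ACS+", "Beh-ACS-")


def quadrant_classify(beh_flags, acs_flags, identity_map) -> pd.DataFrame:
    """Cross-classify cells tracked between a behavior and an ACS session.

    ``identity_map`` is a sequence of ``(behavior_index, acs_index)``
    pairs from tracking.  Returns one row per tracked cell with its
    quadrant; marginal proportions are attached as ``df.attrs['proportions']``.
    """
    pairs = list(identity_map)
    if not pairs:
        raise ValueError("empty identity map between behavior and ACS sessions")
    beh = np.asarray(beh_flags, dtype=bool)
    acs = np.asarray(acs_flags, dtype=bool)
    rows = []
    for bi, ai in pairs:
        b, a = beh[bi], acs[ai]
        quad = f"Beh{'+' if b else '-'}ACS{'+' if a else '-'}"
        rows.append((bi, ai, b, a, quad))
    df = pd.DataFrame(rows, columns=["beh_index", "acs_index",
                                     "beh_modulated", "acs_modulated",
                                     "quadrant"])
    props = df.quadrant.value_counts(normalize=True)
    df.attrs["proportions"] = {q: float(props.get(q, 0.0)) for q in QUADRANTS}
    return df
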