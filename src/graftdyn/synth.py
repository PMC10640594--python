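"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline is exercised on data produced here:

* :func:`gen_task_session` — a reach-to-grasp imaging session: continuous
  10 Hz traces in which task-modulated cells carry trial-locked calcium
  transients (instantaneous rise, single-exponential decay) at
  cell-specific latencies, the population shares ``q`` latent factor time
  courses calibrated to a target shared-over-total variance fraction, and
  non-modulated cells are flat on average.
* :func:`gen_acs_session` — a 15 min epidural-stimulation session
  (5 min baseline / 5 min stimulation / 5 min post) with 5 s ON / 10 s OFF
  stimulation-locked excitation and optional post-block suppression.
* :func:`gen_multisession` — session-to-session cell maps with centroid
  jitter, partial retention and session-unique cells.
* :func:`gen_flow_video` — a 60 Hz fluorescence video of erythrocyte
  motion along a vessel at a set speed.
* :func:`gen_cell_positions` — cell centroids at controlled distances
  from a vessel mask.

Design notes.  The transient family at different latencies is compressed
onto its top-``q`` principal time courses, and each modulated cell's
response is the rank-``q`` projection of its ideal waveform.  This keeps
the noiseless task-window signal *exactly* rank ``q``, so the target
shared-variance fraction can be calibrated in closed form against the
additive private noise, while the realized responses remain
visually indistinguishable from the ideal rise-and-decay transients.
Trial-to-trial variability enters through per-cell amplitude jitter and
zero-mean factor amplitudes, both confined to the same ``q``-dimensional
subspace.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.spatial import cKDTree

from graftdyn.preprocess import SessionRecording
from graftdyn.tracking import CellMap


@dataclass
class TaskSessionSpec:
    """Parameters of one synthetic reach-to-grasp session.

    ``trial_window_s`` is the (pre, post) task window around pellet touch
    inside which transients and factors live and the shared-variance
    calibration holds.  ``shared_frac`` is the target shared-over-total
    variance fraction of the task-window population activity;
    ``None`` disables calibration.
    """

    n_cells: int = 50
    n_trials: int = 40
    rate_hz: float = 10.0
    trial_window_s: tuple = (2.5, 2.5)
    frac_modulated: float = 0.5
    latency_spread_s: float = 0.4
    shared_factors: int = 2
    shared_frac: float = 0.6
    noise_sd: float = 1.0
    transient_decay_s: float = 0.5
    transient_amp: float = 3.0
    amp_jitter_sd: float = 0.25
    frac_cue: float = 0.0
    cue_lead_s: float = 1.0
    trial_spacing_s: float = 15.0
    pad_s: float = 10.0
    success_rate: float = 0.6
    factor_scope: str = "all"  # or "modulated"
    resid_sd: float = 1.0
    session_label: str = "early"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.frac_modulated <= 1:
            raise ValueError("frac_modulated must be in [0, 1]")
        if self.shared_frac is not None and not 0 <= self.shared_frac < 1:
            raise ValueError("shared_frac must be in [0, 1)")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.factor_scope not in ("all", "modulated"):
            raise ValueError("factor_scope must be 'all' or 'modulated'")


@dataclass
class FlowVideoSpec:
    """Parameters of one synthetic vessel-flow video."""

    shape_px: tuple = (40, 200)
    n_frames: int = 1800
    rate_hz: float = 60.0
    pixel_size_um: float = 2.0
    vessel_polyline: np.ndarray = None   # ordered (x, y) points in px
    vessel_width_um: float = 10.0
    speed_um_per_s: float = 1000.0
    particle_density: float = 2.0        # particles per 100 um of vessel
    noise_sd: float = 2.0
    train_sigma_um: float = 20.0
    perp_sigma_um: float = 2.0
    lumen_intensity: float = 10.0
    particle_amp: float = 60.0
    substeps: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.speed_um_per_s < 0:
            raise ValueError("speed_um_per_s must be >= 0")
        if self.vessel_width_um <= 0 or self.rate_hz <= 0:
            raise ValueError("vessel_width_um and rate_hz must be positive")
        if self.vessel_polyline is None:
            h, w = self.shape_px
            self.vessel_polyline = np.array([[0.0, h / 2.0], [w - 1.0, h / 2.0]])
        else:
            self.vessel_polyline = np.asarray(self.vessel_polyline, dtype=float)
            h, w = self.shape_px
            x, y = self.vessel_polyline[:, 0], self.vessel_polyline[:, 1]
            if (x < 0).any() or (x > w - 1).any() or (y < 0).any() or (y > h - 1).any():
                raise ValueError("vessel polyline outside frame bounds")


@dataclass
class GroundTruth:
    """Ground truth accompanying a generated object; fields not relevant
    to a given generator stay ``None``."""

    modulated_ids: np.ndarray = None
    cue_ids: np.ndarray = None
    latencies_s: np.ndarray = None
    factor_timecourses: np.ndarray = None
    factor_times_s: np.ndarray = None
    loadings: np.ndarray = None
    true_shared_frac: float = None
    responsive_ids: np.ndarray = None
    suppressed_ids: np.ndarray = None
    event_times: list = None
    event_amps: list = None
    stim_onsets_s: np.ndarray = None
    session_identity: list = None
    true_speed_um_per_s: float = None
    displacement_px_per_frame: float = None
    vessel_mask: np.ndarray = None
    distances_um: np.ndarray = None


def _decay_waveform(t: np.ndarray, latency: float, tau: float) -> np.ndarray:
    w = np.zeros_like(t)
    on = t >= latency
    w[on] = np.exp(-(t[on] - latency) / tau)
    return w


def gen_task_session(spec: TaskSessionSpec):
    """Generate one task session; returns ``(SessionRecording, GroundTruth)``."""
    rng = np.random.default_rng(spec.seed)
    n, q = spec.n_cells, spec.shared_factors
    pre, post = spec.trial_window_s
    m = int(round((pre + post) * spec.rate_hz))
    t_rel = (np.arange(m) - int(round(pre * spec.rate_hz))) / spec.rate_hz

    n_mod = int(round(spec.frac_modulated * n))
    n_cue = int(round(spec.frac_cue * n))
    if spec.factor_scope == "modulated" and n_mod < 1 and \
            spec.shared_frac is not None and spec.shared_frac > 0:
        raise ValueError(
            "shared_frac > 0 with factor_scope='modulated' requires at "
            "least one modulated cell")
    perm = rng.permutation(n)
    mod_ids = np.sort(perm[:n_mod])
    cue_ids = np.sort(perm[n_mod:n_mod + n_cue])

    # Rank-q time-course basis spanning the transient family.
    sig = spec.latency_spread_s
    lat_lo = max(-2.5 * sig, -pre + 2.0 / spec.rate_hz)
    lat_hi = 2.5 * sig
    lat_hi = min(lat_hi, post - 3 * spec.transient_decay_s)
    if lat_hi < lat_lo:
        lat_hi = lat_lo
    grid = np.linspace(lat_lo, lat_hi, 41)
    fam = np.stack([_decay_waveform(t_rel, l, spec.transient_decay_s)
                    for l in grid])
    _, s, vt = np.linalg.svd(fam, full_matrices=False)
    q_eff = int(min(q, (s > 1e-10 * s[0]).sum()))
    g = vt[:q_eff]                                     # orthonormal, q_eff x m

    def projected_response(lat):
        w = _decay_waveform(t_rel, lat, spec.transient_decay_s)
        r = g.T @ (g @ w)
        peak = r.max()
        return (r / peak if peak > 1e-12 else r), t_rel[int(np.argmax(r))]

    # Deterministic trial-locked responses.  Task-modulated cells are
    # kept as coefficient rows on the basis g so that the shared factor
    # fluctuations below live on the same population patterns; cue cells
    # (peaking at the door-open tone, outside the latency range the
    # basis spans) keep their ideal waveforms.
    sig_ids = np.concatenate([mod_ids, cue_ids]).astype(int)
    lat_mod = np.clip(rng.normal(0.0, sig, n_mod), lat_lo, lat_hi)
    M = np.zeros((n, q_eff))                       # det coefficients on g
    peak_times = np.full(n, np.nan)
    for cid, lat in zip(mod_ids, lat_mod):
        r, pk = projected_response(lat)
        M[cid] = spec.transient_amp * (g @ r)
        peak_times[cid] = pk
    det = M @ g                                    # n x m mean waveforms
    lat_cue = np.clip(rng.normal(-spec.cue_lead_s, sig / 2 if sig else 0.1,
                                 n_cue), -pre + 2.0 / spec.rate_hz, lat_hi)
    for cid, lat in zip(cue_ids, lat_cue):
        w = _decay_waveform(t_rel, lat, spec.transient_decay_s)
        det[cid] = spec.transient_amp * w
        peak_times[cid] = t_rel[int(np.argmax(w))]

    # Shared factor loadings.  With scope 'modulated' the loadings are the
    # transient coefficient patterns themselves (per-trial gains on the
    # two population time courses), which keeps the task-window shared
    # covariance exactly rank q.  With scope 'all', non-signal cells gain
    # loadings of comparable size in random directions; the shared
    # covariance is then only approximately rank q.
    L = M.copy()
    if spec.factor_scope == "all":
        others = np.setdiff1d(np.arange(n), sig_ids)
        if len(others):
            row_norm = np.linalg.norm(M, axis=1)
            scale = np.median(row_norm[row_norm > 0]) if (row_norm > 0).any() else 1.0
            extra = rng.standard_normal((len(others), q_eff))
            extra /= np.linalg.norm(extra, axis=1, keepdims=True)
            L[others] = scale * extra
    a = rng.standard_normal((q_eff, spec.n_trials))
    a -= a.mean(axis=1, keepdims=True)

    jitter = 1.0 + spec.amp_jitter_sd * rng.standard_normal((n, spec.n_trials))
    jitter = np.clip(jitter, 0.0, None)

    det_trials = np.repeat(det[:, None, :], spec.n_trials, axis=1)
    sto_trials = np.einsum("ck,kr,km->crm", L, a, g)

    def assemble(beta_, gamma_=1.0, with_jitter=True):
        sig_ = gamma_ * det_trials + beta_ * sto_trials
        return jitter[:, :, None] * sig_ if with_jitter else sig_

    def topq_frac(beta_, gamma_=1.0):
        # shared variance: top-q eigenvalues of the jitter-free covariance
        # (per-cell amplitude jitter is private — uncorrelated across
        # cells — and must not be counted as shared)
        flat = assemble(beta_, gamma_, with_jitter=False).reshape(n, -1)
        ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(np.cov(flat))))[::-1]
        shared = ev[:q_eff].sum()
        flat_j = assemble(beta_, gamma_).reshape(n, -1)
        total = float(np.sum(flat_j.var(axis=1))) + n * spec.noise_sd ** 2
        return float(shared / total) if total > 0 else 0.0

    beta = 0.0
    true_frac = None
    if spec.shared_frac is not None and spec.noise_sd > 0:
        from scipy.optimize import brentq
        f = spec.shared_frac
        has_sto = float(np.abs(sto_trials).max()) > 0
        if f == 0:
            beta = 0.0
            if np.abs(det).max() > 0:
                warnings.warn(
                    "shared_frac=0 with trial-locked transients present: "
                    "factor fluctuations removed but transients still "
                    "contribute shared variance")
        elif topq_frac(0.0) >= f or not has_sto:
            # transients alone meet or exceed the target: shrink them
            beta = 0.0
            gamma = brentq(lambda s: topq_frac(0.0, s) - f,
                           0.0, 1.0, xtol=1e-4)
            det_trials *= gamma
            warnings.warn(
                "trial-locked transients alone exceed the requested shared "
                f"fraction; transient amplitude rescaled by {gamma:.3f}")
        else:
            hi = 1.0
            while topq_frac(hi) < f:
                hi *= 2.0
                if hi > 1e4:
                    raise ValueError(
                        f"shared_frac={f} unreachable with this configuration")
            beta = brentq(lambda b: topq_frac(b) - f,
                          0.0, hi, xtol=1e-4)
    signal = assemble(beta)
    if spec.noise_sd > 0:
        true_frac = topq_frac(beta)

    # Continuous traces with embedded trials.
    touch = spec.pad_s + spec.trial_spacing_s * np.arange(spec.n_trials)
    dur = touch[-1] + spec.pad_s
    T = int(round(dur * spec.rate_hz))
    traces = (rng.normal(0.0, spec.noise_sd, (n, T)) if spec.noise_sd > 0
              else np.zeros((n, T)))
    pre_samp = int(round(pre * spec.rate_hz))
    for k, tk in enumerate(touch):
        i0 = int(round(tk * spec.rate_hz)) - pre_samp
        traces[:, i0:i0 + m] += signal[:, k, :]
    residuals = (rng.normal(0.0, spec.resid_sd, (n, T)) if spec.resid_sd > 0
                 else np.zeros((n, T)))

    rows = []
    for k, tk in enumerate(touch):
        rows += [(k, "door_open", tk - spec.cue_lead_s),
                 (k, "pellet_touch", tk),
                 (k, "door_close", tk + 2.0)]
    events = pd.DataFrame(rows, columns=["trial", "event", "time_s"])
    success = rng.random(spec.n_trials) < spec.success_rate

    rec = SessionRecording(traces=traces, residuals=residuals,
                           rate_hz=spec.rate_hz, events=events,
                           success=success,
                           attempt=np.ones(spec.n_trials, dtype=bool),
                           session_label=spec.session_label)
    gt = GroundTruth(modulated_ids=mod_ids, cue_ids=cue_ids,
                     latencies_s=peak_times, factor_timecourses=g,
                     factor_times_s=t_rel, loadings=beta * L,
                     true_shared_frac=true_frac)
    return rec, gt


def gen_acs_session(n_cells: int = 50, frac_responsive: float = 0.75,
                    frac_post_suppressed: float = 0.70, seed: int = 0,
                    rate_hz: float = 10.0, noise_sd: float = 0.15,
                    bg_event_rate_hz: float = 0.05, stim_amp: float = 1.0,
                    bg_amp: float = 1.0, decay_s: float = 0.5,
                    suppression: float = 0.8, block_s: float = 300.0,
                    on_s: float = 5.0, off_s: float = 10.0,
                    n_reps: int = 20):
    """Generate a 15 min stimulation session (baseline / ACS / post blocks).

    Responsive cells gain transients locked to the 5 s ON windows of the
    middle block; post-suppressed cells have their spontaneous event rate
    reduced by ``suppression`` in the final block.  Traces follow the
    AR(1) calcium model (impulse events convolved with an exponential
    kernel of time constant ``decay_s``) plus Gaussian noise.
    """
    for f in (frac_responsive, frac_post_suppressed):
        if not 0 <= f <= 1:
            raise ValueError("fractions must be in [0, 1]")
    from graftdyn.stim import ACSSession   # avoid import cycle at module load

    rng = np.random.default_rng(seed)
    T = int(round(3 * block_s * rate_hz))
    b1 = int(round(block_s * rate_hz))
    onsets_s = block_s + (on_s + off_s) * np.arange(n_reps)
    perm = rng.permutation(n_cells)
    resp = np.sort(perm[:int(round(frac_responsive * n_cells))])
    supp = np.sort(rng.permutation(n_cells)[:int(round(frac_post_suppressed * n_cells))])

    impulses = np.zeros((n_cells, T))
    ev_times = [[] for _ in range(n_cells)]
    ev_amps = [[] for _ in range(n_cells)]
    p_bg = bg_event_rate_hz / rate_hz
    for c in range(n_cells):
        p = np.full(T, p_bg)
        if c in supp:
            p[2 * b1:] *= (1 - suppression)
        hits = np.flatnonzero(rng.random(T) < p)
        amps = bg_amp * rng.uniform(0.8, 1.2, len(hits))
        impulses[c, hits] += amps
        ev_times[c] += (hits / rate_hz).tolist()
        ev_amps[c] += amps.tolist()
    for c in resp:
        for os_ in onsets_s:
            f0 = int(round(os_ * rate_hz)) + int(rng.integers(0, 4))
            a0 = stim_amp * rng.uniform(0.8, 1.2)
            impulses[c, f0] += a0
            ev_times[c].append(f0 / rate_hz)
            ev_amps[c].append(a0)
            f1 = int(round(os_ * rate_hz)) + 25 + int(rng.integers(0, 4))
            a1 = 0.7 * stim_amp * rng.uniform(0.8, 1.2)
            impulses[c, f1] += a1
            ev_times[c].append(f1 / rate_hz)
            ev_amps[c].append(a1)

    gamma = np.exp(-1.0 / (rate_hz * decay_s))
    calcium = lfilter([1.0], [1.0, -gamma], impulses, axis=1)
    traces = calcium + rng.normal(0.0, noise_sd, (n_cells, T))

    session = ACSSession(traces=traces, rate_hz=rate_hz, stim_onsets_s=onsets_s,
                         block_s=block_s, on_s=on_s, off_s=off_s,
                         stim_freq_hz=1.0, stim_amp_ua=200.0)
    gt = GroundTruth(responsive_ids=resp, suppressed_ids=supp,
                     event_times=[np.array(v) for v in ev_times],
                     event_amps=[np.array(v) for v in ev_amps],
                     stim_onsets_s=onsets_s)
    return session, gt


def gen_multisession(base_centroids: np.ndarray, n_sessions: int,
                     jitter_px: float = 1.0, retention_frac: float = 0.55,
                     new_frac: float = 0.2, fov_shape: tuple = (200, 200),
                     footprint_sigma_px: float = None, seed: int = 0):
    """Session cell maps: each session independently retains a
    ``retention_frac`` Bernoulli subset of the base population, jitters
    centroids isotropically by ``jitter_px``, and gains session-unique
    cells.  Returns ``(list[CellMap], GroundTruth)`` where
    ``session_identity[s][base_id]`` is the session-local index or −1.
    """
    if not 0 < retention_frac <= 1:
        raise ValueError("retention_frac must be in (0, 1]")
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    base = np.asarray(base_centroids, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(base)
    h, w = fov_shape
    maps, identity = [], []
    for s in range(n_sessions):
        kept = np.flatnonzero(rng.random(n) < retention_frac) \
            if retention_frac < 1 else np.arange(n)
        cent = base[kept] + rng.normal(0.0, jitter_px, (len(kept), 2))
        n_new = int(round(new_frac * n))
        new = np.column_stack([rng.uniform(0, w - 1, n_new),
                               rng.uniform(0, h - 1, n_new)])
        allc = np.vstack([cent, new]) if n_new else cent
        order = rng.permutation(len(allc))
        inv = np.empty(len(allc), dtype=int)
        inv[order] = np.arange(len(allc))
        ident = np.full(n, -1, dtype=int)
        ident[kept] = inv[:len(kept)]
        allc = np.clip(allc[order], 0, [w - 1, h - 1])
        fp = None
        if footprint_sigma_px is not None:
            fp = _footprints(allc, fov_shape, footprint_sigma_px, rng)
        maps.append(CellMap(session=s, centroids=allc, fov_shape=fov_shape,
                            footprints=fp))
        identity.append(ident)
    return maps, GroundTruth(session_identity=identity)


def _footprints(centroids, fov_shape, sigma, rng, patch: int = 7):
    h, w = fov_shape
    yy, xx = np.mgrid[0:h, 0:w]
    out = np.empty((len(centroids), h, w), dtype=np.float32)
    for i, (x, y) in enumerate(centroids):
        s = sigma * rng.uniform(0.9, 1.1)
        out[i] = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s ** 2))
    return out


def _polyline_geometry(poly_px, pixel_size_um):
    pts = poly_px * pixel_size_um
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    return pts, seg, seglen, cum


def _point_on_polyline(s, pts, seg, seglen, cum):
    s = np.clip(s, 0.0, cum[-1])
    i = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - cum[i]) / seglen[i]
    p = pts[i] + frac[..., None] * seg[i]
    tang = seg[i] / seglen[i][..., None]
    return p, tang


def vessel_lumen_mask(spec: FlowVideoSpec) -> np.ndarray:
    """Boolean lumen mask (pixels within half the vessel width of the
    centerline polyline)."""
    h, w = spec.shape_px
    pts, seg, seglen, cum = _polyline_geometry(spec.vessel_polyline,
                                               spec.pixel_size_um)
    dense = np.linspace(0, cum[-1], max(int(cum[-1]), 2))
    cpts, _ = _point_on_polyline(dense, pts, seg, seglen, cum)
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel() * spec.pixel_size_um,
                           yy.ravel() * spec.pixel_size_um])
    d, _ = cKDTree(cpts).query(pix)
    return (d <= spec.vessel_width_um / 2).reshape(h, w)


def gen_flow_video(spec: FlowVideoSpec):
    """Render erythrocyte motion along a vessel at a fixed speed.

    Particles are anisotropic intensity trains advected along the
    centerline; on leaving the vessel they re-enter at the start with a
    fresh transverse offset and brightness (as newly arriving cells
    would), which keeps the intensity pattern aperiodic.  Sub-frame
    motion is rendered with ``substeps`` averaged positions per frame,
    emulating full-frame exposure.  Returns ``(frames, GroundTruth)``
    with ``frames`` a ``T x H x W`` float32 stack.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    px = spec.pixel_size_um
    pts, seg, seglen, cum = _polyline_geometry(spec.vessel_polyline, px)
    length = cum[-1]
    n_part = max(int(spec.particle_density * length / 100.0), 1)
    pos = rng.uniform(0, length, n_part)
    half = spec.vessel_width_um / 2
    off_lim = max(half - spec.perp_sigma_um, 0.1)
    off = rng.uniform(-off_lim, off_lim, n_part)
    amp = rng.uniform(0.6, 1.4, n_part) * spec.particle_amp

    lumen = vessel_lumen_mask(spec).astype(np.float32) * spec.lumen_intensity
    frames = np.empty((spec.n_frames, h, w), dtype=np.float32)
    dt = 1.0 / spec.rate_hz
    pr = int(np.ceil(3 * spec.train_sigma_um / px))
    yy_full, xx_full = np.mgrid[0:h, 0:w]

    for f in range(spec.n_frames):
        img = np.zeros((h, w), dtype=np.float64)
        for s_i in range(spec.substeps):
            p = (pos + spec.speed_um_per_s * dt * s_i / spec.substeps) % length
            cpts, tang = _point_on_polyline(p, pts, seg, seglen, cum)
            normal = np.column_stack([-tang[:, 1], tang[:, 0]])
            centers = cpts + off[:, None] * normal
            for i in range(n_part):
                cx, cy = centers[i] / px
                x0, x1 = max(int(cx) - pr, 0), min(int(cx) + pr + 1, w)
                y0, y1 = max(int(cy) - pr, 0), min(int(cy) + pr + 1, h)
                if x0 >= x1 or y0 >= y1:
                    continue
                dx = (xx_full[y0:y1, x0:x1] - cx) * px
                dy = (yy_full[y0:y1, x0:x1] - cy) * px
                ax = dx * tang[i, 0] + dy * tang[i, 1]
                pp = -dx * tang[i, 1] + dy * tang[i, 0]
                img[y0:y1, x0:x1] += (amp[i] / spec.substeps) * np.exp(
                    -ax ** 2 / (2 * spec.train_sigma_um ** 2)
                    - pp ** 2 / (2 * spec.perp_sigma_um ** 2))
        noise = rng.normal(0.0, spec.noise_sd, (h, w)) if spec.noise_sd > 0 else 0.0
        frames[f] = lumen + img + noise
        pos = pos + spec.speed_um_per_s * dt
        wrapped = pos >= length
        if wrapped.any():
            k = int(wrapped.sum())
            pos[wrapped] %= length
            off[wrapped] = rng.uniform(-off_lim, off_lim, k)
            amp[wrapped] = rng.uniform(0.6, 1.4, k) * spec.particle_amp

    gt = GroundTruth(
        true_speed_um_per_s=spec.speed_um_per_s,
        displacement_px_per_frame=spec.speed_um_per_s / (spec.rate_hz * px),
        vessel_mask=vessel_lumen_mask(spec))
    return frames, gt


def gen_cell_positions(n_cells: int, mask: np.ndarray, max_dist_um: float,
                       pixel_size_um: float, seed: int = 0,
                       distribution: str = "uniform"):
    """Place cell centroids at controlled distances from a vessel mask.

    Target distances are drawn from ``distribution`` (``uniform`` over
    ``[0, max_dist_um]`` or ``exponential`` with mean ``max_dist_um / 3``
    truncated at ``max_dist_um``); each centroid is placed on a pixel
    whose distance-transform value matches its target (±half pixel), with
    sub-pixel jitter.  Returns ``(centroids_px (x, y), GroundTruth)``
    where ``distances_um`` are the exact realized distances to the
    nearest mask pixel.
    """
    from scipy.ndimage import distance_transform_edt
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    dist_px = distance_transform_edt(~mask)
    h, w = mask.shape
    if max_dist_um > dist_px.max() * pixel_size_um:
        raise ValueError(
            f"max_dist_um={max_dist_um} exceeds the largest vessel distance "
            f"in this field ({dist_px.max() * pixel_size_um:.1f} um); use a "
            "larger field of view")
    tree = cKDTree(np.argwhere(mask)[:, ::-1].astype(float))  # (x, y)
    cents = np.empty((n_cells, 2))
    for i in range(n_cells):
        for _ in range(1000):
            if distribution == "uniform":
                d = rng.uniform(0, max_dist_um)
            elif distribution == "exponential":
                d = min(rng.exponential(max_dist_um / 3), max_dist_um)
            else:
                raise ValueError(f"unknown distribution '{distribution}'")
            d_px = d / pixel_size_um
            cand = np.argwhere(np.abs(dist_px - d_px) <= 0.5)
            if len(cand):
                r, c = cand[rng.integers(len(cand))]
                cents[i] = (c + rng.uniform(-0.5, 0.5),
                            r + rng.uniform(-0.5, 0.5))
                cents[i] = np.clip(cents[i], 0, [w - 1, h - 1])
                break
        else:
            raise ValueError(
                f"could not place a cell at distance {d:.1f} um; field too small")
    d_real, _ = tree.query(cents)
    return cents, GroundTruth(distances_um=d_real * pixel_size_um)


def gen_behavior_summary(n_mice: int = 6, n_sessions: int = 10,
                         r: float = 0.6, intercept_sd: float = 0.3,
                         slope_sd: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Per-session behavior/modulation summaries with a set latent
    correlation ``r`` between success rate and the proportion of
    task-modulated cells, plus per-mouse random intercepts and slopes."""
    rng = np.random.default_rng(seed)
    rows = []
    for mouse in range(n_mice):
        b0 = rng.normal(0.0, intercept_sd)
        b1 = rng.normal(0.0, slope_sd)
        x = rng.standard_normal(n_sessions)
        y = (r + b1) * x + np.sqrt(max(1 - r ** 2, 0.0)) * \
            rng.standard_normal(n_sessions) + b0
        rows.append(pd.DataFrame({
            "mouse": mouse, "session": np.arange(n_sessions),
            "proportion_modulated": np.clip(0.30 + 0.10 * x, 0, 1),
            "success_rate": np.clip(0.40 + 0.12 * y, 0, 1),
            "attempt_rate": np.clip(0.8 + 0.05 * rng.standard_normal(n_sessions), 0, 1),
        }))
    return pd.concat(rows, ignore_index=True)
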