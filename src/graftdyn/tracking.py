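"""Longitudinal cell registration across imaging sessions.

Cells are matched between consecutive sessions by optimal one-to-one
assignment (Hungarian algorithm) on centroid distance, gated by a hard
maximum distance and, when spatial footprints are available, a minimum
footprint correlation.  Identities are chained transitively across
sessions.  Task covariance between tracked cells is assessed against a
trial-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


@dataclass
class CellMap:
    """Per-session cell centroids ``(x, y)`` in pixels with optional
    footprint images (``n x H x W``)."""

    session: int
    centroids: np.ndarray
    fov_shape: tuple = None
    footprints: np.ndarray = None

    def __post_init__(self):
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.fov_shape is not None:
            h, w = self.fov_shape
            x, y = self.centroids[:, 0], self.centroids[:, 1]
            if len(x) and ((x < 0).any() or (x > w - 1).any()
                           or (y < 0).any() or (y > h - 1).any()):
                raise ValueError("centroids outside field of view")

    @property
    def n_cells(self):
        return len(self.centroids)


@dataclass
class TrackingResult:
    """Chains of ``(session, local_index)`` per tracked identity."""

    chains: list
    pair_distances: list          # per consecutive pair: array of distances
    unmatched: list               # per session: local indices in no chain
    n_sessions: int

    def chain_table(self) -> pd.DataFrame:
        rows = []
        for ident, chain in enumerate(self.chains):
            for session, local in chain:
                rows.append((ident, session, local))
        return pd.DataFrame(rows, columns=["identity", "session", "local_index"])


def _pair_assignment(map_a: CellMap, map_b: CellMap, max_dist_px: float,
                     min_footprint_corr: float = None):
    """One-to-one matches between two maps; returns list of (i, j, dist)."""
    if map_a.n_cells == 0 or map_b.n_cells == 0:
        raise ValueError("cannot register an empty cell map")
    d = cdist(map_a.centroids, map_b.centroids)
    big = 1e6
    cost = np.where(d <= max_dist_px, d, big)
    if min_footprint_corr is not None and map_a.footprints is not None \
            and map_b.footprints is not None:
        fa = map_a.footprints.reshape(map_a.n_cells, -1)
        fb = map_b.footprints.reshape(map_b.n_cells, -1)
        fa = fa - fa.mean(1, keepdims=True)
        fb = fb - fb.mean(1, keepdims=True)
        na = np.linalg.norm(fa, axis=1)
        nb = np.linalg.norm(fb, axis=1)
        corr = (fa @ fb.T) / np.outer(np.where(na == 0, 1, na),
                                      np.where(nb == 0, 1, nb))
        cost = np.where(corr >= min_footprint_corr, cost, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j), float(d[i, j]))
            for i, j in zip(rows, cols) if cost[i, j] < big]


def register_sessions(maps, max_dist_px: float = 8.0,
                      min_footprint_corr: float = None) -> TrackingResult:
    """Register cells across ≥2 session maps and chain identities.

    Consecutive sessions are matched independently; a chain follows a
    cell through every consecutive match it participates in.  Cells never
    matched to anything form no chain and are reported unmatched.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least two session maps")
    pair_matches, pair_dists = [], []
    for a, b in zip(maps[:-1], maps[1:]):
        matches = _pair_assignment(a, b, max_dist_px, min_footprint_corr)
        pair_matches.append({i: j for i, j, _ in matches})
        pair_dists.append(np.array([m[2] for m in matches]))

    chains = []
    in_chain = [set() for _ in maps]
    for s0 in range(len(maps) - 1):
        for i in range(maps[s0].n_cells):
            if i in in_chain[s0] or i not in pair_matches[s0]:
                continue
            chain = [(s0, i)]
            cur = i
            for s in range(s0, len(maps) - 1):
                nxt = pair_matches[s].get(cur)
                if nxt is None:
                    break
                chain.append((s + 1, nxt))
                cur = nxt
            if len(chain) > 1:
                for s, loc in chain:
                    in_chain[s].add(loc)
                chains.append(chain)
    unmatched = [sorted(set(range(m.n_cells)) - in_chain[s])
                 for s, m in enumerate(maps)]
    return TrackingResult(chains=chains, pair_distances=pair_dists,
                          unmatched=unmatched, n_sessions=len(maps))


def tracked_fraction(result: TrackingResult, base_count: int) -> dict:
    """Fractions of the base population tracked across sessions.

    ``full_span`` counts chains covering every session; ``adjacent``
    gives the per-consecutive-pair match fraction.  Both are relative to
    ``base_count``, the size of the underlying population.
    """
    if base_count <= 0:
        raise ValueError("base_count must be positive")
    n_full = sum(1 for c in result.chains if len(c) == result.n_sessions)
    adjacent = [len(d) / base_count for d in result.pair_distances]
    return {"full_span": n_full / base_count, "adjacent": adjacent,
            "n_full_span": n_full}


def covariance_network(tracked_data: np.ndarray, n_shuffles: int = 1000,
                       alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Pairwise task covariance of tracked cells against a trial-shuffle null.

    ``tracked_data`` is ``cells x trials x samples`` task-window activity.
    For each pair the Pearson correlation of trial-concatenated activity
    is compared with the distribution obtained by permuting one cell's
    trial order (which preserves within-trial structure but breaks
    trial-by-trial co-variation).  Returns an edge table with two-sided
    permutation p-values; ``significant`` marks edges with p < alpha.
    """
    import warnings as _w
    x = np.asarray(tracked_data, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need cells x trials x samples with >= 2 cells")
    n, n_trials, m = x.shape
    if n_shuffles < 100:
        _w.warn("n_shuffles < 100 gives poor p-value resolution")
    rng = np.random.default_rng(seed)
    flat = x.reshape(n, -1)
    flat = flat - flat.mean(1, keepdims=True)
    norm = np.linalg.norm(flat, axis=1)
    norm = np.where(norm == 0, 1.0, norm)
    z = flat / norm[:, None]
    perms = np.stack([rng.permutation(n_trials) for _ in range(n_shuffles)])
    rows = []
    for i in range(n):
        zi3 = z[i].reshape(n_trials, m)
        null_i = zi3[perms].reshape(n_shuffles, -1)     # shuffled cell i
        for j in range(i + 1, n):
            r = float(z[i] @ z[j])
            r_null = null_i @ z[j]
            p = (1 + np.sum(np.abs(r_null) >= abs(r))) / (n_shuffles + 1)
            rows.append((i, j, r, float(p), int(np.sign(r))))
    df = pd.DataFrame(rows, columns=["cell_i", "cell_j", "r", "p", "sign"])
    df["significant"] = df.p < alpha
    return df
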