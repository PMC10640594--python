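"""Population-level metrics of task-window activity.

The central statistic is the shared-over-total variance (SOT) from a
maximum-likelihood factor analysis of task-window activity: with
loadings ``L`` (cells x q) and per-cell uniquenesses ``psi``,

    SOT = sum_c ||L_c||^2 / (sum_c ||L_c||^2 + sum_c psi_c)

i.e. the fraction of total population variance carried by the shared
latent factors rather than by private, cell-specific fluctuations.  SOT
rises when cells co-fire through common latent drives.

Sample space: time points are pooled across trials within the task
window (variables = cells), so a session with ``n_trials`` trials of
``m`` samples yields ``n_trials * m`` observations.  The factor count is
chosen from PCA (two components dominate task activity in motor
networks); leave-one-out PCA guards the explained-variance estimate
against overfitting to single trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA, FactorAnalysis

from graftdyn.preprocess import TrialTensor


@dataclass
class BinaryRaster:
    """Thresholded activity: 1 where a cell exceeds mean + k·SD."""

    data: np.ndarray
    threshold_sd: float


@dataclass
class FactorDecomposition:
    loadings: np.ndarray        # cells x q
    private_var: np.ndarray     # per cell, >= 0
    q: int
    n_iter: int
    loglik: float

    @property
    def shared_var(self) -> np.ndarray:
        return (self.loadings ** 2).sum(axis=1)

    @property
    def sot(self) -> float:
        shared = float(self.shared_var.sum())
        private = float(self.private_var.sum())
        return shared / (shared + private)


@dataclass
class Trajectory:
    components: np.ndarray      # q x time
    times_s: np.ndarray
    length_scale_s: float
    touch_index: int


def _pooled(task_data) -> np.ndarray:
    """Return pooled ``observations x cells`` from tensor-like input."""
    if isinstance(task_data, TrialTensor):
        x = task_data.data
    else:
        x = np.asarray(task_data, dtype=float)
    if x.ndim == 3:
        n = x.shape[0]
        return x.reshape(n, -1).T
    if x.ndim == 2:
        return x.T
    raise ValueError("expected cells x trials x samples or cells x samples")


def binarize(data, k_sd: float = 1.0) -> BinaryRaster:
    """Per-cell threshold at mean + ``k_sd``·SD over the analyzed window.

    The raster is invariant to any positive affine rescaling of a cell's
    trace, since mean and SD rescale with the data.
    """
    x = np.asarray(data, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("binarize requires finite traces")
    flat = x.reshape(x.shape[0], -1)
    thr = flat.mean(axis=1) + k_sd * flat.std(axis=1)
    out = (flat > thr[:, None]).astype(np.uint8).reshape(x.shape)
    return BinaryRaster(data=out, threshold_sd=k_sd)


def cofire(a: np.ndarray, b: np.ndarray) -> int:
    """Co-firing count of two binary vectors: their dot product."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return int(a.astype(np.int64) @ b.astype(np.int64))


def cofire_matrix(raster) -> np.ndarray:
    """Symmetric cells x cells co-firing counts; diagonal = per-cell
    supra-threshold sample counts."""
    r = raster.data if isinstance(raster, BinaryRaster) else np.asarray(raster)
    flat = r.reshape(r.shape[0], -1).astype(np.int64)
    return flat @ flat.T


def pca_loo(task_data, n_components: int = 2) -> dict:
    """Leave-one-trial-out PCA of task-window activity.

    For each held-out trial, PCA is fit on the remaining trials' pooled
    time points and the held-out trial is projected into that space; the
    explained-variance ratio of each component is measured on the
    held-out projection.  Returns mean ratios across folds, the
    per-fold ratios, and the projected trials.
    """
    x = task_data.data if isinstance(task_data, TrialTensor) else np.asarray(task_data, float)
    if x.ndim != 3:
        raise ValueError("expected cells x trials x samples")
    n, n_trials, m = x.shape
    if n_trials < 3:
        raise ValueError("leave-one-out PCA needs at least 3 trials")
    if n < n_components:
        raise ValueError(f"{n_components} components requested but only {n} cells")
    ratios = np.empty((n_trials, n_components))
    captured = np.empty((n_trials, n_components))
    totals = np.empty(n_trials)
    projections = np.empty((n_trials, m, n_components))
    for k in range(n_trials):
        train = np.delete(x, k, axis=1).reshape(n, -1).T
        pca = PCA(n_components=n_components, svd_solver="full").fit(train)
        held = x[:, k, :].T - pca.mean_
        scores = held @ pca.components_.T
        totals[k] = (held ** 2).sum()
        captured[k] = (scores ** 2).sum(axis=0)
        ratios[k] = captured[k] / totals[k] if totals[k] > 0 else 0.0
        projections[k] = scores
    # energy-weighted cross-validated ratio: total captured over total
    # held-out energy (robust to trial-to-trial amplitude differences)
    ev = captured.sum(axis=0) / totals.sum() if totals.sum() > 0 \
        else np.zeros(n_components)
    return {"explained_variance_ratio": ev,
            "per_trial_ratio": ratios, "projected_trials": projections}


def fa_sot(task_data, q: int = 2, tol: float = 1e-6,
           max_iter: int = 1000) -> FactorDecomposition:
    """Maximum-likelihood factor analysis of pooled task-window activity
    and its shared-over-total variance.

    Variables are cells, observations are trial-pooled time points.
    Uniquenesses hitting zero (Heywood cases) are floored at 1e-6 with a
    warning.  The fit is deterministic (SVD-based, no random init).
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    X = _pooled(task_data)
    n_obs, n_cells = X.shape
    if n_obs <= n_cells:
        warnings.warn(
            f"only {n_obs} observations for {n_cells} cells; factor "
            "estimates may be unstable")
    fa = FactorAnalysis(n_components=q, tol=tol, max_iter=max_iter,
                        svd_method="lapack")
    fa.fit(X)
    if fa.n_iter_ >= max_iter:
        raise RuntimeError(
            f"factor analysis did not converge in {max_iter} iterations "
            f"(final log-likelihood {fa.loglike_[-1]:.3f})")
    psi = fa.noise_variance_.copy()
    if (psi < 1e-6).any():
        warnings.warn(
            f"{int((psi < 1e-6).sum())} Heywood case(s): uniqueness floored at 1e-6")
        psi = np.maximum(psi, 1e-6)
    return FactorDecomposition(loadings=fa.components_.T, private_var=psi,
                               q=q, n_iter=int(fa.n_iter_),
                               loglik=float(fa.loglike_[-1]))


def smooth_trajectory(task_data, q: int = 2, length_scale_s: float = 0.3,
                      rate_hz: float = None,
                      decomposition: FactorDecomposition = None) -> Trajectory:
    """Trial-averaged latent trajectory, Gaussian-smoothed in time.

    Factor scores of the trial-averaged activity are smoothed with a
    Gaussian kernel of standard deviation ``length_scale_s`` (the
    posterior mean of a Gaussian-process factor model in the
    high-signal-to-noise limit).  ``length_scale_s = 0`` leaves the
    scores untouched.
    """
    if isinstance(task_data, TrialTensor):
        x = task_data.data
        rate_hz = task_data.rate_hz
        pre = task_data.window_s[0]
        times = task_data.times_s
    else:
        x = np.asarray(task_data, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required for array input")
        pre = x.shape[-1] / rate_hz / 2
        times = np.arange(x.shape[-1]) / rate_hz - pre
    if decomposition is None:
        decomposition = fa_sot(x, q=q)
    avg = x.mean(axis=1) if x.ndim == 3 else x          # cells x time
    L, psi = decomposition.loadings, decomposition.private_var
    # posterior-mean factor scores: E[f|x] = (I + L' Psi^-1 L)^-1 L' Psi^-1 x
    lp = L.T / psi[None, :]
    cov = np.eye(decomposition.q) + lp @ L
    scores = np.linalg.solve(cov, lp @ (avg - avg.mean(axis=1, keepdims=True)))
    if length_scale_s > 0:
        scores = gaussian_filter1d(scores, sigma=length_scale_s * rate_hz,
                                   axis=1, mode="nearest")
    touch_idx = int(np.argmin(np.abs(times)))
    return Trajectory(components=scores, times_s=times,
                      length_scale_s=length_scale_s, touch_index=touch_idx)
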