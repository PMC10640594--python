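"""Task- and cue-modulation classification of single cells.

A cell is *task-modulated* when its binned trial activity differs across
time bins: a one-way ANOVA across bins (trials as replicates) followed by
Tukey's HSD all-pairs comparison; the cell is flagged when any bin pair
is significant at ``alpha``.  The Tukey criterion is evaluated in closed
form against the studentized-range critical value, which is exactly
equivalent to thresholding every pairwise p-value at ``alpha`` and is
vectorized over cells.

Cue classification uses the same machinery on a door-open-aligned window;
cells significant there whose activity peaks before reach onset are
labeled cue-preferential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from graftdyn.preprocess import BinnedTensor


@dataclass
class ModulationResult:
    modulated: np.ndarray         # bool per cell
    p_omnibus: np.ndarray         # one-way ANOVA p per cell
    n_sig_pairs: np.ndarray       # significant Tukey pairs per cell
    computable: np.ndarray        # False where within-bin variance was zero
    alpha: float
    window_s: tuple

    @property
    def proportion(self) -> float:
        if self.computable.sum() == 0:
            raise ValueError("no computable cells")
        return float(self.modulated[self.computable].mean())

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": np.arange(len(self.modulated)),
            "modulated": self.modulated,
            "p_omnibus": self.p_omnibus,
            "n_sig_pairs": self.n_sig_pairs,
            "computable": self.computable,
        })


def anova_modulation(binned: BinnedTensor, window_bins=None,
                     alpha: float = 0.05) -> ModulationResult:
    """Flag cells whose mean activity differs between time bins.

    ``window_bins`` optionally restricts the test to a subset of bin
    indices.  Requires at least 2 bins and 2 trials.  Cells with zero
    within-bin variance everywhere are marked non-computable and
    excluded with a warning.
    """
    x = binned.data
    if window_bins is not None:
        x = x[:, :, window_bins]
    n_cells, n_trials, n_bins = x.shape
    if n_bins < 2:
        raise ValueError("need at least 2 time bins")
    if n_trials < 2:
        raise ValueError("need at least 2 trials (replicates)")

    means = x.mean(axis=1)                               # cells x bins
    ssw = ((x - means[:, None, :]) ** 2).sum(axis=(1, 2))
    df_w = n_bins * (n_trials - 1)
    mse = ssw / df_w
    computable = mse > 0
    if (~computable).any():
        warnings.warn(
            f"{int((~computable).sum())} cell(s) with zero within-bin "
            "variance excluded from modulation test")

    grand = means.mean(axis=1)
    ssb = n_trials * ((means - grand[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (n_bins - 1)) / mse
    p_omni = np.where(computable, sps.f.sf(f, n_bins - 1, df_w), np.nan)

    # Tukey HSD: pair (i, j) significant iff |m_i - m_j| / se > q_crit
    q_crit = sps.studentized_range.ppf(1 - alpha, n_bins, df_w)
    se = np.sqrt(mse / n_trials)
    diff = np.abs(means[:, :, None] - means[:, None, :])
    iu = np.triu_indices(n_bins, k=1)
    pair_diff = diff[:, iu[0], iu[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        n_sig = (pair_diff / se[:, None] > q_crit).sum(axis=1)
    n_sig = np.where(computable, n_sig, 0)
    modulated = computable & (n_sig > 0)
    return ModulationResult(modulated=modulated, p_omnibus=p_omni,
                            n_sig_pairs=n_sig, computable=computable,
                            alpha=alpha, window_s=binned.window_s)


def classify_task_and_cue(task_binned: BinnedTensor,
                          cue_binned: BinnedTensor = None,
                          alpha: float = 0.05,
                          reach_onset_s: float = 0.0) -> pd.DataFrame:
    """Label each cell ``task``, ``cue`` or ``none``.

    Task modulation is tested on the pellet-touch-aligned window, cue
    modulation on the door-open-aligned window.  A cue-significant cell
    is labeled ``cue`` (preferential cue activation) when its
    trial-averaged activity peaks before ``reach_onset_s`` in
    touch-aligned time (default: before pellet touch); cue-significant
    cells peaking later, and all other task-significant cells, are
    labeled ``task``.
    """
    task_res = anova_modulation(task_binned, alpha=alpha)
    if cue_binned is None:
        warnings.warn("no door-open-aligned data: cue classification skipped")
        cue_mod = np.zeros(task_binned.data.shape[0], dtype=bool)
    else:
        cue_mod = anova_modulation(cue_binned, alpha=alpha).modulated
    avg = task_binned.data.mean(axis=1)
    centers = task_binned.bin_edges_s + task_binned.bin_s / 2
    peak_t = centers[np.argmax(avg, axis=1)]
    label = np.where(cue_mod & (peak_t < reach_onset_s), "cue",
                     np.where(task_res.modulated | cue_mod, "task", "none"))
    return pd.DataFrame({
        "cell": np.arange(len(label)), "label": label,
        "task_modulated": task_res.modulated, "cue_modulated": cue_mod,
        "peak_time_s": peak_t, "p_omnibus": task_res.p_omnibus,
    })


def proportion_modulated(result: ModulationResult) -> float:
    """Fraction of computable cells flagged as modulated."""
    return result.proportion


def behavior_summary(results: dict, recordings: dict) -> pd.DataFrame:
    """Per-session summary rows (success rate, attempt rate, proportion
    modulated) from per-session modulation results and recordings."""
    rows = []
    for key, res in results.items():
        rec = recordings[key]
        rows.append({
            "session": key,
            "success_rate": float(np.mean(rec.success)),
            "attempt_rate": float(np.mean(rec.attempt)),
            "proportion_modulated": res.proportion,
        })
    return pd.DataFrame(rows)


def lme_correlation(summary: pd.DataFrame, y: str = "success_rate",
                    x: str = "proportion_modulated",
                    group: str = "mouse") -> dict:
    """Correlation between behavior and modulation via a linear
    mixed-effects model with random intercept and random slope per mouse.

    Both variables are z-scored before the (REML) fit so the fixed-effect
    slope is on the correlation scale and reported as ``r``; the random
    slope and intercept standard deviations are reported alongside.  With
    a single grouping level the model degenerates and a plain OLS slope
    is returned with a warning; a singular random-slope fit falls back to
    a random-intercept-only model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = summary[[x, y, group]].dropna().copy()
    if df[x].std(ddof=0) == 0:
        raise ValueError(f"zero variance in '{x}'")
    if len(df) < 3:
        raise ValueError("need at least 3 observations")
    df["_x"] = (df[x] - df[x].mean()) / df[x].std(ddof=0)
    df["_y"] = (df[y] - df[y].mean()) / df[y].std(ddof=0)

    if df[group].nunique() < 2:
        warnings.warn("single group: falling back to OLS")
        ols = smf.ols("_y ~ _x", data=df).fit()
        return {"r": float(ols.params["_x"]), "p": float(ols.pvalues["_x"]),
                "random_r_sd": 0.0, "random_intercept_sd": 0.0,
                "n_obs": len(df), "model": "ols"}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("_y ~ _x", data=df, groups=df[group],
                            re_formula="~_x")
        try:
            res = model.fit(reml=True)
            singular = np.any(np.diag(res.cov_re) < 1e-10) or not res.converged
        except Exception:
            res, singular = None, True
        if res is None or singular:
            warnings.warn("singular random-slope fit: using random intercept only")
            res = smf.mixedlm("_y ~ _x", data=df, groups=df[group]).fit(reml=True)
            slope_sd = 0.0
        else:
            slope_sd = float(np.sqrt(res.cov_re.iloc[1, 1]))
    return {"r": float(res.params["_x"]), "p": float(res.pvalues["_x"]),
            "random_r_sd": slope_sd,
            "random_intercept_sd": float(np.sqrt(res.cov_re.iloc[0, 0])),
            "n_obs": len(df), "model": "lme"}
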