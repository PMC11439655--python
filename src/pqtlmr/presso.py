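"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

A Monte-Carlo test for horizontal pleiotropy among MR instruments.  The
observed residual sum of squares

    RSS_obs = sum_j w_j * (beta_out_j - b_hat_{-j} * beta_exp_j)^2,

with b_hat_{-j} the leave-one-out IVW slope and w_j = 1/se_out_j^2, is
compared with its distribution under the no-pleiotropy model: in each
simulation replicate, exposure effects are redrawn around their estimates
and outcome effects around the leave-one-out predictions.  The same
machinery gives a per-variant outlier test (Bonferroni-corrected), an
outlier-corrected IVW estimate, and a distortion test asking whether
removing the flagged outliers moved the estimate more than removing a
random subset of the same size would.

All empirical p-values use the (r + 1)/(n + 1) estimator so they can never
be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mr import InsufficientInstrumentsError

__all__ = ["PressoReport", "presso"]


@dataclass
class PressoReport:
    """Global, per-variant and distortion test results for one protein."""

    global_rss: float
    global_p: float
    per_variant_p: dict[str, float]
    outliers: list[str]
    beta_raw: float
    beta_outlier_corrected: float | None
    distortion_p: float | None
    n_sim: int
    seed: int
    extra: dict = field(default_factory=dict)


def _ivw_slope(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> float:
    """IVW slope = weighted regression of by on bx through the origin."""
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every j, vectorized."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def presso(
    instrument_data,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoReport:
    """Run the global, outlier and distortion tests.

    Parameters
    ----------
    instrument_data
        DataFrame (or mapping) with columns ``variant_id``, ``beta_exp``,
        ``se_exp``, ``beta_out``, ``se_out`` — one row per instrument,
        at least four rows.
    n_sim
        Number of Monte-Carlo replicates (the test's resolution is
        1/(n_sim + 1)).
    outlier_alpha
        Per-variant significance level after Bonferroni correction.
    """
    import pandas as pd

    df = pd.DataFrame(instrument_data)
    j = len(df)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 instruments")
    variant_ids = df["variant_id"].astype(str).tolist()
    bx = df["beta_exp"].to_numpy(dtype=float)
    sx = df["se_exp"].to_numpy(dtype=float)
    by = df["beta_out"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    w = 1.0 / sy**2

    loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, j))

    # leave-one-out slopes within each simulated replicate
    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    loo_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim**2)
    resid_sim = w * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    # per-variant: observed weighted residual vs its simulated distribution
    exceed = (resid_sim >= resid_obs[None, :]).sum(axis=0)
    p_var = (1 + exceed) / (n_sim + 1)
    p_var_bonf = np.minimum(1.0, p_var * j)
    per_variant_p = dict(zip(variant_ids, map(float, p_var_bonf)))
    outlier_mask = p_var_bonf < outlier_alpha
    outliers = [v for v, o in zip(variant_ids, outlier_mask) if o]

    beta_raw = _ivw_slope(bx, by, w)
    beta_corrected = None
    distortion_p = None
    if outliers and outlier_mask.sum() < j:
        keep = ~outlier_mask
        beta_corrected = _ivw_slope(bx[keep], by[keep], w[keep])
        # distortion: slope after removing random subsets of the same size
        # from the simulated (no-pleiotropy) data
        n_out = int(outlier_mask.sum())
        slopes_sub = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            m = np.ones(j, dtype=bool)
            m[drop] = False
            slopes_sub[i] = _ivw_slope(bx_sim[i, m], by_sim[i, m], w[m])
        lower = np.sum(slopes_sub <= beta_corrected)
        upper = np.sum(slopes_sub >= beta_corrected)
        distortion_p = float(
            min(1.0, 2.0 * (1 + min(lower, upper)) / (n_sim + 1))
        )
    return PressoReport(
        global_rss=rss_obs,
        global_p=global_p,
        per_variant_p=per_variant_p,
        outliers=outliers,
        beta_raw=beta_raw,
        beta_outlier_corrected=beta_corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )
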