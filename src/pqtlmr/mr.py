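"""Two-sample MR estimators and sensitivity diagnostics.

Implements the validation-stage battery of a drug-target MR screen:

* per-variant Wald ratio estimates with first-order standard errors;
* inverse-variance-weighted (IVW) meta-analysis with Cochran's Q and the
  fixed/random-effects switch (random effects when the Q p-value < 0.05,
  implemented as multiplicative overdispersion of the fixed-effects SE);
* MR-Egger regression, whose intercept estimates directional horizontal
  pleiotropy;
* the weighted-median estimator, consistent when at least half of the
  instrument weight comes from valid instruments;
* leave-one-out refits and plot-ready forest/funnel/scatter tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .smr import or_ci
from .sumstats import HarmonizedSet

__all__ = [
    "MRResult",
    "HeterogeneityReport",
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "leave_one_out",
    "diagnostics_tables",
    "mr_battery",
]


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator requires."""


@dataclass
class MRResult:
    """One estimator's causal-effect estimate for one protein."""

    protein: str
    method: str  # ivw_fixed | ivw_random | egger | weighted_median
    n_snp: int
    beta: float
    se: float
    pvalue: float
    or_point: float
    or_ci_low: float
    or_ci_high: float
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None

    @classmethod
    def from_estimate(cls, protein, method, n_snp, beta, se, pvalue, **kw):
        point, lo, hi = or_ci(beta, se)
        return cls(protein, method, n_snp, float(beta), float(se), float(pvalue),
                   point, lo, hi, **kw)


@dataclass
class HeterogeneityReport:
    """Cochran's Q across ratio estimates and the model it selects."""

    q_stat: float
    df: int
    q_pvalue: float
    model_selected: str  # fixed | random


def ratio_estimates(harmonized: HarmonizedSet) -> pd.DataFrame:
    """Per-variant Wald ratios: b = beta_out/beta_exp, se = se_out/|beta_exp|.

    The first-order SE ignores exposure-side sampling error, the standard
    choice for strong (F > 10) instruments.  Variants with a null exposure
    effect are dropped.
    """
    p = harmonized.pairs
    keep = p["beta_exp"] != 0
    p = p.loc[keep]
    b = p["beta_out"] / p["beta_exp"]
    se = p["se_out"] / p["beta_exp"].abs()
    return pd.DataFrame(
        {
            "variant_id": p["variant_id"],
            "b_ratio": b,
            "se_ratio": se,
            "weight": 1.0 / se**2,
            "beta_exp": p["beta_exp"],
            "se_exp": p["se_exp"],
            "beta_out": p["beta_out"],
            "se_out": p["se_out"],
        }
    ).reset_index(drop=True)


def ivw(
    estimates: pd.DataFrame, model: str = "auto", protein: str = ""
) -> tuple[MRResult, HeterogeneityReport]:
    """Inverse-variance-weighted meta-analysis of ratio estimates.

    ``model`` is ``"fixed"``, ``"random"`` or ``"auto"``; auto selects
    random effects exactly when the Cochran's Q p-value is below 0.05.
    Random effects inflates the fixed-effects SE by sqrt(max(1, Q/df)).
    """
    j = len(estimates)
    if j == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    w = estimates["weight"].to_numpy()
    b = estimates["b_ratio"].to_numpy()
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)

    if j >= 2:
        q = float(np.sum(w * (b - beta) ** 2))
        df = j - 1
        q_p = float(stats.chi2.sf(q, df))
    else:
        q, df, q_p = float("nan"), 0, 1.0

    if model == "auto":
        selected = "random" if (df >= 1 and q_p < 0.05) else "fixed"
    elif model in ("fixed", "random"):
        selected = model
    else:
        raise ValueError(f"unknown model {model!r}")

    se = se_fixed
    if selected == "random" and df >= 1:
        se = se_fixed * float(np.sqrt(max(1.0, q / df)))
    pvalue = float(2.0 * stats.norm.sf(abs(beta) / se))
    result = MRResult.from_estimate(
        protein, f"ivw_{selected}", j, beta, se, max(pvalue, np.finfo(float).tiny)
    )
    return result, HeterogeneityReport(q, df, q_p, selected)


def egger(estimates: pd.DataFrame, protein: str = "") -> MRResult:
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    Pairs are oriented so that every exposure beta is positive (both betas
    of a pair are negated when flipping); weights are 1/se_out^2.  Standard
    errors carry multiplicative overdispersion floored at 1, and inference
    uses the t distribution with J - 2 degrees of freedom.  The intercept
    estimates the average directional pleiotropic effect.
    """
    j = len(estimates)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    sign = np.sign(estimates["beta_exp"].to_numpy())
    bx = estimates["beta_exp"].to_numpy() * sign
    by = estimates["beta_out"].to_numpy() * sign
    w = 1.0 / estimates["se_out"].to_numpy() ** 2

    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    sigma2 = float(fit.scale)  # residual mean square of the weighted fit
    inter, slope = fit.params
    # overdispersion floored at 1 (never deflate below the fixed-effect SE)
    se_inter, se_slope = np.sqrt(
        np.diag(fit.normalized_cov_params) * max(1.0, sigma2)
    )
    df = j - 2
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    p_inter = float(2.0 * stats.t.sf(abs(inter) / se_inter, df))
    return MRResult.from_estimate(
        protein, "egger", j, slope, se_slope, max(p_slope, np.finfo(float).tiny),
        egger_intercept=float(inter), egger_intercept_p=p_inter,
    )


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median at cumulative weight 0.5."""
    order = np.argsort(b)
    b, w = b[order], w[order]
    wn = w / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, b))


def weighted_median(
    estimates: pd.DataFrame, n_boot: int = 1000, seed: int = 0, protein: str = ""
) -> MRResult:
    """Weighted-median MR estimate with a parametric-bootstrap SE.

    The bootstrap redraws each ratio estimate from N(b_ratio, se_ratio^2)
    (weights held fixed) and takes the standard deviation of the re-computed
    medians, seeded for reproducibility.
    """
    j = len(estimates)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 instruments")
    b = estimates["b_ratio"].to_numpy()
    se = estimates["se_ratio"].to_numpy()
    w = estimates["weight"].to_numpy()
    est = _weighted_median(b, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se, size=(n_boot, j))
    boots = np.array([_weighted_median(d, w) for d in draws])
    se_boot = float(boots.std(ddof=1))
    pvalue = float(2.0 * stats.norm.sf(abs(est) / se_boot)) if se_boot > 0 else 1.0
    return MRResult.from_estimate(
        protein, "weighted_median", j, est, se_boot, max(pvalue, np.finfo(float).tiny)
    )


def leave_one_out(estimates: pd.DataFrame, protein: str = "") -> pd.DataFrame:
    """IVW (auto model) refits omitting one instrument at a time.

    A refit is flagged when omitting the variant flips the sign of the
    estimate or moves it by more than one SE of the refit (the refit SE is
    the relevant yardstick: omitting a gross outlier shrinks the
    heterogeneity inflation that the outlier itself caused).
    """
    j = len(estimates)
    if j < 2:
        raise InsufficientInstrumentsError("leave-one-out requires at least 2 instruments")
    full, _ = ivw(estimates, model="auto", protein=protein)
    rows = []
    for i in range(j):
        sub = estimates.drop(index=estimates.index[i])
        fit, _ = ivw(sub, model="auto", protein=protein)
        shift = fit.beta - full.beta
        rows.append(
            {
                "left_out_variant": estimates.iloc[i]["variant_id"],
                "ivw_beta": fit.beta,
                "ivw_se": fit.se,
                "shift": shift,
                "flagged": bool(
                    (np.sign(fit.beta) != np.sign(full.beta) and full.beta != 0)
                    or abs(shift) > fit.se
                ),
            }
        )
    return pd.DataFrame(rows)


def diagnostics_tables(
    estimates: pd.DataFrame,
    ivw_result: MRResult,
    egger_result: MRResult | None = None,
) -> dict[str, pd.DataFrame]:
    """Plot-ready forest, funnel and scatter tables (pure reformatting)."""
    forest = estimates[["variant_id", "b_ratio", "se_ratio"]].copy()
    forest["ci_low"] = forest["b_ratio"] - 1.959964 * forest["se_ratio"]
    forest["ci_high"] = forest["b_ratio"] + 1.959964 * forest["se_ratio"]

    funnel = pd.DataFrame(
        {
            "variant_id": estimates["variant_id"],
            "b_ratio": estimates["b_ratio"],
            "precision": 1.0 / estimates["se_ratio"],
        }
    )

    scatter = estimates[["variant_id", "beta_exp", "se_exp", "beta_out", "se_out"]].copy()
    scatter["ivw_fit"] = ivw_result.beta * scatter["beta_exp"]
    if egger_result is not None:
        scatter["egger_fit"] = (
            egger_result.egger_intercept + egger_result.beta * scatter["beta_exp"].abs()
        ) * np.sign(scatter["beta_exp"])
    return {"forest": forest, "funnel": funnel, "scatter": scatter}


def mr_battery(
    harmonized: HarmonizedSet,
    protein: str = "",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Run IVW (auto), MR-Egger and weighted median on one harmonized set.

    Estimators whose instrument-count preconditions are not met are simply
    absent from the returned dict; ``heterogeneity`` and ``loo`` ride along
    when computable.
    """
    est = ratio_estimates(harmonized)
    out: dict = {"estimates": est}
    if len(est) == 0:
        return out
    res, het = ivw(est, model="auto", protein=protein)
    out["ivw"] = res
    out["heterogeneity"] = het
    if len(est) >= 3:
        out["egger"] = egger(est, protein=protein)
        out["weighted_median"] = weighted_median(est, n_boot=n_boot, seed=seed, protein=protein)
    if len(est) >= 2:
        out["loo"] = leave_one_out(est, protein=protein)
    out["diagnostics"] = diagnostics_tables(est, out["ivw"], out.get("egger"))
    return out
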