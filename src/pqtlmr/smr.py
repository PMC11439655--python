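"""Summary-data-based Mendelian randomization (SMR) and FDR correction.

The SMR test asks whether a trait association at a locus is mediated by a
molecular exposure (here: plasma protein abundance).  For the top cis-pQTL
of a protein, the causal effect of the protein on the outcome is estimated
by the Wald ratio

    b_SMR = b_GWAS / b_pQTL

and tested with the statistic

    T = (z_GWAS^2 * z_pQTL^2) / (z_GWAS^2 + z_pQTL^2)  ~  chi-square(1),

which accounts for sampling error in both the numerator and denominator
z-scores.  Across the protein screen, p-values are adjusted with the
Benjamini-Hochberg false discovery rate; P_FDR < 0.05 is the screen's
significance rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .instruments import InstrumentSet
from .sumstats import HarmonizedSet

__all__ = ["SMRResult", "smr_test", "or_ci", "bh_fdr", "smr_for_protein", "smr_table"]

Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass
class SMRResult:
    """SMR estimate for one protein, anchored at its top cis-pQTL."""

    protein: str
    top_variant: str
    beta_smr: float
    se_smr: float
    p_smr: float
    or_point: float
    or_ci_low: float
    or_ci_high: float
    p_fdr: float | None = None


def smr_test(
    beta_gwas: float, se_gwas: float, beta_pqtl: float, se_pqtl: float
) -> tuple[float, float, float]:
    """Return ``(beta_smr, se_smr, p_smr)`` for a single instrument.

    ``se_smr`` is |beta_smr|/sqrt(T) (NaN when T = 0, i.e. a null GWAS
    effect, where the ratio carries no information about its own scale).
    """
    if se_gwas <= 0 or se_pqtl <= 0:
        raise ValueError("standard errors must be positive")
    if beta_pqtl == 0:
        raise ZeroDivisionError("beta_pqtl = 0: SMR ratio undefined")
    beta_smr = beta_gwas / beta_pqtl
    z_g = beta_gwas / se_gwas
    z_p = beta_pqtl / se_pqtl
    t_smr = (z_g**2 * z_p**2) / (z_g**2 + z_p**2)
    p_smr = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    se_smr = abs(beta_smr) / np.sqrt(t_smr) if t_smr > 0 else float("nan")
    return float(beta_smr), float(se_smr), p_smr


def or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio and confidence interval from a log-odds estimate."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr: empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def smr_for_protein(harmonized: HarmonizedSet, instruments: InstrumentSet) -> SMRResult | None:
    """SMR test at the protein's top cis-pQTL (smallest pQTL p among instruments).

    Returns None when the protein has no instruments or the top instrument
    is not present in the harmonized exposure/outcome set.
    """
    if len(instruments) == 0:
        return None
    inst = instruments.instruments
    z = (inst["beta"] / inst["se"]).abs()
    top = inst.loc[z.idxmax()]
    rows = harmonized.pairs.loc[harmonized.pairs["variant_id"] == top["variant_id"]]
    if rows.empty:
        return None
    r = rows.iloc[0]
    beta, se, p = smr_test(r["beta_out"], r["se_out"], r["beta_exp"], r["se_exp"])
    if np.isnan(se):
        point, lo, hi = float(np.exp(beta)), float("nan"), float("nan")
    else:
        point, lo, hi = or_ci(beta, se)
    return SMRResult(
        protein=instruments.protein,
        top_variant=str(r["variant_id"]),
        beta_smr=beta,
        se_smr=se,
        p_smr=p,
        or_point=point,
        or_ci_low=lo,
        or_ci_high=hi,
    )


def smr_table(results: list[SMRResult]) -> pd.DataFrame:
    """Assemble the screen-level SMR report and fill in FDR-adjusted p-values.

    FDR correction is applied across every protein in the run (mirroring a
    proteome-wide screen), and the table carries both the raw SMR p and
    the adjusted value.
    """
    if not results:
        return pd.DataFrame(
            columns=[
                "protein", "top_variant", "beta_smr", "se_smr", "p_smr",
                "p_fdr", "or_point", "or_ci_low", "or_ci_high",
            ]
        )
    padj = bh_fdr([r.p_smr for r in results])
    rows = []
    for r, q in zip(results, padj):
        r.p_fdr = float(q)
        rows.append(
            {
                "protein": r.protein,
                "top_variant": r.top_variant,
                "beta_smr": r.beta_smr,
                "se_smr": r.se_smr,
                "p_smr": r.p_smr,
                "p_fdr": r.p_fdr,
                "or_point": r.or_point,
                "or_ci_low": r.or_ci_low,
                "or_ci_high": r.or_ci_high,
            }
        )
    return pd.DataFrame(rows).sort_values("protein").reset_index(drop=True)
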