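"""Bayesian colocalization under the five-hypothesis framework.

Given per-variant summary statistics for two traits over one genomic
region, the method compares:

* H0 — neither trait is associated in the region;
* H1 — only trait 1 (protein) is associated;
* H2 — only trait 2 (outcome) is associated;
* H3 — both are associated, through *different* causal variants;
* H4 — both are associated, through the *same* causal variant.

Each variant's evidence for association is a Wakefield log approximate
Bayes factor

    lABF = 0.5 * (ln(1 - r) + r * z^2),    r = W / (W + V),

with z = beta/se, V = se^2 and W the prior variance of a true effect.
Hypothesis weights combine the per-variant Bayes factors with the priors
p1, p2 (single-trait association) and p12 (shared causal variant); all
sums over variants are done with log-sum-exp so that regions with very
strong signals do not overflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import EmptyInputError, SummaryDataset

logger = logging.getLogger(__name__)

__all__ = ["ColocPriors", "ColocResult", "labf", "coloc_abf", "regional_table"]

#: prior standard deviation of a true effect, standardized quantitative trait
W_QUANT = 0.15**2
#: prior standard deviation of a true log-odds effect, case-control trait
W_CC = 0.2**2

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities for the three association patterns."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            warnings.warn(
                "p12 exceeds min(p1, p2); the shared-variant prior is usually "
                "no larger than either single-trait prior"
            )


@dataclass
class ColocResult:
    """Posterior probabilities of H0-H4 for one protein region."""

    protein: str
    n_snps: int
    pp: dict[str, float]
    priors: ColocPriors = field(default_factory=ColocPriors)
    window_bp: int | None = None

    @property
    def pp_h4(self) -> float:
        return self.pp["pp_h4"]

    @property
    def best(self) -> str:
        return max(self.pp, key=self.pp.get)


def labf(beta, se, prior_w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor (association vs. null)."""
    if prior_w <= 0:
        raise ValueError("prior_w must be positive")
    beta = np.asarray(beta, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    if np.any(v <= 0):
        raise ValueError("se must be positive")
    r = prior_w / (prior_w + v)
    z2 = beta**2 / v
    # ln(1 - r) written as ln(V) - ln(W + V), stable when r is close to 1
    return 0.5 * (np.log(v) - np.log(prior_w + v) + r * z2)


def _align_regions(
    region_pqtl: SummaryDataset, region_gwas: SummaryDataset
) -> pd.DataFrame:
    """Intersect two region slices by variant id and align effect alleles.

    Allele alignment only affects the sign of beta, which the Bayes factors
    square away, but it keeps the returned table usable for plotting and
    sanity checks.  Irreconcilable allele pairs are dropped.
    """
    from .sumstats import harmonize

    hs = harmonize(region_pqtl, region_gwas, palindrome_eaf_margin=0.0)
    return hs.pairs


def coloc_abf(
    region_pqtl: SummaryDataset,
    region_gwas: SummaryDataset,
    priors: ColocPriors | None = None,
    w_quant: float = W_QUANT,
    w_cc: float = W_CC,
    protein: str | None = None,
) -> ColocResult:
    """Colocalize a protein's cis region with the outcome GWAS.

    Trait 1 is the (quantitative) protein, trait 2 the outcome; when the
    outcome dataset is case-control the log-odds effect prior ``w_cc`` is
    used for it, otherwise ``w_quant``.

    The H3 weight is the sum of Bayes factors over *ordered pairs of
    distinct variants*, ``S1*S2 - S12``, computed in log space and floored
    at zero (it can only be negative through rounding).
    """
    priors = priors or ColocPriors()
    pairs = _align_regions(region_pqtl, region_gwas)
    if pairs.empty:
        raise EmptyInputError("coloc: no shared variants in the region")

    w2 = w_cc if region_gwas.trait_type == "case_control" else w_quant
    w1 = w_cc if region_pqtl.trait_type == "case_control" else w_quant
    l1 = labf(pairs["beta_exp"].to_numpy(), pairs["se_exp"].to_numpy(), w1)
    l2 = labf(pairs["beta_out"].to_numpy(), pairs["se_out"].to_numpy(), w2)

    log_s1 = logsumexp(l1)
    log_s2 = logsumexp(l2)
    log_s12 = logsumexp(l1 + l2)

    log_w = np.empty(5)
    log_w[0] = 0.0
    log_w[1] = np.log(priors.p1) + log_s1
    log_w[2] = np.log(priors.p2) + log_s2
    # H3: log(S1*S2 - S12) via the complement trick, floored at zero weight
    diff = log_s12 - (log_s1 + log_s2)
    if len(pairs) == 1 or diff >= 0:
        log_w[3] = -np.inf
    else:
        log_w[3] = np.log(priors.p1) + np.log(priors.p2) + log_s1 + log_s2 + np.log1p(-np.exp(diff))
    log_w[4] = np.log(priors.p12) + log_s12

    pp = np.exp(log_w - logsumexp(log_w))
    pp /= pp.sum()
    return ColocResult(
        protein=protein or region_pqtl.trait_name,
        n_snps=len(pairs),
        pp=dict(zip(HYPOTHESES, map(float, pp))),
        priors=priors,
    )


def regional_table(
    region_pqtl: SummaryDataset,
    region_gwas: SummaryDataset,
    ld=None,
) -> pd.DataFrame:
    """Plot-ready regional association table for a colocalization locus.

    One row per shared variant: position, -log10 p for both traits
    (recomputed from beta/se) and, when an LD reference is given, the r^2
    of each variant with the region's lead pQTL variant.
    """
    from scipy import stats

    pairs = _align_regions(region_pqtl, region_gwas)
    zp = (pairs["beta_exp"] / pairs["se_exp"]).abs()
    zg = (pairs["beta_out"] / pairs["se_out"]).abs()
    # two-sided: -log10(2 * sf(|z|)) computed stably in log space
    out = pd.DataFrame(
        {
            "variant_id": pairs["variant_id"],
            "position": pairs["position"],
            "neglog10_p_pqtl": -(stats.norm.logsf(zp) + np.log(2.0)) / np.log(10),
            "neglog10_p_gwas": -(stats.norm.logsf(zg) + np.log(2.0)) / np.log(10),
        }
    )
    lead = pairs.loc[zp.idxmax(), "variant_id"]
    if ld is not None:
        out["r2_to_lead"] = [
            ld.r(lead, v) ** 2 if (v in ld and lead in ld) else np.nan
            for v in pairs["variant_id"]
        ]
    out["lead_variant"] = lead
    return out
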