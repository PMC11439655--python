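"""Synthetic GWAS/pQTL summary statistics with known ground truth.

Summary statistics are simulated directly from their asymptotic sampling
distribution on the standardized scale — no individual-level genotypes.
For a region with LD correlation matrix ``R`` and true standardized joint
effects ``b``, the marginal standardized effect estimates are

    beta_hat ~ MVN(R @ b, R / n),

equivalently ``z = sqrt(n) * beta_hat`` with mean ``sqrt(n) * R @ b`` and
covariance ``R``.  Estimates are then rescaled to the units the pipeline
consumes: per-allele SD units for the protein trait (``se = 1/sqrt(2f(1-f)n)``)
and per-allele log-odds for the case-control trait
(``se = 1/sqrt(2f(1-f) n s (1-s))`` with ``s`` the case proportion).

The causal protein-to-outcome effect ``theta`` is expressed in log-odds of
the outcome per SD of protein, so the GWAS standardized joint effect at a
protein causal variant is ``theta * b_protein * sqrt(s(1-s))``; with that
convention the per-allele Wald ratio recovers ``theta`` on the log-odds
scale.

Two generators cover the pipeline's needs:

* :func:`simulate_region` — one cis region under a colocalization
  hypothesis H0-H4 (shared vs. distinct causal variants, AR(1) LD);
* :func:`simulate_instruments` — independent instruments for the MR
  estimator battery, with optional balanced/directional pleiotropy and
  planted outliers;
* :func:`simulate_cohort` — a multi-protein screen mixing scenarios, with
  a truth table recording which evidence tier each protein should reach.

Sample-size presets mirror the scale of the real resources this emulates:
a 35,559-sample pQTL study, a discovery GWAS of 247,173 with 54% cases,
and a replication GWAS of 201,713 with 9.3% cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import (
    HarmonizedSet,
    LDReference,
    SummaryDataset,
    write_ld_reference,
    write_summary_stats,
)

__all__ = [
    "RegionScenario",
    "InstrumentScenario",
    "ar1_corr",
    "simulate_region",
    "simulate_instruments",
    "simulate_cohort",
    "PQTL_N",
    "DISCOVERY_N",
    "DISCOVERY_CASE_PROP",
    "REPLICATION_N",
    "REPLICATION_CASE_PROP",
]

# scale presets: deCODE-like pQTL panel, BCAC-like discovery GWAS,
# FinnGen-like replication GWAS
PQTL_N = 35_559
DISCOVERY_N = 247_173
DISCOVERY_CASE_PROP = 133_384 / 247_173
REPLICATION_N = 201_713
REPLICATION_CASE_PROP = 18_786 / 201_713

REGION_BP = 1_000_000

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class RegionScenario:
    """One cis region under a colocalization hypothesis.

    ``var_explained_pqtl`` is the protein variance explained by the causal
    pQTL (0.10 by default — a strong top cis-pQTL); ``theta`` the causal
    log-odds effect per SD of protein (0.35, in the range of published
    protein-breast-cancer effects).
    """

    scenario: str  # H0 | H1 | H2 | H3 | H4
    m_snps: int = 200
    rho: float = 0.9
    n_pqtl: int = 10_000
    n_gwas: int = 10_000
    case_proportion: float = 0.5
    var_explained_pqtl: float = 0.10
    theta: float = 0.35
    causal_index_pqtl: int | None = None
    causal_index_gwas: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("H0", "H1", "H2", "H3", "H4"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        m = self.m_snps
        if self.causal_index_pqtl is None:
            self.causal_index_pqtl = m // 4 if self.scenario == "H3" else m // 2
        if self.causal_index_gwas is None:
            self.causal_index_gwas = (3 * m) // 4 if self.scenario == "H3" else m // 2
        if self.scenario == "H4" and self.causal_index_pqtl != self.causal_index_gwas:
            raise ValueError("H4 requires a shared causal index")
        if self.scenario == "H3" and self.causal_index_pqtl == self.causal_index_gwas:
            raise ValueError("H3 requires distinct causal indices")


@dataclass
class InstrumentScenario:
    """Independent-instrument scenario for the MR estimator battery."""

    j_instruments: int = 50
    theta: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_scale: float = 0.0
    prop_invalid: float = 0.0
    outlier_indices: tuple[int, ...] = ()
    outlier_shift_se: float = 0.0
    se_exp: float = 0.01
    se_out: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 <= self.prop_invalid < 1:
            raise ValueError("prop_invalid must lie in [0, 1)")
        if any(i < 0 or i >= self.j_instruments for i in self.outlier_indices):
            raise ValueError("outlier index out of range")


def ar1_corr(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: r_ij = rho^|i-j| (always PSD for |rho| < 1)."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _chol(r: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(r)
        if w.min() < -1e-8:
            raise ValueError("LD matrix not PSD even after eigenvalue floor")
        w = np.clip(w, 1e-10, None)
        return v * np.sqrt(w)


def _marginal_z(r: np.ndarray, chol: np.ndarray, joint_std: np.ndarray,
                n: int, rng: np.random.Generator) -> np.ndarray:
    """Marginal z-scores: mean sqrt(n) * R @ b, covariance R."""
    return np.sqrt(n) * (r @ joint_std) + chol @ rng.standard_normal(len(joint_std))


def _region_frame(prefix: str, chromosome: str, m: int, maf: np.ndarray,
                  z: np.ndarray, se_allele: np.ndarray, n: int,
                  alleles: np.ndarray, positions: np.ndarray) -> pd.DataFrame:
    from scipy import stats

    beta = z * se_allele
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "variant_id": [f"{prefix}_v{i:04d}" for i in range(m)],
            "chromosome": chromosome,
            "position": positions,
            "effect_allele": [_ALLELE_PAIRS[a][0] for a in alleles],
            "other_allele": [_ALLELE_PAIRS[a][1] for a in alleles],
            "eaf": maf,  # effect allele chosen as the minor allele
            "beta": beta,
            "se": se_allele,
            "pvalue": np.maximum(p, np.finfo(float).tiny),
            "n": n,
        }
    )


def _simulate_region_pair(
    *,
    prefix: str,
    chromosome: str,
    m: int,
    rho: float,
    joint_pqtl: np.ndarray,
    joint_gwas_std: np.ndarray,
    n_pqtl: int,
    n_gwas: int,
    case_proportion: float,
    rng: np.random.Generator,
    protein_name: str,
    gwas_name: str,
    chol: np.ndarray | None = None,
    r: np.ndarray | None = None,
) -> tuple[SummaryDataset, SummaryDataset, LDReference]:
    if r is None:
        r = ar1_corr(m, rho)
    if chol is None:
        chol = _chol(r)
    maf = rng.uniform(0.05, 0.5, size=m)
    h = 2.0 * maf * (1.0 - maf)
    positions = np.linspace(1, REGION_BP, m).round().astype(int)
    alleles = rng.integers(0, len(_ALLELE_PAIRS), size=m)

    z_p = _marginal_z(r, chol, joint_pqtl, n_pqtl, rng)
    se_p = 1.0 / np.sqrt(h * n_pqtl)
    pqtl = SummaryDataset(
        protein_name,
        "quantitative",
        _region_frame(prefix, chromosome, m, maf, z_p, se_p, n_pqtl, alleles, positions),
    )

    s = case_proportion
    z_g = _marginal_z(r, chol, joint_gwas_std, n_gwas, rng)
    se_g = 1.0 / np.sqrt(h * n_gwas * s * (1.0 - s))
    gframe = _region_frame(prefix, chromosome, m, maf, z_g, se_g, n_gwas, alleles, positions)
    gframe["n_cases"] = int(round(n_gwas * s))
    gwas = SummaryDataset(gwas_name, "case_control", gframe, case_proportion=s)

    ld = LDReference(list(pqtl.records["variant_id"]), r)
    return pqtl, gwas, ld


def simulate_region(scenario: RegionScenario, prefix: str = "region",
                    chromosome: str = "1"):
    """Simulate one region under H0-H4.

    Returns ``(pqtl, gwas, ld, truth)`` where ``truth`` records the latent
    causal structure (scenario, causal indices, joint effects, theta).
    """
    rng = np.random.default_rng(scenario.seed)
    m = scenario.m_snps
    b = float(np.sqrt(scenario.var_explained_pqtl))
    s = scenario.case_proportion
    g = scenario.theta * b * np.sqrt(s * (1.0 - s))

    joint_p = np.zeros(m)
    joint_g = np.zeros(m)
    if scenario.scenario in ("H1", "H3", "H4"):
        joint_p[scenario.causal_index_pqtl] = b
    if scenario.scenario == "H4":
        joint_g[scenario.causal_index_gwas] = g
    elif scenario.scenario in ("H2", "H3"):
        joint_g[scenario.causal_index_gwas] = abs(g) if g else 0.0

    pqtl, gwas, ld = _simulate_region_pair(
        prefix=prefix,
        chromosome=chromosome,
        m=m,
        rho=scenario.rho,
        joint_pqtl=joint_p,
        joint_gwas_std=joint_g,
        n_pqtl=scenario.n_pqtl,
        n_gwas=scenario.n_gwas,
        case_proportion=s,
        rng=rng,
        protein_name=prefix,
        gwas_name=f"{prefix}_gwas",
    )
    truth = {
        "scenario": scenario.scenario,
        "causal_index_pqtl": scenario.causal_index_pqtl,
        "causal_index_gwas": scenario.causal_index_gwas,
        "theta": scenario.theta,
        "var_explained_pqtl": scenario.var_explained_pqtl,
        "joint_pqtl": joint_p,
        "joint_gwas_std": joint_g,
        "seed": scenario.seed,
    }
    return pqtl, gwas, ld, truth


def simulate_instruments(scenario: InstrumentScenario, protein: str = "protein"):
    """Simulate J independent, pre-harmonized instruments.

    True exposure effects are drawn from N(0.15, 0.05^2) truncated to be
    positive; true outcome effects are ``theta * beta_exp + alpha`` with
    ``alpha`` the pleiotropic component on the invalid fraction (zero-mean
    normal for balanced pleiotropy, a constant shift for directional).
    Observed statistics add N(0, se) noise on each side; planted outliers
    shift the observed outcome effect by ``outlier_shift_se * se_out``.

    Returns ``(HarmonizedSet, truth)`` with the truth record carrying the
    latent effects and validity labels.
    """
    from scipy import stats

    rng = np.random.default_rng(scenario.seed)
    j = scenario.j_instruments
    a = (0.0 - 0.15) / 0.05
    true_bx = stats.truncnorm.rvs(a, np.inf, loc=0.15, scale=0.05, size=j,
                                  random_state=rng)

    alpha = np.zeros(j)
    invalid = np.zeros(j, dtype=bool)
    n_invalid = int(round(scenario.prop_invalid * j))
    if scenario.pleiotropy_mode != "none" and n_invalid > 0:
        idx = rng.choice(j, size=n_invalid, replace=False)
        invalid[idx] = True
        if scenario.pleiotropy_mode == "balanced":
            alpha[idx] = rng.normal(0.0, scenario.pleiotropy_scale, size=n_invalid)
        else:
            alpha[idx] = scenario.pleiotropy_scale
    elif scenario.pleiotropy_mode == "directional" and n_invalid == 0:
        # directional pleiotropy with no stated invalid fraction applies to all
        invalid[:] = True
        alpha[:] = scenario.pleiotropy_scale

    true_by = scenario.theta * true_bx + alpha

    se_exp = np.full(j, scenario.se_exp, dtype=float)
    se_out = np.full(j, scenario.se_out, dtype=float)
    bx_hat = rng.normal(true_bx, se_exp)
    by_hat = rng.normal(true_by, se_out)
    for i in scenario.outlier_indices:
        by_hat[i] += scenario.outlier_shift_se * se_out[i]

    from scipy.stats import norm

    pairs = pd.DataFrame(
        {
            "variant_id": [f"iv{i:03d}" for i in range(j)],
            "chromosome": "1",
            "position": np.arange(1, j + 1) * 1_000_000,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf_exp": 0.3,
            "beta_exp": bx_hat,
            "se_exp": se_exp,
            "pvalue_exp": np.maximum(2 * norm.sf(np.abs(bx_hat / se_exp)), 1e-300),
            "n_exp": PQTL_N,
            "eaf_out": 0.3,
            "beta_out": by_hat,
            "se_out": se_out,
            "pvalue_out": np.maximum(2 * norm.sf(np.abs(by_hat / se_out)), 1e-300),
            "n_out": DISCOVERY_N,
        }
    )
    truth = {
        "theta": scenario.theta,
        "true_beta_exp": true_bx,
        "true_beta_out": true_by,
        "alpha": alpha,
        "invalid": invalid,
        "outlier_indices": list(scenario.outlier_indices),
        "seed": scenario.seed,
    }
    return HarmonizedSet(protein, pairs), truth


# ---------------------------------------------------------------------------
# multi-protein cohorts for the end-to-end pipeline
# ---------------------------------------------------------------------------

#: default 20-protein cohort: a mixture of planted evidence tiers and nulls
DEFAULT_COHORT_PLAN = (
    ["tier1"] * 3 + ["tier2"] * 3 + ["tier3"] * 3 + ["h3"] * 4 + ["h0"] * 4
    + ["weak"] * 3
)

#: variance explained by each of a protein's independent cis signals; a
#: strongly dominant lead signal keeps the top variant (and the coloc
#: lead pair) unambiguous in every replicate
_COHORT_VE = (0.050, 0.010, 0.010, 0.008, 0.008)
_COHORT_THETA = 0.3
_COHORT_M = 200
_COHORT_RHO = 0.9
_COHORT_SITES = (20, 60, 100, 140, 180)  # >= 33 apart: r^2 < 0.001 at rho = 0.9


@dataclass
class CohortTruth:
    """Planted truth for one cohort protein."""

    protein: str
    kind: str
    expected_tier: str
    theta_discovery: float
    theta_replication: float


_EXPECTED_TIER = {"tier1": "1", "tier2": "2", "tier3": "3",
                  "h3": "none", "h0": "none", "weak": "none"}


def _cohort_joint_effects(kind: str, s_disc: float, s_rep: float):
    """Standardized joint effect vectors (protein, discovery, replication)."""
    m = _COHORT_M
    joint_p = np.zeros(m)
    joint_d = np.zeros(m)
    joint_r = np.zeros(m)
    b = np.sqrt(np.array(_COHORT_VE))
    sites = np.array(_COHORT_SITES)

    if kind in ("tier1", "tier2", "tier3"):
        joint_p[sites] = b
        if kind in ("tier1", "tier2"):
            # exclusion restriction holds: GWAS effect proportional to the
            # protein effect at every causal site
            joint_d[sites] = _COHORT_THETA * b * np.sqrt(s_disc * (1 - s_disc))
            th_rep = _COHORT_THETA if kind == "tier1" else 0.0
            joint_r[sites] = th_rep * b * np.sqrt(s_rep * (1 - s_rep))
            return joint_p, joint_d, joint_r, _COHORT_THETA, th_rep
        # tier3: strong colocalizing signal at the lead site, but the
        # remaining instruments carry opposing pleiotropic outcome effects
        # chosen so the IVW-weighted mean ratio is zero
        for joint, s in ((joint_d, s_disc), (joint_r, s_rep)):
            g1 = _COHORT_THETA * b[0] * np.sqrt(s * (1 - s))
            g_rest = -g1 * b[0] / b[1:].sum()  # makes sum_j b_j g_j = 0
            joint[sites] = [g1] + [g_rest] * (len(sites) - 1)
        return joint_p, joint_d, joint_r, 0.0, 0.0
    if kind == "h3":
        joint_p[sites[0]] = b[0]
        g = _COHORT_THETA * b[0]
        joint_d[sites[-1]] = g * np.sqrt(s_disc * (1 - s_disc))
        joint_r[sites[-1]] = g * np.sqrt(s_rep * (1 - s_rep))
        return joint_p, joint_d, joint_r, 0.0, 0.0
    if kind == "weak":
        # real but sub-threshold pQTL signal: never reaches p < 5e-8
        joint_p[sites[0]] = 0.01
        return joint_p, joint_d, joint_r, 0.0, 0.0
    if kind == "h0":
        return joint_p, joint_d, joint_r, 0.0, 0.0
    raise ValueError(f"unknown cohort kind {kind!r}")


def simulate_cohort(
    plan=DEFAULT_COHORT_PLAN,
    seed: int = 0,
    n_pqtl: int = PQTL_N,
    n_discovery: int = DISCOVERY_N,
    s_discovery: float = DISCOVERY_CASE_PROP,
    n_replication: int = REPLICATION_N,
    s_replication: float = REPLICATION_CASE_PROP,
):
    """Generate a multi-protein screen with known tier assignments.

    Each protein occupies its own chromosome (one AR(1) region of
    ``121`` variants over 1 Mb, TSS at the region centre).  Returns a dict
    with per-protein pQTL datasets, pooled discovery/replication GWAS
    datasets, per-protein LD references, a gene annotation table, and the
    list of :class:`CohortTruth` records.
    """
    rng = np.random.default_rng(seed)
    r = ar1_corr(_COHORT_M, _COHORT_RHO)
    chol = _chol(r)

    pqtl_sets: dict[str, SummaryDataset] = {}
    ld_refs: dict[str, LDReference] = {}
    disc_frames, rep_frames, annot_rows, truths = [], [], [], []

    for i, kind in enumerate(plan):
        protein = f"PROT{i + 1:02d}"
        chrom = str(i + 1)
        joint_p, joint_d, joint_r, th_d, th_r = _cohort_joint_effects(
            kind, s_discovery, s_replication
        )
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        pqtl, disc, ld = _simulate_region_pair(
            prefix=protein, chromosome=chrom, m=_COHORT_M, rho=_COHORT_RHO,
            joint_pqtl=joint_p, joint_gwas_std=joint_d,
            n_pqtl=n_pqtl, n_gwas=n_discovery, case_proportion=s_discovery,
            rng=sub, protein_name=protein, gwas_name="discovery",
            chol=chol, r=r,
        )
        # replication GWAS: same variants/frequencies, independent cohort
        h = 2.0 * pqtl.records["eaf"].to_numpy() * (1 - pqtl.records["eaf"].to_numpy())
        z_rep = _marginal_z(r, chol, joint_r, n_replication, sub)
        se_rep = 1.0 / np.sqrt(h * n_replication * s_replication * (1 - s_replication))
        rep = disc.records.copy()
        rep["beta"] = z_rep * se_rep
        rep["se"] = se_rep
        from scipy import stats as _st

        rep["pvalue"] = np.maximum(2 * _st.norm.sf(np.abs(z_rep)), np.finfo(float).tiny)
        rep["n"] = n_replication
        rep["n_cases"] = int(round(n_replication * s_replication))

        pqtl_sets[protein] = pqtl
        ld_refs[protein] = ld
        disc_frames.append(disc.records)
        rep_frames.append(rep)
        tss = int(pqtl.records["position"].iloc[_COHORT_M // 2])
        annot_rows.append({"gene": protein, "chromosome": chrom, "tss": tss})
        truths.append(
            CohortTruth(protein, kind, _EXPECTED_TIER[kind], th_d, th_r)
        )

    discovery = SummaryDataset(
        "discovery", "case_control", pd.concat(disc_frames, ignore_index=True),
        case_proportion=s_discovery,
    )
    replication = SummaryDataset(
        "replication", "case_control", pd.concat(rep_frames, ignore_index=True),
        case_proportion=s_replication,
    )
    annotation = pd.DataFrame(annot_rows)
    return {
        "pqtl": pqtl_sets,
        "discovery": discovery,
        "replication": replication,
        "ld": ld_refs,
        "annotation": annotation,
        "truth": truths,
    }


def write_cohort(cohort: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as the delimited files the pipeline reads."""
    out = Path(out_dir)
    (out / "pqtl").mkdir(parents=True, exist_ok=True)
    (out / "ld").mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    for protein, ds in cohort["pqtl"].items():
        write_summary_stats(ds, out / "pqtl" / f"{protein}.tsv")
        write_ld_reference(
            cohort["ld"][protein],
            out / "ld" / f"{protein}.variants.txt",
            out / "ld" / f"{protein}.matrix.tsv",
        )
    write_summary_stats(cohort["discovery"], out / "discovery_gwas.tsv")
    write_summary_stats(cohort["replication"], out / "replication_gwas.tsv")
    cohort["annotation"].to_csv(out / "gene_annotation.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        [
            {
                "protein": t.protein,
                "kind": t.kind,
                "expected_tier": t.expected_tier,
                "theta_discovery": t.theta_discovery,
                "theta_replication": t.theta_replication,
            }
            for t in cohort["truth"]
        ]
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["root"] = out
    return paths
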