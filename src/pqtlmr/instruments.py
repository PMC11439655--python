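"""cis-pQTL instrument selection.

For each protein, genetic instruments are chosen from its pQTL summary
statistics in four ordered steps:

1. genome-wide significance screen (default p < 5e-8, recomputed from
   beta/se rather than the printed p-value);
2. cis classification — variants within 1 Mb of the transcription start
   site of the protein-coding gene are cis, everything else is trans and
   excluded (trans signals carry too much pleiotropy to be trusted as
   instruments);
3. greedy LD clumping (default r^2 <= 0.001 within 10,000 kb), keeping
   index variants in order of significance;
4. instrument-strength filter: F > 10, with
   R^2 = 2*MAF*(1-MAF)*(beta/sd)^2 and F = R^2/(1-R^2) * (n-k-1)/k.

Every excluded variant is logged with its reason, so the selection is a
partition of the input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDReference, SummaryDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "InstrumentSet",
    "compute_r2",
    "compute_f",
    "classify_cis",
    "clump",
    "select_instruments",
    "read_gene_annotation",
]

CIS_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene symbol with the chromosome and 1-based transcription start site."""

    gene: str
    chromosome: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError("tss must be >= 1")


@dataclass
class InstrumentSet:
    """Selected instruments for one protein plus the exclusion log.

    ``instruments`` carries the surviving variant rows with the appended
    metric columns ``maf``, ``r2``, ``f_stat`` and ``is_cis``;
    ``selection_log`` lists every excluded ``(variant_id, reason)``.
    """

    protein: str
    instruments: pd.DataFrame
    selection_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def f_set(self) -> float | None:
        """Set-level F statistic (k = number of retained instruments)."""
        if len(self.instruments) == 0:
            return None
        r2_total = min(float(self.instruments["r2"].sum()), 1.0 - 1e-12)
        n = int(self.instruments["n"].min())
        k = len(self.instruments)
        if n <= k + 1:
            return None
        return compute_f(r2_total, n, k)


def read_gene_annotation(path, sep: str = "\t") -> dict[str, GeneAnnotation]:
    """Read a gene/chromosome/tss table into a dict keyed by gene symbol."""
    df = pd.read_csv(path, sep=sep)
    return {
        str(r.gene): GeneAnnotation(str(r.gene), str(r.chromosome), int(r.tss))
        for r in df.itertuples(index=False)
    }


def compute_r2(maf: float, beta: float, sd: float = 1.0) -> float:
    """Variance in the trait explained by one variant.

    ``R^2 = 2 * MAF * (1 - MAF) * (beta/sd)^2`` with beta the per-allele
    effect and ``sd`` the trait standard deviation (1 when beta is already
    in SD units).  Values that reach 1 are clamped just below it, with a
    warning, so the downstream F statistic stays finite.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    r2 = 2.0 * maf * (1.0 - maf) * (beta / sd) ** 2
    cap = 1.0 - 1e-12
    if r2 >= 1.0:
        warnings.warn(f"R^2 = {r2:.4g} >= 1; clamped — check the effect-size scale")
        r2 = cap
    return min(r2, cap)


def compute_f(r2: float, n: int, k: int = 1) -> float:
    """Instrument-strength F statistic: ``(R^2/(1-R^2)) * ((n-k-1)/k)``."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    if n <= k + 1:
        raise ValueError("sample too small for F")
    return (r2 / (1.0 - r2)) * ((n - k - 1) / k)


def classify_cis(
    chromosome: str, position: int, gene: GeneAnnotation, window_bp: int = CIS_WINDOW_BP
) -> bool:
    """True iff the variant lies within ``window_bp`` (inclusive) of the gene TSS."""
    return str(chromosome) == str(gene.chromosome) and abs(position - gene.tss) <= window_bp


def _order_by_significance(df: pd.DataFrame) -> pd.DataFrame:
    """Most significant first: smallest p, ties by larger |z|, then id.

    |z| = |beta/se| breaks ties among p-values that saturate at the
    precision of the source file (or underflow when recomputed); the
    variant id breaks exact ties so clumping is reproducible regardless
    of input row order.
    """
    z = (df["beta"] / df["se"]).abs()
    return (
        df.assign(_absz=z)
        .sort_values(["pvalue", "_absz", "variant_id"], ascending=[True, False, True])
        .drop(columns="_absz")
    )


def clump(
    records: pd.DataFrame,
    ld: LDReference,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Greedy LD clumping of a per-variant table.

    Repeatedly take the most significant remaining variant as an index
    variant, then remove every remaining variant within ``window_kb``
    kilobases whose squared correlation with it exceeds ``r2_threshold``.
    Returns the surviving index variants (ordered by significance) and a
    log of exclusions.
    """
    log: list[tuple[str, str]] = []
    in_ld = records["variant_id"].map(lambda v: v in ld)
    for vid in records.loc[~in_ld, "variant_id"]:
        log.append((vid, "no-LD-info"))
    df = _order_by_significance(records.loc[in_ld])

    window_bp = window_kb * 1000
    kept_rows = []
    remaining = df.to_dict("records")
    while remaining:
        index = remaining.pop(0)
        kept_rows.append(index)
        survivors = []
        for cand in remaining:
            close = abs(cand["position"] - index["position"]) <= window_bp
            if close and ld.r(index["variant_id"], cand["variant_id"]) ** 2 > r2_threshold:
                log.append((cand["variant_id"], f"clumped-with-{index['variant_id']}"))
            else:
                survivors.append(cand)
        remaining = survivors
    kept = pd.DataFrame(kept_rows, columns=records.columns)
    return kept.reset_index(drop=True), log


def select_instruments(
    dataset: SummaryDataset,
    gene: GeneAnnotation,
    ld: LDReference,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    f_min: float = 10.0,
    cis_window_bp: int = CIS_WINDOW_BP,
) -> InstrumentSet:
    """Run the full instrument-selection cascade for one protein.

    The returned set may be empty; that outcome is valid and fully logged.
    Significance is judged on the two-sided normal p-value recomputed from
    beta/se; the per-variant F uses k = 1 (each variant judged alone),
    while :attr:`InstrumentSet.f_set` reports the set-level F.
    """
    if len(dataset) == 0:
        raise ValueError("select_instruments: empty dataset")
    df = dataset.records.copy()
    log: list[tuple[str, str]] = []

    z = (df["beta"] / df["se"]).abs()
    p = 2.0 * stats.norm.sf(z)
    df = df.assign(pvalue=p)  # printed p-values are rounded; recompute from beta/se
    sig = p < p_threshold
    log.extend((vid, "not-significant") for vid in df.loc[~sig, "variant_id"])
    df = df.loc[sig]

    if len(df):
        cis = df.apply(
            lambda r: classify_cis(r["chromosome"], r["position"], gene, cis_window_bp),
            axis=1,
        )
        log.extend((vid, "trans") for vid in df.loc[~cis, "variant_id"])
        df = df.loc[cis]

    if len(df):
        df, clump_log = clump(df, ld, r2_threshold, window_kb)
        log.extend(clump_log)

    if len(df):
        maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
        r2 = 2.0 * maf * (1.0 - maf) * (df["beta"] / 1.0) ** 2
        r2 = np.minimum(r2, 1.0 - 1e-12)
        f = np.array([compute_f(v, int(n), 1) for v, n in zip(r2, df["n"])])
        weak = f <= f_min
        log.extend((vid, "weak-instrument") for vid in df.loc[weak, "variant_id"])
        df = df.assign(maf=maf, r2=r2, f_stat=f, is_cis=True).loc[~weak]

    if len(df) == 0:
        logger.info("%s: no instruments", gene.gene)
        empty = pd.DataFrame(
            columns=list(dataset.records.columns) + ["maf", "r2", "f_stat", "is_cis"]
        )
        return InstrumentSet(gene.gene, empty, log)
    return InstrumentSet(gene.gene, df.reset_index(drop=True), log)
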