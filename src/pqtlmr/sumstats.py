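"""Summary-statistics containers, validated I/O, and allele harmonization.

GWAS and pQTL summary statistics arrive as delimited text with one row per
variant.  This module turns them into validated :class:`SummaryDataset`
objects (a thin wrapper over a :class:`pandas.DataFrame`), reads/writes LD
reference panels (variant list + dense correlation matrix), and harmonizes
an exposure/outcome pair of datasets onto a common effect allele so that
two-sample MR can combine per-variant effects.

Conventions
-----------
* Positions are 1-based; all genomic windows are inclusive on both ends.
* Effect sizes for case-control traits live on the log-odds scale; for
  quantitative (protein) traits on the standardized (SD-unit) scale.
* Source p-values are carried but never trusted for computation: every
  downstream test recomputes significance from ``beta/se``, because printed
  p-values in public summary files are rounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "SummaryDataset",
    "LDReference",
    "HarmonizedSet",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_reference",
    "write_ld_reference",
    "harmonize",
    "is_palindromic",
]

#: canonical column names for a per-variant summary-statistics table
REQUIRED_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

_VALID_ALLELE = frozenset("ACGT")

#: complement map used to recognise palindromic (strand-ambiguous) variants
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigurationError(ValueError):
    """A column map or run configuration does not match the input file."""


class EmptyInputError(ValueError):
    """No valid rows survive validation, or two datasets share no variants."""


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G variants, whose strand cannot be inferred."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class SummaryDataset:
    """One trait's marginal per-variant association statistics.

    Parameters
    ----------
    trait_name
        Label used in logs and error messages.
    trait_type
        ``"quantitative"`` (protein abundance, SD units) or
        ``"case_control"`` (log-odds scale).
    records
        DataFrame with the :data:`REQUIRED_COLUMNS` (``n_cases`` optional),
        unique by ``variant_id``.
    case_proportion
        Proportion of cases among ``n``; required iff case-control.
    """

    trait_name: str
    trait_type: str
    records: pd.DataFrame
    case_proportion: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if (self.trait_type == "case_control") != (self.case_proportion is not None):
            raise ValueError(
                "case_proportion must be supplied iff trait_type='case_control'"
            )
        if self.records["variant_id"].duplicated().any():
            dup = self.records["variant_id"][self.records["variant_id"].duplicated()]
            raise ValueError(f"duplicate variant_ids: {sorted(set(dup))[:5]}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> pd.Series:
        return self.records["variant_id"]

    def subset(self, variant_ids: Sequence[str]) -> "SummaryDataset":
        """Restrict to the given variants (kept in the dataset's own order)."""
        keep = self.records["variant_id"].isin(set(variant_ids))
        return SummaryDataset(
            self.trait_name,
            self.trait_type,
            self.records.loc[keep].reset_index(drop=True),
            self.case_proportion,
        )

    def region(self, chromosome: str, start: int, end: int) -> "SummaryDataset":
        """Variants on ``chromosome`` with ``start <= position <= end`` (inclusive)."""
        r = self.records
        keep = (r["chromosome"].astype(str) == str(chromosome)) & (
            r["position"] >= start
        ) & (r["position"] <= end)
        return SummaryDataset(
            self.trait_name, self.trait_type, r.loc[keep].reset_index(drop=True),
            self.case_proportion,
        )


@dataclass
class LDReference:
    """Pairwise allelic correlations (r, signed) for an ordered variant panel."""

    variant_ids: list[str]
    r_matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.r_matrix, dtype=float)
        k = len(self.variant_ids)
        if m.shape != (k, k):
            raise ValueError(f"r_matrix shape {m.shape} != ({k}, {k})")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        w = np.linalg.eigvalsh(m)
        if w.min() < -1e-8:
            raise ValueError(f"LD matrix not PSD (min eigenvalue {w.min():.3g})")
        self.r_matrix = m
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r(self, v1: str, v2: str) -> float:
        return float(self.r_matrix[self._index[v1], self._index[v2]])

    def submatrix(self, variant_ids: Sequence[str]) -> np.ndarray:
        idx = [self._index[v] for v in variant_ids]
        return self.r_matrix[np.ix_(idx, idx)]


@dataclass
class HarmonizedSet:
    """Exposure/outcome statistics aligned to a shared effect allele.

    ``pairs`` holds one row per retained variant with exposure columns
    (suffix ``_exp``) and outcome columns (suffix ``_out``); ``dropped``
    records every input variant excluded during harmonization together
    with the reason.
    """

    protein: str
    pairs: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def _validate_rows(df: pd.DataFrame, trait_name: str) -> tuple[pd.DataFrame, int]:
    """Drop rows violating field invariants; return (clean frame, n dropped)."""
    n0 = len(df)
    alle_ok = df["effect_allele"].str.upper().map(
        lambda a: set(a) <= _VALID_ALLELE and len(a) > 0
    ) & df["other_allele"].str.upper().map(lambda a: set(a) <= _VALID_ALLELE and len(a) > 0)
    ok = (
        (df["se"] > 0)
        & (df["eaf"] > 0)
        & (df["eaf"] < 1)
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & (df["n"] > 0)
        & alle_ok
        & (df["effect_allele"].str.upper() != df["other_allele"].str.upper())
        & df[["position", "eaf", "beta", "se", "pvalue", "n"]].notna().all(axis=1)
    )
    bad = df.loc[~ok]
    for vid in bad["variant_id"].head(20):
        logger.debug("%s: dropped invalid row %s", trait_name, vid)
    clean = df.loc[ok].copy()

    # consistency warning: printed p vs two-sided normal p from beta/se,
    # tolerant to a factor of 10 to absorb rounding in source files
    from scipy import stats

    z = (clean["beta"] / clean["se"]).abs()
    # compare in log space; ignore the comparison once both p-values are so
    # small that floating-point underflow dominates
    log_p_recomputed = (stats.norm.logsf(z) + np.log(2.0)) / np.log(10.0)
    with np.errstate(divide="ignore"):
        log_p_stated = np.log10(clean["pvalue"])
    comparable = (log_p_recomputed > -250) & (log_p_stated > -250)
    n_inconsistent = int(
        (comparable & (np.abs(log_p_recomputed - log_p_stated) > 1.0)).sum()
    )
    if n_inconsistent:
        logger.warning(
            "%s: %d rows have a stated p-value more than 10x away from the "
            "beta/se-implied p-value (kept; downstream tests recompute from beta/se)",
            trait_name,
            n_inconsistent,
        )
    return clean, n0 - len(clean)


def read_summary_stats(
    path: str | Path,
    trait_type: str,
    trait_name: str | None = None,
    dialect: Mapping[str, str] | None = None,
    case_proportion: float | None = None,
    sep: str = "\t",
) -> SummaryDataset:
    """Read and validate a delimited summary-statistics table.

    Parameters
    ----------
    path
        TSV/CSV file (gzip is handled transparently by pandas).
    dialect
        Mapping from canonical column name to the file's column name, e.g.
        ``{"variant_id": "SNP", "pvalue": "P"}``.  Unmapped canonical names
        are looked up verbatim.

    Rows violating per-variant invariants (non-positive SE, EAF outside
    (0,1), identical alleles, p outside (0,1]) are dropped and counted in
    the run log; a file yielding zero valid rows is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip parsing: written statistics must survive a write/read cycle
    # at full precision
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    dialect = dict(dialect or {})
    rename = {}
    wanted = list(REQUIRED_COLUMNS) + ["n_cases"]
    for canon in wanted:
        src = dialect.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon != "n_cases":
            raise ConfigurationError(
                f"{path}: required column {canon!r} (mapped to {src!r}) not found"
            )
    df = raw.rename(columns=rename)[[c for c in wanted if c in rename.values()]]
    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    clean, n_dropped = _validate_rows(df, trait_name or path.stem)
    if n_dropped:
        logger.info("%s: dropped %d invalid rows", path, n_dropped)
    if clean.empty:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    clean = clean.drop_duplicates(subset="variant_id", keep="first")
    ds = SummaryDataset(
        trait_name=trait_name or path.stem,
        trait_type=trait_type,
        records=clean.reset_index(drop=True),
        case_proportion=case_proportion,
    )
    ds.n_dropped_on_read = n_dropped  # type: ignore[attr-defined]
    return ds


def write_summary_stats(dataset: SummaryDataset, path: str | Path, sep: str = "\t") -> None:
    """Write a dataset as delimited text; numeric fields round-trip exactly."""
    dataset.records.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_ld_reference(
    variants_path: str | Path, matrix_path: str | Path, sep: str = "\t"
) -> LDReference:
    """Read an LD panel: one variant id per line plus a dense r matrix."""
    ids = [ln.strip() for ln in Path(variants_path).read_text().splitlines() if ln.strip()]
    mat = np.loadtxt(matrix_path, delimiter=sep, ndmin=2)
    return LDReference(ids, mat)


def write_ld_reference(
    ld: LDReference, variants_path: str | Path, matrix_path: str | Path, sep: str = "\t"
) -> None:
    Path(variants_path).write_text("\n".join(ld.variant_ids) + "\n")
    np.savetxt(matrix_path, ld.r_matrix, delimiter=sep, fmt="%.17g")


def _align_outcome_row(exp_row, out_row):
    """Return (aligned outcome beta, eaf, status) for one exposure/outcome pair.

    status is 'same', 'swapped' or 'mismatch'.
    """
    ea_e, oa_e = exp_row.effect_allele, exp_row.other_allele
    ea_o, oa_o = out_row.effect_allele, out_row.other_allele
    if (ea_e, oa_e) == (ea_o, oa_o):
        return out_row.beta, out_row.eaf, "same"
    if (ea_e, oa_e) == (oa_o, ea_o):
        return -out_row.beta, 1.0 - out_row.eaf, "swapped"
    # strand flip: compare against the complemented outcome alleles
    cea, coa = _COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?")
    if (ea_e, oa_e) == (cea, coa):
        return out_row.beta, out_row.eaf, "same"
    if (ea_e, oa_e) == (coa, cea):
        return -out_row.beta, 1.0 - out_row.eaf, "swapped"
    return np.nan, np.nan, "mismatch"


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_eaf_margin: float = 0.08,
    protein: str | None = None,
) -> HarmonizedSet:
    """Align outcome statistics to the exposure's effect allele, per variant.

    Matching is by ``variant_id``.  Outcome rows whose alleles are swapped
    relative to the exposure have their beta negated and eaf replaced by
    ``1 - eaf``.  Palindromic variants (A/T, C/G) are inherently
    strand-ambiguous: they are kept only when both effect-allele
    frequencies fall on the same side of 0.5 and both are at least
    ``palindrome_eaf_margin`` away from 0.5 — otherwise they are dropped
    with reason ``"palindromic-ambiguous"``.  Irreconcilable allele sets
    are dropped with reason ``"allele-mismatch"``.

    Every exposure variant appears exactly once: in ``pairs`` or ``dropped``.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise EmptyInputError("harmonize: empty input dataset")
    out_by_id = {r.variant_id: r for r in outcome.records.itertuples(index=False)}
    dropped: list[tuple[str, str]] = []
    rows = []
    for e in exposure.records.itertuples(index=False):
        o = out_by_id.get(e.variant_id)
        if o is None:
            dropped.append((e.variant_id, "missing-in-outcome"))
            continue
        if e.effect_allele == e.other_allele:
            dropped.append((e.variant_id, "degenerate alleles"))
            continue
        beta_o, eaf_o, status = _align_outcome_row(e, o)
        if status == "mismatch":
            dropped.append((e.variant_id, "allele-mismatch"))
            continue
        if is_palindromic(e.effect_allele, e.other_allele):
            same_side = (e.eaf - 0.5) * (eaf_o - 0.5) > 0
            clear = (
                abs(e.eaf - 0.5) >= palindrome_eaf_margin
                and abs(eaf_o - 0.5) >= palindrome_eaf_margin
            )
            if not (same_side and clear):
                dropped.append((e.variant_id, "palindromic-ambiguous"))
                continue
        rows.append(
            {
                "variant_id": e.variant_id,
                "chromosome": e.chromosome,
                "position": e.position,
                "effect_allele": e.effect_allele,
                "other_allele": e.other_allele,
                "eaf_exp": e.eaf,
                "beta_exp": e.beta,
                "se_exp": e.se,
                "pvalue_exp": e.pvalue,
                "n_exp": e.n,
                "eaf_out": eaf_o,
                "beta_out": beta_o,
                "se_out": o.se,
                "pvalue_out": o.pvalue,
                "n_out": o.n,
            }
        )
    if not rows:
        raise EmptyInputError(
            f"harmonize: no shared variants between {exposure.trait_name!r} "
            f"and {outcome.trait_name!r}"
        )
    pairs = pd.DataFrame(rows)
    return HarmonizedSet(protein or exposure.trait_name, pairs, dropped)
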