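"""End-to-end orchestration of the drug-target screen.

Stage order: instrument selection -> SMR + FDR -> colocalization ->
discovery MR -> replication MR -> sensitivity battery -> evidence tiers.
Each stage writes its table to the run directory before the next stage
starts, and a manifest records the configuration hash, seeds and per-stage
row counts; re-running with an unchanged configuration skips stages whose
outputs already exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import instruments as inst_mod
from . import mr as mr_mod
from . import presso as presso_mod
from . import smr as smr_mod
from . import tiering as tier_mod
from .sumstats import (
    EmptyInputError,
    SummaryDataset,
    harmonize,
    read_ld_reference,
    read_summary_stats,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGES = ("select", "smr", "coloc", "mr_discovery", "mr_replication", "sensitivity", "tier")


@dataclass
class RunConfig:
    """All inputs and thresholds for one screen."""

    pqtl_dir: str
    discovery_path: str
    replication_path: str
    ld_dir: str
    annotation_path: str
    out_dir: str
    discovery_case_proportion: float
    replication_case_proportion: float

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    cis_window_bp: int = 1_000_000
    fdr_threshold: float = 0.05
    coloc_window_bp: int = 500_000
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pph4_threshold: float = 0.80
    mr_alpha: float = 0.05
    palindrome_eaf_margin: float = 0.08
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


class PipelineState:
    """In-memory stage products for one run (also mirrored to disk)."""

    def __init__(self) -> None:
        self.instrument_sets: dict[str, inst_mod.InstrumentSet] = {}
        self.harmonized_disc: dict = {}
        self.harmonized_rep: dict = {}
        self.smr_results: list = []
        self.smr_table: pd.DataFrame | None = None
        self.coloc_results: dict = {}
        self.mr_disc: dict = {}
        self.mr_rep: dict = {}
        self.sensitivity: dict = {}
        self.tiers: pd.DataFrame | None = None


def _load_inputs(cfg: RunConfig):
    pqtl_dir = Path(cfg.pqtl_dir)
    annotation = inst_mod.read_gene_annotation(cfg.annotation_path)
    pqtl: dict[str, SummaryDataset] = {}
    for path in sorted(pqtl_dir.glob("*.tsv")):
        protein = path.stem
        pqtl[protein] = read_summary_stats(path, "quantitative", trait_name=protein)
    discovery = read_summary_stats(
        cfg.discovery_path, "case_control", trait_name="discovery",
        case_proportion=cfg.discovery_case_proportion,
    )
    replication = read_summary_stats(
        cfg.replication_path, "case_control", trait_name="replication",
        case_proportion=cfg.replication_case_proportion,
    )
    ld_dir = Path(cfg.ld_dir)
    ld = {
        p: read_ld_reference(ld_dir / f"{p}.variants.txt", ld_dir / f"{p}.matrix.tsv")
        for p in pqtl
        if (ld_dir / f"{p}.variants.txt").exists()
    }
    return pqtl, discovery, replication, ld, annotation


def run_pipeline(cfg: RunConfig, resume: bool = True) -> Path:
    """Execute all stages; returns the run directory.

    Proteins are processed in sorted name order so outputs are byte-stable
    regardless of input file enumeration.  A stage failure aborts the run
    with the stage and protein named in the raised error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest = old

    pqtl, discovery, replication, ld, annotation = _load_inputs(cfg)
    proteins = sorted(pqtl)
    state = PipelineState()

    def done(stage: str) -> bool:
        return resume and stage in manifest["stages"] and (out / f"{stage}.tsv").exists()

    def record(stage: str, n_rows: int) -> None:
        manifest["stages"][stage] = {"rows": n_rows}
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # ---- stage: instrument selection -------------------------------------
    inst_rows, log_rows = [], []
    for protein in proteins:
        if protein not in annotation:
            raise RuntimeError(f"stage=select protein={protein}: no gene annotation")
        try:
            iset = inst_mod.select_instruments(
                pqtl[protein], annotation[protein], ld[protein],
                p_threshold=cfg.p_threshold, r2_threshold=cfg.clump_r2,
                window_kb=cfg.clump_window_kb, f_min=cfg.f_min,
                cis_window_bp=cfg.cis_window_bp,
            )
        except Exception as exc:  # noqa: BLE001 — annotate and re-raise
            raise RuntimeError(f"stage=select protein={protein}: {exc}") from exc
        state.instrument_sets[protein] = iset
        if len(iset):
            inst_rows.append(iset.instruments.assign(protein=protein))
        log_rows.extend(
            {"protein": protein, "variant_id": v, "reason": r}
            for v, r in iset.selection_log
        )
    inst_table = (
        pd.concat(inst_rows, ignore_index=True) if inst_rows else pd.DataFrame()
    )
    if not done("select"):
        _write(inst_table, out / "select.tsv")
        _write(pd.DataFrame(log_rows), out / "select_log.tsv")
        record("select", len(inst_table))

    # harmonize instruments against both outcomes (needed by most stages)
    for protein in proteins:
        iset = state.instrument_sets[protein]
        if len(iset) == 0:
            continue
        exp = pqtl[protein].subset(iset.instruments["variant_id"])
        try:
            state.harmonized_disc[protein] = harmonize(
                exp, discovery, cfg.palindrome_eaf_margin, protein=protein
            )
            state.harmonized_rep[protein] = harmonize(
                exp, replication, cfg.palindrome_eaf_margin, protein=protein
            )
        except EmptyInputError:
            logger.warning("%s: instruments absent from an outcome GWAS", protein)

    # ---- stage: SMR + FDR -------------------------------------------------
    for protein in proteins:
        hs = state.harmonized_disc.get(protein)
        if hs is None:
            continue
        res = smr_mod.smr_for_protein(hs, state.instrument_sets[protein])
        if res is not None:
            state.smr_results.append(res)
    state.smr_table = smr_mod.smr_table(state.smr_results)
    if not done("smr"):
        _write(state.smr_table, out / "smr.tsv")
        record("smr", len(state.smr_table))

    # ---- stage: colocalization --------------------------------------------
    priors = coloc_mod.ColocPriors(cfg.coloc_p1, cfg.coloc_p2, cfg.coloc_p12)
    coloc_rows = []
    for protein in proteins:
        if len(state.instrument_sets[protein]) == 0:
            continue
        gene = annotation[protein]
        lo, hi = gene.tss - cfg.coloc_window_bp, gene.tss + cfg.coloc_window_bp
        region_p = pqtl[protein].region(gene.chromosome, lo, hi)
        region_g = discovery.region(gene.chromosome, lo, hi)
        if len(region_p) == 0 or len(region_g) == 0:
            continue
        try:
            res = coloc_mod.coloc_abf(region_p, region_g, priors, protein=protein)
        except EmptyInputError:
            continue
        res.window_bp = cfg.coloc_window_bp
        state.coloc_results[protein] = res
        coloc_rows.append({"protein": protein, "n_snps": res.n_snps, **res.pp})
    if not done("coloc"):
        _write(pd.DataFrame(coloc_rows), out / "coloc.tsv")
        record("coloc", len(coloc_rows))

    # ---- stages: discovery / replication MR -------------------------------
    for stage, store, harm in (
        ("mr_discovery", state.mr_disc, state.harmonized_disc),
        ("mr_replication", state.mr_rep, state.harmonized_rep),
    ):
        rows = []
        for protein in proteins:
            hs = harm.get(protein)
            if hs is None or len(hs) == 0:
                continue
            battery = mr_mod.mr_battery(
                hs, protein=protein, n_boot=cfg.n_boot, seed=cfg.seed
            )
            store[protein] = battery
            for key in ("ivw", "egger", "weighted_median"):
                r = battery.get(key)
                if r is None:
                    continue
                het = battery.get("heterogeneity")
                rows.append(
                    {
                        "protein": protein,
                        "method": r.method,
                        "n_snp": r.n_snp,
                        "beta": r.beta,
                        "se": r.se,
                        "pvalue": r.pvalue,
                        "or_point": r.or_point,
                        "or_ci_low": r.or_ci_low,
                        "or_ci_high": r.or_ci_high,
                        "q_stat": het.q_stat if key == "ivw" else np.nan,
                        "q_pvalue": het.q_pvalue if key == "ivw" else np.nan,
                        "egger_intercept": r.egger_intercept if key == "egger" else np.nan,
                        "egger_intercept_p": r.egger_intercept_p if key == "egger" else np.nan,
                    }
                )
        if not done(stage):
            _write(pd.DataFrame(rows), out / f"{stage}.tsv")
            record(stage, len(rows))

    # ---- stage: sensitivity (PRESSO + leave-one-out flags) -----------------
    sens_rows = []
    for protein in proteins:
        battery = state.mr_disc.get(protein)
        if battery is None:
            continue
        est = battery["estimates"]
        row = {"protein": protein, "n_snp": len(est)}
        if len(est) >= 4:
            rep = presso_mod.presso(
                est, n_sim=cfg.presso_n_sim, seed=cfg.seed
            )
            state.sensitivity[protein] = rep
            row.update(
                presso_global_rss=rep.global_rss,
                presso_global_p=rep.global_p,
                presso_outliers=";".join(rep.outliers),
                presso_beta_raw=rep.beta_raw,
                presso_beta_corrected=rep.beta_outlier_corrected,
                presso_distortion_p=rep.distortion_p,
            )
        loo = battery.get("loo")
        row["loo_any_flagged"] = bool(loo["flagged"].any()) if loo is not None else False
        sens_rows.append(row)
    if not done("sensitivity"):
        _write(pd.DataFrame(sens_rows), out / "sensitivity.tsv")
        record("sensitivity", len(sens_rows))

    # ---- stage: evidence tiers ---------------------------------------------
    smr_by_protein = {r.protein: r for r in state.smr_results}
    flags = []
    for protein in proteins:
        smr_res = smr_by_protein.get(protein)
        coloc_res = state.coloc_results.get(protein)
        disc = state.mr_disc.get(protein, {}).get("ivw")
        rep = state.mr_rep.get(protein, {}).get("ivw")
        direction_ok = True
        if smr_res is not None and disc is not None:
            direction_ok = np.sign(smr_res.beta_smr) == np.sign(disc.beta)
        flags.append(
            tier_mod.StageFlags(
                protein=protein,
                smr_pass=bool(smr_res is not None and smr_res.p_fdr < cfg.fdr_threshold),
                coloc_pass=bool(coloc_res is not None and coloc_res.pp_h4 > cfg.pph4_threshold),
                discovery_pass=bool(disc is not None and disc.pvalue < cfg.mr_alpha),
                replication_pass=bool(rep is not None and rep.pvalue < cfg.mr_alpha),
                directions_consistent=bool(direction_ok),
            )
        )
    state.tiers = tier_mod.tier_report(flags)
    if not done("tier"):
        _write(state.tiers, out / "tier.tsv")
        record("tier", len(state.tiers))

    run_pipeline.last_state = state  # convenience for library callers
    return out
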