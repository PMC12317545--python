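"""End-to-end orchestration: simulate or load inputs, then run the
phenotype, tolerance, clustering and association stages with one config.

Every run writes its tables as TSV into an output directory together with
a run report (stage record counts, warnings, parameter echo, seed) so a
run is reproducible from the report alone.  Identical (config, seed) give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import apply_bonferroni, candidate_genes, glm_scan, impute_mean, marker_qc, pca_covariates
from .cluster_profiles import DEFAULT_CLUSTER_TRAITS, cluster_genotypes, cluster_means, genotype_performance_classes, standardize
from .containers import GeneAnnotationSet, GenotypeMatrix, PhenotypeTable, ValidationError
from .io_formats import (
    read_genotypes_dosage,
    read_genotypes_vcf,
    read_gff3,
    read_phenotype_table,
    write_genotypes_dosage,
    write_genotypes_vcf,
    write_phenotype_table,
    write_table,
)
from .phenostats import change_metrics, derive_traits, genotype_means, summary_table
from .simulate import GenoSimConfig, PhenoSimConfig, simulate_genotypes, simulate_phenotypes
from .tolerance import DEFAULT_MFVP_TRAITS, compute_mfvp, compute_sti, rank_select

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs (paths or simulation configs), stage switches and thresholds."""

    # inputs: either file paths ...
    phenotype_csv: str | None = None
    vcf: str | None = None
    dosage_csv: str | None = None
    markers_csv: str | None = None
    gff3: str | None = None
    # ... or simulation configs
    pheno_sim: PhenoSimConfig | None = None
    geno_sim: GenoSimConfig | None = None

    # stage switches
    run_phenostats: bool = True
    run_tolerance: bool = True
    run_clustering: bool = True
    run_gwas: bool = True

    # analysis parameters
    mfvp_traits: tuple[str, ...] = DEFAULT_MFVP_TRAITS
    cluster_traits: tuple[str, ...] = DEFAULT_CLUSTER_TRAITS
    gwas_traits: tuple[str, ...] = ("SDW", "Pupt", "PUE")
    call_rate_min: float = 0.85
    maf_min: float = 0.05
    alpha: float = 0.05
    n_pc: int = 3
    window_bp: int = 1_000_000
    k_main: int = 2
    k_sub: int = 9
    top_k: int = 20
    linkage: str = "complete"
    seed: int = 0
    out_dir: str = "results/run"

    def validate(self) -> None:
        if self.run_phenostats or self.run_tolerance or self.run_clustering:
            if self.phenotype_csv is None and self.pheno_sim is None:
                raise ValidationError("phenotype stages enabled but no phenotype input or simulation config")
        if self.run_gwas:
            has_files = self.vcf is not None or (self.dosage_csv is not None and self.markers_csv is not None)
            if not has_files and self.geno_sim is None:
                raise ValidationError("GWAS stage enabled but no genotype input or simulation config")
        for name, v, lo, hi in [
            ("call_rate_min", self.call_rate_min, 0, 1),
            ("maf_min", self.maf_min, 0, 0.5),
            ("alpha", self.alpha, 0, 1),
        ]:
            if not lo <= v <= hi:
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k_main > self.k_sub:
            raise ValidationError("k_main must be <= k_sub")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping (flat keys; the
    ``pheno_sim``/``geno_sim`` sub-mappings hold simulation settings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "pheno_sim" in raw and isinstance(raw["pheno_sim"], dict):
        raw["pheno_sim"] = PhenoSimConfig(**raw["pheno_sim"])
    if "geno_sim" in raw and isinstance(raw["geno_sim"], dict):
        raw["geno_sim"] = GenoSimConfig(**raw["geno_sim"])
    return PipelineConfig(**raw)


@dataclass
class RunReport:
    seed: int
    version: str
    parameters: dict
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        if stage in self.stages:
            raise ValidationError(f"stage {stage!r} recorded twice")
        self.stages[stage] = counts

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": self.seed,
            "version": self.version,
            "parameters": self.parameters,
            "stages": self.stages,
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _echo_parameters(cfg: PipelineConfig) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
    return out


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order and write all outputs.

    Order: derive -> means -> descriptives/ANOVA/H2 -> STI/MFVP ->
    clustering -> QC/scan/PVE/candidate genes.  Fail-fast validation runs
    before any computation.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed, version=__version__, parameters=_echo_parameters(cfg))

    genotypes: GenotypeMatrix | None = None
    if cfg.vcf:
        genotypes = read_genotypes_vcf(cfg.vcf)
    elif cfg.dosage_csv and cfg.markers_csv:
        genotypes = read_genotypes_dosage(cfg.dosage_csv, cfg.markers_csv)
    elif cfg.geno_sim is not None:
        geno_cfg = dataclasses.replace(cfg.geno_sim, seed=cfg.seed)
        genotypes, _ = simulate_genotypes(geno_cfg)
        report.record("simulate_genotypes", n_samples=genotypes.n_samples, n_markers=genotypes.n_markers)

    table: PhenotypeTable | None = None
    if cfg.phenotype_csv:
        table = read_phenotype_table(cfg.phenotype_csv)
    elif cfg.pheno_sim is not None:
        pheno_cfg = dataclasses.replace(cfg.pheno_sim, seed=cfg.seed)
        table, truth = simulate_phenotypes(pheno_cfg, genotypes=genotypes)
        report.record("simulate_phenotypes", n_records=len(table), n_truncated=truth.n_truncated)
        if truth.n_truncated:
            report.warnings.append(f"{truth.n_truncated} negative draws truncated at 0")

    means = None
    if table is not None:
        table = derive_traits(table)
        write_phenotype_table(table, out_dir / "phenotypes_derived.csv")
        means = genotype_means(table)
        report.record("derive_and_means", n_records=len(table), n_means=len(means))

    if cfg.run_phenostats:
        if table is None:
            raise ValidationError("phenostats stage needs phenotypes")
        summary = summary_table(table)
        write_table(summary, out_dir / "trait_summary.tsv")
        changes = []
        for trait in summary["trait"]:
            try:
                ch = change_metrics(means, trait)
            except ValidationError:
                continue
            changes.append(
                {
                    "trait": trait,
                    "mean_pct_reduction": ch.mean_pct_reduction,
                    "pct_reduction_of_means": ch.pct_reduction_of_means,
                    "n_increased_under_lp": ch.n_increased_under_lp,
                }
            )
        write_table(pd.DataFrame(changes), out_dir / "change_metrics.tsv")
        report.record("phenostats", n_traits=len(summary))

    if cfg.run_tolerance:
        if means is None:
            raise ValidationError("tolerance stage needs phenotypes")
        sti_tables = {t: compute_sti(means, t) for t in cfg.mfvp_traits}
        mfvp = compute_mfvp(sti_tables, list(cfg.mfvp_traits))
        top, bottom = rank_select(mfvp, min(cfg.top_k, len(mfvp.data)))
        sti_wide = mfvp.data.copy()
        for t, st in sti_tables.items():
            sti_wide[f"STI_{t}"] = sti_wide["genotype_id"].map(
                st.data.set_index("genotype_id")["sti"]
            )
        write_table(sti_wide.round(4), out_dir / "tolerance_scores.tsv")
        write_table(top.round(4), out_dir / "tolerance_top.tsv")
        write_table(bottom.round(4), out_dir / "tolerance_bottom.tsv")
        report.record("tolerance", n_scored=len(mfvp.data), n_traits=len(mfvp.traits))

    if cfg.run_clustering:
        if means is None:
            raise ValidationError("clustering stage needs phenotypes")
        z = standardize(means, traits=cfg.cluster_traits)
        assignment = cluster_genotypes(z, linkage=cfg.linkage, k_main=cfg.k_main, k_sub=min(cfg.k_sub, len(z.data)))
        cm = cluster_means(assignment, means, traits=cfg.cluster_traits)
        write_table(genotype_performance_classes(assignment, cm), out_dir / "cluster_assignments.tsv")
        write_table(cm.table.round(4), out_dir / "cluster_means.tsv")
        report.record("clustering", n_genotypes=len(assignment.data), k_sub=assignment.k_sub)

    if cfg.run_gwas:
        if genotypes is None or means is None:
            raise ValidationError("GWAS stage needs genotypes and phenotypes")
        filtered, qc = marker_qc(genotypes, cfg.call_rate_min, cfg.maf_min)
        imputed = impute_mean(filtered)
        scores, evr = pca_covariates(imputed, n_pc=cfg.n_pc)
        write_table(
            pd.DataFrame(
                {
                    "component": np.arange(1, cfg.n_pc + 1),
                    "explained_variance_fraction": evr,
                }
            ),
            out_dir / "pca_variance.tsv",
        )
        scan_frames = []
        for trait in cfg.gwas_traits:
            for treat in ("HP", "LP"):
                sub = means.loc[(means["trait"] == trait) & (means["treatment"] == treat)]
                y = sub.set_index("genotype_id")["mean"].reindex(imputed.sample_ids)
                if y.notna().sum() < cfg.n_pc + 3:
                    continue
                rec = glm_scan(imputed, y, covariates=scores, trait=f"{trait}_{treat}")
                # Bonferroni over the markers tested within each scan
                rec, rule = apply_bonferroni(rec, alpha=cfg.alpha)
                scan_frames.append(rec)
        records = pd.concat(scan_frames, ignore_index=True)
        write_table(records, out_dir / "associations.tsv")
        write_table(
            pd.DataFrame([dataclasses.asdict(qc)]), out_dir / "qc_report.tsv"
        )
        hits = records.loc[records["significant"]]
        if cfg.gff3:
            genes = read_gff3(cfg.gff3)
            frames = [candidate_genes(row, genes, cfg.window_bp) for _, row in hits.iterrows()]
            cand = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=["marker_id", "gene_id", "chrom", "start", "end", "distance", "description"])
            )
            write_table(cand, out_dir / "candidate_genes.tsv")
        report.record(
            "gwas",
            markers_tested=qc.markers_out,
            n_significant=int(records["significant"].sum()),
            threshold_neglog10p=rule.threshold_neglog10p,
        )

    report.to_json(out_dir / "run_report.json")
    return report


def make_fixture(kind: str, seed: int, out_dir: str | os.PathLike,
                 pheno_cfg: PhenoSimConfig | None = None,
                 geno_cfg: GenoSimConfig | None = None) -> dict[str, str]:
    """Write ready-to-read fixture files (plus ground truth) for tests.

    kind: "phenotypes" (CSV), "genotypes" (VCF + dosage/marker CSV), or
    "panel" (both, sharing sample ids).  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if kind not in {"phenotypes", "genotypes", "panel"}:
        raise ValidationError(f"unknown fixture kind {kind!r}")

    genotypes = None
    if kind in {"genotypes", "panel"}:
        gcfg = dataclasses.replace(geno_cfg or GenoSimConfig(n_samples=20, n_markers=120), seed=seed)
        genotypes, _ = simulate_genotypes(gcfg)
        paths["vcf"] = str(out / "genotypes.vcf")
        paths["dosage_csv"] = str(out / "dosage.csv")
        paths["markers_csv"] = str(out / "markers.csv")
        write_genotypes_vcf(genotypes, paths["vcf"])
        write_genotypes_dosage(genotypes, paths["dosage_csv"], paths["markers_csv"])
    if kind in {"phenotypes", "panel"}:
        n = genotypes.n_samples if genotypes is not None else 20
        pcfg = dataclasses.replace(pheno_cfg or PhenoSimConfig(n_genotypes=n), seed=seed, n_genotypes=n)
        table, truth = simulate_phenotypes(pcfg, genotypes=genotypes)
        paths["phenotype_csv"] = str(out / "phenotypes.csv")
        write_phenotype_table(table, paths["phenotype_csv"])
        paths["truth_json"] = str(out / "truth.json")
        truth_payload = {
            "seed": truth.seed,
            "true_h2": truth.true_h2,
            "n_truncated": truth.n_truncated,
            "planted": truth.planted.to_dict("records") if truth.planted is not None else [],
        }
        with open(paths["truth_json"], "w") as fh:
            json.dump(truth_payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return paths
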