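"""Readers and writers for the external formats the pipeline touches.

Phenotypes travel as CSV (long format, or wide-by-trait via a dialect
config), genotypes as VCF (GT field, biallelic records) or as a dosage CSV
paired with a marker-map CSV, gene annotation as GFF3, and all result
tables as TSV.  Coordinates are 1-based inclusive everywhere.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    GENE_COLUMNS,
    MARKER_COLUMNS,
    PHENOTYPE_COLUMNS,
    TRAIT_UNITS,
    GeneAnnotationSet,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeDialect:
    """How a phenotype CSV maps onto the internal long schema.

    ``layout`` is "long" (columns genotype_id/treatment/replicate/trait/value)
    or "wide" (one column per trait).  ``column_map`` renames file columns to
    the internal names; ``trait_map`` renames file trait codes to the
    canonical ones.
    """

    layout: str = "long"
    column_map: dict[str, str] | None = None
    trait_map: dict[str, str] | None = None


def read_phenotype_table(path: str | os.PathLike, dialect: PhenotypeDialect | None = None) -> PhenotypeTable:
    """Read and validate a phenotype CSV.

    Raises :class:`ValidationError` (with row context) for unknown treatment
    labels, duplicate keys, or negative values of non-negative traits.
    """
    dialect = dialect or PhenotypeDialect()
    df = pd.read_csv(path)
    if dialect.column_map:
        df = df.rename(columns=dialect.column_map)
    if dialect.layout == "wide":
        id_cols = ["genotype_id", "treatment", "replicate"]
        missing = [c for c in id_cols if c not in df.columns]
        if missing:
            raise ValidationError(f"wide phenotype CSV lacks id columns {missing}")
        df = df.melt(id_vars=id_cols, var_name="trait", value_name="value")
    elif dialect.layout != "long":
        raise ValidationError(f"unknown phenotype layout {dialect.layout!r}")
    if dialect.trait_map:
        df["trait"] = df["trait"].replace(dialect.trait_map)
    unknown = sorted(set(df["trait"].unique()) - set(TRAIT_UNITS))
    if unknown:
        logger.warning("phenotype CSV contains %d unrecognized trait code(s): %s", len(unknown), unknown)
    return PhenotypeTable(df)


def write_phenotype_table(table: PhenotypeTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, index=False, columns=PHENOTYPE_COLUMNS)


def read_genotypes_vcf(path: str | os.PathLike, ploidy: int = 2) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    GT is decoded as the count of alternate alleles; "./." becomes NaN.
    Multiallelic records are skipped with a logged count.
    """
    vcf = VCF(str(path), gts012=True)
    if "GT" not in {f["ID"] for f in vcf.header_iter() if f["HeaderType"] == "FORMAT"}:
        raise ValidationError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    markers: list[tuple] = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt-allele count, 3 = missing
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        marker_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append((marker_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_skipped:
        logger.info("read_genotypes_vcf: skipped %d multiallelic record(s)", n_skipped)
    if not markers:
        raise ValidationError(f"{path}: no biallelic SNP records")
    marker_df = pd.DataFrame(markers, columns=MARKER_COLUMNS)
    dosage = np.vstack(rows).T  # records x samples -> samples x markers
    return GenotypeMatrix(sample_ids=samples, markers=marker_df, dosage=dosage, ploidy=ploidy)


def write_genotypes_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a diploid GenotypeMatrix as a minimal VCF 4.2 with GT calls."""
    if g.ploidy != 2:
        raise ValidationError("VCF writer only supports diploid dosages")
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in g.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids) + "\n")
        for j, m in g.markers.iterrows():
            calls = [
                "./." if not np.isfinite(d) else code[int(round(d))]
                for d in g.dosage[:, j]
            ]
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.marker_id}\t{m.ref}\t{m.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_genotypes_dosage(dosage_path: str | os.PathLike, markers_path: str | os.PathLike, ploidy: int = 2) -> GenotypeMatrix:
    """Read a samples x markers dosage CSV plus its marker-map CSV."""
    dm = pd.read_csv(dosage_path, index_col=0)
    marker_df = pd.read_csv(markers_path)
    if list(dm.columns) != list(marker_df["marker_id"].astype(str)):
        raise ValidationError("dosage CSV columns do not match the marker map order")
    return GenotypeMatrix(
        sample_ids=list(dm.index.astype(str)),
        markers=marker_df,
        dosage=dm.to_numpy(dtype=float),
        ploidy=ploidy,
    )


def write_genotypes_dosage(g: GenotypeMatrix, dosage_path: str | os.PathLike, markers_path: str | os.PathLike) -> None:
    pd.DataFrame(
        g.dosage, index=pd.Index(g.sample_ids, name="sample_id"), columns=g.markers["marker_id"]
    ).to_csv(dosage_path)
    g.markers.to_csv(markers_path, index=False, columns=MARKER_COLUMNS)


def read_gff3(path: str | os.PathLike, feature_type: str = "gene") -> GeneAnnotationSet:
    """Read features of one type from a GFF3 into a gene annotation table.

    Coordinates stay 1-based inclusive.  A light pre-scan reports malformed
    (non-9-column) lines with their line number before parsing.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise ValidationError(f"{path}: malformed GFF3 line {lineno} (expected 9 tab-separated fields)")
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    records = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        desc = feat.attributes.get("description", [""])[0] or feat.attributes.get("Name", [""])[0]
        records.append((gene_id, feat.seqid, feat.start, feat.end, desc))
    return GeneAnnotationSet(pd.DataFrame(records, columns=GENE_COLUMNS))


def write_table(df: pd.DataFrame, path: str | os.PathLike, float_format: str = "%.6g") -> None:
    """Write a result table as TSV (the output dialect for all stages)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
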