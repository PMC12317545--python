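"""Core in-memory containers shared by all pipeline stages.

The pipeline operates on three kinds of data: long-format phenotype records
(genotype x treatment x replicate x trait), an allele-dosage matrix with a
marker map, and a gene annotation table.  Each container validates its
invariants on construction so downstream stages can assume well-formed input.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fertilization treatments: high phosphorus (control) and low phosphorus (stress).
TREATMENTS = ("HP", "LP")

#: Measured and derived trait codes with units.
TRAIT_UNITS = {
    "SFW": "g",             # shoot fresh weight
    "RFW": "g",             # root fresh weight
    "SDW": "g",             # shoot dry weight
    "RDW": "g",             # root dry weight
    "TFW": "g",             # tuber fresh weight
    "TDW": "g",             # tuber dry weight
    "TotalFW": "g",         # total fresh biomass
    "TotalDW": "g",         # total dry biomass
    "PH1": "cm",            # plant height 7 d after planting
    "PH2": "cm",            # plant height 30 d after planting
    "RL": "cm",             # longest-root length
    "P_conc": "mg (100 g)^-1",  # shoot P concentration
    "Pupt": "mg plant^-1",      # P uptake (derived)
    "PUE": "g mg^-1",           # P utilization efficiency (derived)
    "RS_ratio": "-",            # root:shoot dry-weight ratio (derived)
}

#: Traits that cannot be negative (weights, lengths, concentrations, ratios).
NONNEGATIVE_TRAITS = frozenset(TRAIT_UNITS)

PHENOTYPE_COLUMNS = ["genotype_id", "treatment", "replicate", "trait", "value"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class PhenotypeTable:
    """Long-format phenotype records.

    ``data`` holds one row per (genotype_id, treatment, replicate, trait)
    with a real ``value`` (NaN = missing observation, kept explicit).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"phenotype table lacks columns {missing_cols}")
        df = df.loc[:, PHENOTYPE_COLUMNS].copy()
        df["genotype_id"] = df["genotype_id"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")

        bad_treat = df.loc[~df["treatment"].isin(TREATMENTS)]
        if len(bad_treat):
            rows = bad_treat.index.tolist()[:10]
            labels = sorted(bad_treat["treatment"].astype(str).unique())
            raise ValidationError(
                f"unknown treatment label(s) {labels} at rows {rows}; allowed: {TREATMENTS}"
            )
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
        if (df["replicate"] < 1).any():
            rows = df.index[df["replicate"] < 1].tolist()[:10]
            raise ValidationError(f"replicate must be a positive integer (rows {rows})")

        key = ["genotype_id", "treatment", "replicate", "trait"]
        dup = df.duplicated(subset=key, keep=False)
        if dup.any():
            offenders = df.loc[dup, key].drop_duplicates().head(5).to_dict("records")
            raise ValidationError(f"duplicate (genotype, treatment, replicate, trait) keys: {offenders}")

        neg = df["trait"].isin(NONNEGATIVE_TRAITS) & (df["value"] < 0)
        if neg.any():
            rows = df.index[neg].tolist()[:10]
            raise ValidationError(f"negative value for a non-negative trait at rows {rows}")

        self.data = df.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype_id"].unique())

    def subset_trait(self, trait: str) -> pd.DataFrame:
        return self.data.loc[self.data["trait"] == trait]

    def __len__(self) -> int:
        return len(self.data)


MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x markers alternate-allele dosage matrix with a marker map.

    ``dosage`` is a float array in {0, 1, ..., ploidy} with NaN for missing
    calls.  Markers are kept sorted by (chrom, pos); the constructor sorts
    and reorders columns if needed.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        mk = self.markers
        missing_cols = [c for c in MARKER_COLUMNS if c not in mk.columns]
        if missing_cols:
            raise ValidationError(f"marker map lacks columns {missing_cols}")
        mk = mk.loc[:, MARKER_COLUMNS].copy()
        mk["marker_id"] = mk["marker_id"].astype(str)
        mk["chrom"] = mk["chrom"].astype(str)
        mk["pos"] = mk["pos"].astype(int)
        if (mk["pos"] < 1).any():
            raise ValidationError("marker positions must be 1-based (>= 1)")
        if (mk["ref"] == mk["alt"]).any():
            bad = mk.loc[mk["ref"] == mk["alt"], "marker_id"].tolist()[:5]
            raise ValidationError(f"ref == alt for markers {bad}")
        if mk["marker_id"].duplicated().any():
            bad = mk.loc[mk["marker_id"].duplicated(), "marker_id"].tolist()[:5]
            raise ValidationError(f"duplicate marker ids {bad}")

        dosage = np.asarray(self.dosage, dtype=float)
        if dosage.shape != (len(self.sample_ids), len(mk)):
            raise ValidationError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(mk)} markers"
            )
        finite = dosage[np.isfinite(dosage)]
        if len(finite) and (finite.min() < 0 or finite.max() > self.ploidy):
            raise ValidationError(f"dosages must lie in [0, {self.ploidy}]")

        order = np.lexsort((mk["pos"].to_numpy(), mk["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(mk))):
            mk = mk.iloc[order].reset_index(drop=True)
            dosage = dosage[:, order]
        self.markers = mk.reset_index(drop=True)
        self.dosage = dosage

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return np.isfinite(self.dosage).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / self.ploidy

    def maf(self) -> np.ndarray:
        """Minor allele frequency, folded to <= 0.5."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep].copy(),
            ploidy=self.ploidy,
        )


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "description"]


@dataclass
class GeneAnnotationSet:
    """Gene records with 1-based inclusive [start, end] intervals."""

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in GENE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"gene annotation lacks columns {missing_cols}")
        df = df.loc[:, GENE_COLUMNS].copy()
        df["gene_id"] = df["gene_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"], "gene_id"].tolist()[:5]
            raise ValidationError(f"gene end < start for {bad}")
        if (df["start"] < 1).any():
            raise ValidationError("gene coordinates must be 1-based (>= 1)")
        if df["gene_id"].duplicated().any():
            bad = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()[:5]
            raise ValidationError(f"duplicate gene ids {bad}")
        self.data = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)
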