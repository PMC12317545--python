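"""Marker QC, mean imputation, PCA covariates, single-marker scan,
Bonferroni control, per-SNP phenotypic variance explained, and
candidate-gene window queries.

QC discards markers with call rate below 85% and then markers with minor
allele frequency below 5% (both strict: markers exactly at a threshold are
kept).  The scan is ordinary least squares of the phenotype on (intercept,
principal-component covariates, dosage) per marker - a PC-adjusted
single-marker model standing in for multi-locus scanners; the dosage
coefficient's two-sided t-test gives the p-value.  Significance uses the
Bonferroni rule -log10(p) > -log10(alpha / M) over the M tested markers.

PVE per SNP comes in two variants.  The "shim" form

    PVE = 2 b^2 f(1-f) / [2 b^2 f(1-f) + SE^2 * 2N f(1-f)]

(which reduces to b^2 / (b^2 + N SE^2)); and an "as_printed" form whose
denominator's first term is 2 b^2 (1-f), reproducing a published typesetting
of the same estimator that omits one MAF factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import GeneAnnotationSet, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    markers_in: int
    removed_call_rate: int
    removed_maf: int
    markers_out: int
    call_rate_min: float
    maf_min: float

    def __post_init__(self) -> None:
        assert self.markers_out == self.markers_in - self.removed_call_rate - self.removed_maf


def marker_qc(
    g: GenotypeMatrix, call_rate_min: float = 0.85, maf_min: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by call rate, then MAF (strict thresholds).

    Each marker is counted once: markers failing call rate never reach the
    MAF filter.  MAF uses non-missing samples only, folded to <= 0.5.
    """
    call = g.call_rate()
    pass_call = call >= call_rate_min
    with np.errstate(invalid="ignore"):
        maf = g.maf()
    pass_maf = np.where(np.isfinite(maf), maf >= maf_min, False)
    keep = pass_call & pass_maf
    report = QCReport(
        markers_in=g.n_markers,
        removed_call_rate=int((~pass_call).sum()),
        removed_maf=int((pass_call & ~pass_maf).sum()),
        markers_out=int(keep.sum()),
        call_rate_min=call_rate_min,
        maf_min=maf_min,
    )
    if report.markers_out == 0:
        raise ValidationError("marker QC removed every marker")
    logger.info(
        "marker_qc: %d -> %d markers (%d below call rate %.2f, %d below MAF %.2f)",
        report.markers_in, report.markers_out, report.removed_call_rate,
        call_rate_min, report.removed_maf, maf_min,
    )
    return g.subset_markers(keep), report


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with its marker's mean dosage."""
    dosage = g.dosage.copy()
    n_missing = int((~np.isfinite(dosage)).sum())
    if n_missing:
        col_ok = np.isfinite(dosage).any(axis=0)
        if not col_ok.all():
            bad = g.markers.loc[~col_ok, "marker_id"].tolist()[:5]
            raise ValidationError(f"markers with all calls missing: {bad}")
        col_mean = np.nanmean(dosage, axis=0)
        idx = np.where(np.isfinite(dosage), dosage, col_mean[None, :])
        dosage = idx
    return GenotypeMatrix(
        sample_ids=list(g.sample_ids), markers=g.markers.copy(), dosage=dosage, ploidy=g.ploidy
    )


def pca_covariates(g: GenotypeMatrix, n_pc: int = 3, scale: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Top principal-component scores of the (imputed) dosage matrix.

    Markers are centered (optionally scaled to unit variance); returns the
    samples x n_pc score matrix and the explained-variance fractions.
    """
    if n_pc >= min(g.n_samples, g.n_markers):
        raise ValidationError("n_pc must be < min(n_samples, n_markers)")
    x = g.dosage
    if not np.isfinite(x).all():
        raise ValidationError("PCA needs an imputed (complete) dosage matrix")
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if np.allclose(x.var(axis=0), 0):
        raise ValidationError("dosage matrix is constant; PCA undefined")
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(x)
    return scores, pca.explained_variance_ratio_


def glm_scan(
    g: GenotypeMatrix,
    y: np.ndarray | pd.Series,
    covariates: np.ndarray | None = None,
    trait: str = "",
) -> pd.DataFrame:
    """Per-marker least-squares scan of y on (intercept, covariates, dosage).

    y must be aligned to ``g.sample_ids``; samples with missing phenotype
    are dropped.  Returns one record per marker with the dosage
    coefficient's effect, SE, two-sided t-test p-value, MAF, N and PVE
    (both variants).  Markers constant after imputation get missing
    statistics and ``degenerate=True``.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_samples:
        raise ValidationError("phenotype vector not aligned to sample order")
    keep = np.isfinite(y)
    x = g.dosage[keep]
    if not np.isfinite(x).all():
        raise ValidationError("scan needs an imputed (complete) dosage matrix")
    yk = y[keep]
    n = int(keep.sum())
    c = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), np.asarray(covariates)[keep]])
    if n < c.shape[1] + 2:
        raise ValidationError(f"only {n} samples with phenotype; need >= {c.shape[1] + 2}")

    # Frisch-Waugh: residualize y and every marker against the covariates,
    # then each marker's simple regression equals its full-model coefficient.
    q, _ = np.linalg.qr(c)
    yr = yk - q @ (q.T @ yk)
    xr = x - q @ (q.T @ x)
    sxx = (xr**2).sum(axis=0)
    degenerate = sxx <= 1e-12
    sxx_safe = np.where(degenerate, np.nan, sxx)
    sxy = xr.T @ yr
    beta = sxy / sxx_safe
    df = n - c.shape[1] - 1
    rss = (yr**2).sum() - beta * sxy
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx_safe)
        t = np.where(se > 0, beta / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df)

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g.dosage, axis=0) / g.ploidy
    maf = np.minimum(freq, 1.0 - freq)
    pve_shim = np.full_like(beta, np.nan)
    pve_printed = np.full_like(beta, np.nan)
    ok = ~degenerate & np.isfinite(se) & (se > 0) & (maf > 0)
    pve_shim[ok] = compute_pve(beta[ok], se[ok], maf[ok], n, variant="shim")
    pve_printed[ok] = compute_pve(beta[ok], se[ok], maf[ok], n, variant="as_printed")

    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("glm_scan: %d degenerate (constant) marker(s) flagged", n_deg)
    return pd.DataFrame(
        {
            "trait": trait,
            "marker_id": g.markers["marker_id"],
            "chrom": g.markers["chrom"],
            "pos": g.markers["pos"],
            "ref": g.markers["ref"],
            "alt": g.markers["alt"],
            "beta": beta,
            "se": se,
            "p": p,
            "maf": maf,
            "n": n,
            "pve": pve_shim,
            "pve_as_printed": pve_printed,
            "degenerate": degenerate,
        }
    )


@dataclass
class SignificanceRule:
    """Bonferroni rule: significant iff -log10(p) > -log10(alpha / M)."""

    alpha: float
    n_tests: int
    threshold_neglog10p: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_tests <= 0:
            raise ValidationError("Bonferroni rule needs M >= 1 valid tests")
        self.threshold_neglog10p = float(-np.log10(self.alpha / self.n_tests))


def apply_bonferroni(records: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, SignificanceRule]:
    """Flag records passing the Bonferroni threshold over the valid tests.

    M counts records with a valid p-value; the inequality is strict, so a
    marker at exactly p = alpha/M is not significant.
    """
    valid = records["p"].notna()
    rule = SignificanceRule(alpha=alpha, n_tests=int(valid.sum()))
    out = records.copy()
    with np.errstate(divide="ignore"):
        neglog = -np.log10(out["p"].to_numpy(dtype=float))
    out["significant"] = valid.to_numpy() & (neglog > rule.threshold_neglog10p)
    return out, rule


def compute_pve(
    beta: float | np.ndarray,
    se_beta: float | np.ndarray,
    maf: float | np.ndarray,
    n: int,
    variant: str = "shim",
) -> float | np.ndarray:
    """Proportion of phenotypic variance explained by one SNP.

    variant "shim": 2 b^2 f(1-f) / [2 b^2 f(1-f) + SE^2 2N f(1-f)]
    variant "as_printed": denominator first term is 2 b^2 (1-f).
    Both lie in [0, 1].
    """
    beta = np.asarray(beta, dtype=float)
    se_beta = np.asarray(se_beta, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValidationError("MAF must lie in (0, 0.5]")
    if np.any(se_beta <= 0):
        raise ValidationError("SE(beta) must be positive")
    if n < 2:
        raise ValidationError("n must be >= 2")
    num = 2.0 * beta**2 * maf * (1.0 - maf)
    noise = se_beta**2 * 2.0 * n * maf * (1.0 - maf)
    if variant == "shim":
        den = num + noise
    elif variant == "as_printed":
        den = 2.0 * beta**2 * (1.0 - maf) + noise
    else:
        raise ValidationError(f"unknown PVE variant {variant!r}")
    out = np.where(den > 0, num / den, 0.0)
    return float(out) if out.ndim == 0 else out


def candidate_genes(
    marker: pd.Series | dict,
    genes: GeneAnnotationSet,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Genes overlapping the +-window_bp interval around a marker.

    A gene [start, end] on the marker's chromosome is reported when it
    overlaps [pos - window_bp, pos + window_bp] (all bounds inclusive).
    ``distance`` is 0 for genes spanning the marker, else the bp gap to the
    nearer gene edge; output is sorted by (distance, gene_id).
    """
    chrom = str(marker["chrom"])
    pos = int(marker["pos"])
    lo, hi = pos - window_bp, pos + window_bp
    df = genes.data
    hit = df.loc[(df["chrom"] == chrom) & (df["end"] >= lo) & (df["start"] <= hi)].copy()
    inside = (hit["start"] <= pos) & (hit["end"] >= pos)
    hit["distance"] = np.where(
        inside, 0, np.minimum(np.abs(hit["start"] - pos), np.abs(hit["end"] - pos))
    ).astype(int)
    hit["marker_id"] = str(marker.get("marker_id", f"{chrom}_{pos}"))
    cols = ["marker_id", "gene_id", "chrom", "start", "end", "distance", "description"]
    return hit.sort_values(["distance", "gene_id"], kind="mergesort").reset_index(drop=True).loc[:, cols]
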