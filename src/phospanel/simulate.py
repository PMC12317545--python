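"""Synthetic phenotype panels and structured SNP matrices with known truth.

The phenotype generator emulates a balanced two-treatment pot experiment:

    value = mu_t + g_i + (gt)_it + sum_m beta_m * x_im * [record targeted] + eps

with genotype effects g ~ N(0, sigma_G^2) shared across treatments,
interaction effects (gt) ~ N(0, sigma_GT^2) per genotype x treatment, and
residuals eps ~ N(0, sigma_Re^2) per observation.  Under T treatments and
R replicates this implies a closed-form broad-sense heritability

    H2 = sigma_G^2 / (sigma_G^2 + sigma_GT^2/T + sigma_Re^2/(T R)).

The genotype generator uses the Balding-Nichols construction: per marker an
ancestral frequency p ~ U(0.05, 0.95), subpopulation frequencies drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F) so F controls divergence, and dosages from
Binomial(2, p_k), then missingness masking.

Defaults mirror the study conditions: 200 genotypes, 2 treatments (HP/LP),
2 replicates, trait means/SDs/heritabilities from the published panel
summary, and a 12-chromosome SNP matrix of ~4,800 markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    MARKER_COLUMNS,
    NONNEGATIVE_TRAITS,
    TREATMENTS,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class TraitParams:
    """Per-trait generator settings, all in the trait's own units."""

    mean_hp: float
    mean_lp: float
    sigma_g: float      # genotypic SD
    sigma_gt: float     # genotype-by-treatment SD
    sigma_res: float    # residual SD

    def true_h2(self, n_treatments: int = 2, n_replicates: int = 2) -> float:
        """Closed-form broad-sense heritability implied by the variances."""
        var_p = (
            self.sigma_g**2
            + self.sigma_gt**2 / n_treatments
            + self.sigma_res**2 / (n_treatments * n_replicates)
        )
        return self.sigma_g**2 / var_p if var_p > 0 else float("nan")


def _trait_params_from_summary(mean_hp: float, mean_lp: float, sd_hp: float, h2: float) -> TraitParams:
    """Back out generator SDs from a published panel summary row.

    The printed SD is over genotype means under HP, i.e. an estimate of
    sigma_P = sqrt(sigma_G^2 + sigma_GT^2/T + sigma_Re^2/(TR)).  With
    H2 = sigma_G^2/sigma_P^2 that fixes sigma_G; the remainder is split with
    the convention sigma_Re^2 = 2 sigma_GT^2 (then sigma_GT^2/2 + sigma_Re^2/4
    = sigma_GT^2 each contribute half of the non-genetic part for T=R=2).
    """
    var_p = sd_hp**2
    var_g = h2 * var_p
    rest = var_p - var_g          # = sigma_GT^2/2 + sigma_Re^2/4 at T=R=2
    var_gt = rest                 # solves rest = var_gt/2 + 2*var_gt/4
    var_res = 2.0 * var_gt
    return TraitParams(mean_hp, mean_lp, np.sqrt(var_g), np.sqrt(var_gt), np.sqrt(var_res))


def default_trait_params() -> dict[str, TraitParams]:
    """Study-condition defaults for the primary (measured) traits.

    Per-treatment means, SD over genotype means (HP), and broad-sense
    heritability per trait follow the published panel summary.  P uptake,
    PUE, root:shoot ratio and the biomass totals are always derived
    downstream, never simulated directly.
    """
    rows = {
        # trait: (mean_HP, mean_LP, sd_HP, H2)
        "SFW": (14.28, 3.66, 3.34, 0.61),
        "SDW": (1.53, 0.50, 0.38, 0.55),
        "RFW": (5.76, 3.14, 2.12, 0.69),
        "RDW": (0.64, 0.38, 0.25, 0.71),
        "TFW": (4.41, 2.25, 2.16, 0.58),
        "TDW": (0.52, 0.43, 0.30, 0.51),
        "RL": (22.97, 19.53, 2.97, 0.63),
        "P_conc": (321.04, 172.43, 51.59, 0.64),
        "PH1": (4.98, 4.93, 1.66, 0.77),
        "PH2": (16.35, 11.08, 3.36, 0.88),
    }
    return {t: _trait_params_from_summary(*v) for t, v in rows.items()}


@dataclass
class PlantedEffect:
    """A marker effect planted into one trait (optionally one treatment)."""

    marker_index: int
    trait: str
    beta: float                 # effect per alternate-allele copy, trait units
    treatment: str | None = None  # None = both treatments


@dataclass
class PhenoSimConfig:
    n_genotypes: int = 200
    n_replicates: int = 2
    treatments: tuple[str, str] = TREATMENTS
    trait_params: dict[str, TraitParams] = field(default_factory=default_trait_params)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    missing_cell_rate: float = 0.0  # optional random deletion, to test unbalanced handling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        for t, p in self.trait_params.items():
            if min(p.sigma_g, p.sigma_gt, p.sigma_res) < 0:
                raise ValidationError(f"negative SD for trait {t}")
        for eff in self.planted_effects:
            if eff.trait not in self.trait_params:
                raise ValidationError(f"planted effect targets unknown trait {eff.trait!r}")


@dataclass
class GenoSimConfig:
    n_samples: int = 200
    n_markers: int = 4800
    n_chromosomes: int = 12
    chrom_length_bp: int = 60_000_000
    n_subpopulations: int = 3
    divergence_f: float = 0.2   # Balding-Nichols F in (0, 1)
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0 < self.divergence_f < 1:
            raise ValidationError("divergence_f must be in (0, 1)")


@dataclass
class SimTruth:
    """Ground truth realized by a simulation, for parameter-recovery tests."""

    seed: int
    genotype_effects: pd.DataFrame | None = None   # genotype x trait g_i
    interaction_effects: pd.DataFrame | None = None
    true_h2: dict[str, float] = field(default_factory=dict)
    planted: pd.DataFrame | None = None            # marker_id, trait, beta, maf
    subpopulation: np.ndarray | None = None        # per-sample subpop index
    generating_freqs: np.ndarray | None = None     # subpop x marker allele freqs
    n_truncated: int = 0


def simulate_genotypes(cfg: GenoSimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a structured diploid SNP panel with known subpopulations."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    n, m = cfg.n_samples, cfg.n_markers

    subpop = rng.integers(0, cfg.n_subpopulations, size=n)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = cfg.divergence_f
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    # subpop x marker allele frequencies, kept away from exact 0/1
    p_sub = np.clip(rng.beta(a, b, size=(cfg.n_subpopulations, m)), 1e-6, 1 - 1e-6)
    dosage = rng.binomial(2, p_sub[subpop, :]).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(size=dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan

    # markers spread evenly over chromosomes, random sorted positions within
    chrom_idx = np.arange(m) % cfg.n_chromosomes
    markers = []
    for c in range(cfg.n_chromosomes):
        on_c = np.flatnonzero(chrom_idx == c)
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=len(on_c)))
        while len(pos) < len(on_c):  # top up collisions (rare for bp-scale ranges)
            extra = rng.integers(1, cfg.chrom_length_bp + 1, size=len(on_c) - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        for k, j in enumerate(on_c):
            markers.append((f"snp{j:05d}", f"chr{c + 1:02d}", int(pos[k]), "A", "G"))
    marker_df = pd.DataFrame(markers, columns=MARKER_COLUMNS)

    g = GenotypeMatrix(sample_ids=[f"G{i + 1:03d}" for i in range(n)], markers=marker_df, dosage=dosage)
    truth = SimTruth(seed=cfg.seed, subpopulation=subpop, generating_freqs=p_sub)
    return g, truth


def simulate_phenotypes(
    cfg: PhenoSimConfig,
    genotypes: GenotypeMatrix | None = None,
    geno_cfg: GenoSimConfig | None = None,
) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate a balanced phenotype table; returns the table and its truth.

    Planted marker effects require ``genotypes`` (missing dosages enter via
    their marker-mean, so the planted signal is defined for every sample).
    Negative draws for non-negative traits are truncated at zero (count
    logged and recorded in the truth).
    """
    if cfg.planted_effects and genotypes is None:
        if geno_cfg is None:
            raise ValidationError("planted effects require genotypes or a genotype config")
        genotypes, _ = simulate_genotypes(geno_cfg)
    if genotypes is not None and genotypes.n_samples < cfg.n_genotypes:
        raise ValidationError("genotype matrix has fewer samples than n_genotypes")
    for eff in cfg.planted_effects:
        if not 0 <= eff.marker_index < genotypes.n_markers:
            raise ValidationError(f"planted marker index {eff.marker_index} out of range")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    if genotypes is not None:
        geno_ids = genotypes.sample_ids[: cfg.n_genotypes]
    else:
        geno_ids = [f"G{i + 1:03d}" for i in range(cfg.n_genotypes)]
    traits = list(cfg.trait_params)
    n_g, n_t, n_r = cfg.n_genotypes, len(cfg.treatments), cfg.n_replicates

    g_eff = {t: rng.normal(0.0, cfg.trait_params[t].sigma_g, size=n_g) for t in traits}
    gt_eff = {t: rng.normal(0.0, cfg.trait_params[t].sigma_gt, size=(n_g, n_t)) for t in traits}

    planted_rows = []
    planted_shift = {t: np.zeros((n_g, n_t)) for t in traits}
    for eff in cfg.planted_effects:
        col = genotypes.dosage[: cfg.n_genotypes, eff.marker_index]
        x = np.where(np.isfinite(col), col, np.nanmean(col))
        for ti, treat in enumerate(cfg.treatments):
            if eff.treatment is None or eff.treatment == treat:
                planted_shift[eff.trait][:, ti] += eff.beta * x
        freq = np.nanmean(col) / genotypes.ploidy
        planted_rows.append(
            {
                "marker_id": genotypes.markers["marker_id"].iloc[eff.marker_index],
                "trait": eff.trait,
                "treatment": eff.treatment,
                "beta": eff.beta,
                "maf": min(freq, 1 - freq),
            }
        )

    records = []
    n_trunc = 0
    for t_i, trait in enumerate(traits):
        p = cfg.trait_params[trait]
        mu = {"HP": p.mean_hp, "LP": p.mean_lp}
        eps = rng.normal(0.0, p.sigma_res, size=(n_g, n_t, n_r))
        for ti, treat in enumerate(cfg.treatments):
            base = mu[treat] + g_eff[trait] + gt_eff[trait][:, ti] + planted_shift[trait][:, ti]
            for r in range(n_r):
                vals = base + eps[:, ti, r]
                if trait in NONNEGATIVE_TRAITS:
                    neg = vals < 0
                    n_trunc += int(neg.sum())
                    vals = np.where(neg, 0.0, vals)
                records.append(
                    pd.DataFrame(
                        {
                            "genotype_id": geno_ids,
                            "treatment": treat,
                            "replicate": r + 1,
                            "trait": trait,
                            "value": vals,
                        }
                    )
                )
    df = pd.concat(records, ignore_index=True)
    if cfg.missing_cell_rate > 0:
        drop = rng.random(len(df)) < cfg.missing_cell_rate
        df = df.loc[~drop].reset_index(drop=True)
    if n_trunc:
        logger.info("simulate_phenotypes: truncated %d negative draw(s) at 0", n_trunc)

    truth = SimTruth(
        seed=cfg.seed,
        genotype_effects=pd.DataFrame(g_eff, index=geno_ids),
        true_h2={t: cfg.trait_params[t].true_h2(n_t, n_r) for t in traits},
        planted=pd.DataFrame(planted_rows) if planted_rows else None,
        n_truncated=n_trunc,
    )
    return PhenotypeTable(df), truth
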