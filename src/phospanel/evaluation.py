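"""Quantitative benchmark experiments over the pipeline's own simulator.

Each function runs a self-contained experiment at the study's scale
(200-genotype panels, ~4,800-marker SNP matrices) and returns the measured
quantities: heritability recovery, scan type-I calibration and power on a
planted marker, and a full synthetic panel reproduction of the headline
phenotypic statistics.  They back both the test suite and the acceptance
script, so all reported numbers come from one code path.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .association import apply_bonferroni, glm_scan, impute_mean, marker_qc, pca_covariates
from .phenostats import (
    anova_two_way,
    change_metrics,
    derive_traits,
    genotype_means,
    summary_table,
    variance_components,
)
from .simulate import (
    GenoSimConfig,
    PhenoSimConfig,
    TraitParams,
    simulate_genotypes,
    simulate_phenotypes,
)
from .tolerance import DEFAULT_MFVP_TRAITS, compute_mfvp, compute_sti, rank_select


def trait_params_for_h2(h2: float, mean_hp: float = 10.0, mean_lp: float = 8.0) -> TraitParams:
    """TraitParams with unit phenotypic variance and exact target H2.

    Uses the generator's variance-split convention (sigma_Re^2 = 2 sigma_GT^2)
    so TraitParams.true_h2(2, 2) equals ``h2`` exactly.
    """
    rest = 1.0 - h2
    return TraitParams(mean_hp, mean_lp, np.sqrt(h2), np.sqrt(rest), np.sqrt(2 * rest))


def heritability_recovery(
    h2_targets: tuple[float, ...] = (0.3, 0.6, 0.9),
    n_panels: int = 200,
    n_genotypes: int = 200,
    base_seed: int = 0,
) -> dict[float, float]:
    """Mean ANOVA-estimated H2 over simulated panels per target level."""
    out = {}
    for level, h2 in enumerate(h2_targets):
        params = trait_params_for_h2(h2)
        estimates = []
        for k in range(n_panels):
            cfg = PhenoSimConfig(
                n_genotypes=n_genotypes,
                trait_params={"SDW": params},
                seed=base_seed + 10_000 * level + k,
            )
            table, _ = simulate_phenotypes(cfg)
            vc = variance_components(anova_two_way(table, "SDW"))
            estimates.append(vc.h2_bs)
        out[h2] = float(np.nanmean(estimates))
    return out


def scan_type1_rate(
    n_seeds: int = 50,
    n_samples: int = 200,
    n_markers: int = 500,
    n_pc: int = 3,
    base_seed: int = 0,
) -> tuple[float, int]:
    """Fraction of markers with p < 0.05 under the global null.

    The phenotype is pure noise, independent of the genotypes; returns the
    pooled fraction and the number of valid tests pooled over seeds.
    """
    n_below, n_tests = 0, 0
    for k in range(n_seeds):
        g, _ = simulate_genotypes(
            GenoSimConfig(n_samples=n_samples, n_markers=n_markers, missing_rate=0.0,
                          seed=base_seed + k)
        )
        scores, _ = pca_covariates(g, n_pc=n_pc)
        y = np.random.default_rng(base_seed + 90_000 + k).normal(size=n_samples)
        rec = glm_scan(g, y, covariates=scores)
        valid = rec["p"].dropna()
        n_below += int((valid < 0.05).sum())
        n_tests += len(valid)
    return n_below / n_tests, n_tests


def scan_power_planted_marker(
    n_seeds: int = 50,
    n_samples: int = 200,
    n_markers: int = 4800,
    target_pve: float = 0.10,
    n_pc: int = 3,
    base_seed: int = 0,
) -> dict[str, float]:
    """Detection of one planted common marker sized to a target PVE.

    Per seed: simulate a structured panel, QC + impute, plant an additive
    effect on the post-QC marker nearest MAF 0.5.  beta is sized on the
    scale the scan (and its PVE estimator) actually sees: the marker's
    variance after removing the PC covariates, so the planted SNP explains
    ``target_pve`` of the structure-adjusted phenotypic variance.  Reports
    how often the planted marker attains the smallest p-value and how
    often its Bonferroni flag is set.
    """
    top1 = 0
    flagged = 0
    for k in range(n_seeds):
        seed = base_seed + k
        g, _ = simulate_genotypes(
            GenoSimConfig(n_samples=n_samples, n_markers=n_markers, missing_rate=0.05, seed=seed)
        )
        filtered, _ = marker_qc(g)
        imputed = impute_mean(filtered)
        scores, _ = pca_covariates(imputed, n_pc=n_pc)
        maf = imputed.maf()
        target = int(np.argmin(np.abs(maf - 0.5)))
        x = imputed.dosage[:, target]
        c = np.column_stack([np.ones(n_samples), scores])
        q, _ = np.linalg.qr(c)
        x_resid = x - q @ (q.T @ x)
        var_x = float((x_resid**2).mean())
        # beta^2 var(x_adj) / (beta^2 var(x_adj) + 1) = target_pve, unit noise
        beta = np.sqrt(target_pve / (1 - target_pve) / var_x)
        rng = np.random.default_rng(seed + 50_000)
        y = beta * x + rng.normal(size=n_samples)
        rec = glm_scan(imputed, y, covariates=scores)
        rec, _ = apply_bonferroni(rec)
        if int(rec["p"].idxmin()) == target:
            top1 += 1
        if bool(rec.loc[target, "significant"]):
            flagged += 1
    return {
        "top1_rate": top1 / n_seeds,
        "bonferroni_rate": flagged / n_seeds,
        "n_seeds": n_seeds,
    }


def panel_reproduction(seed: int = 0, n_genotypes: int = 200, n_markers: int = 4800) -> dict[str, float]:
    """Full synthetic study-scale run; returns the headline statistics.

    Simulates the default panel (published trait means/SDs/heritabilities),
    derives the P-efficiency traits, and measures: per-trait H2, mean
    HP->LP reductions for shoot/root biomass, root:shoot-ratio change,
    counts of genotypes with increased RDW/RL under stress, the P-uptake
    STI extremes, the MFVP range, and the marker-QC/scan bookkeeping.
    """
    geno_cfg = GenoSimConfig(n_samples=n_genotypes, n_markers=n_markers, missing_rate=0.05, seed=seed)
    genotypes, _ = simulate_genotypes(geno_cfg)
    table, _ = simulate_phenotypes(PhenoSimConfig(n_genotypes=n_genotypes, seed=seed), genotypes=genotypes)
    table = derive_traits(table)
    means = genotype_means(table)

    summary = summary_table(table).set_index("trait")
    ch_sdw = change_metrics(means, "SDW")
    ch_rdw = change_metrics(means, "RDW")
    ch_rl = change_metrics(means, "RL")
    ch_rs = change_metrics(means, "RS_ratio")

    sti_tables = {t: compute_sti(means, t) for t in DEFAULT_MFVP_TRAITS}
    mfvp = compute_mfvp(sti_tables, list(DEFAULT_MFVP_TRAITS))
    top, bottom = rank_select(mfvp, 20)
    sti_pupt = sti_tables["Pupt"].data["sti"]

    filtered, qc = marker_qc(genotypes)
    imputed = impute_mean(filtered)
    scores, _ = pca_covariates(imputed, n_pc=3)
    y = means.loc[(means["trait"] == "Pupt") & (means["treatment"] == "LP")]
    y = y.set_index("genotype_id")["mean"].reindex(imputed.sample_ids)
    rec = glm_scan(imputed, y, covariates=scores, trait="Pupt_LP")
    rec, rule = apply_bonferroni(rec)

    return {
        "n_genotypes": n_genotypes,
        "h2_sdw": float(summary.loc["SDW", "H2_bs"]),
        "h2_ph2": float(summary.loc["PH2", "H2_bs"]),
        "sdw_mean_pct_reduction": ch_sdw.mean_pct_reduction,
        "rdw_mean_pct_reduction": ch_rdw.mean_pct_reduction,
        "rs_ratio_mean_pct_increase": -ch_rs.mean_pct_reduction,
        "n_increased_rdw_lp": ch_rdw.n_increased_under_lp,
        "n_increased_rl_lp": ch_rl.n_increased_under_lp,
        "sti_pupt_max": float(sti_pupt.max()),
        "sti_pupt_min": float(sti_pupt.min()),
        "mfvp_max": float(mfvp.data["mfvp"].max()),
        "mfvp_min": float(mfvp.data["mfvp"].min()),
        "top20_mean_mfvp": float(top["mfvp"].mean()),
        "markers_post_qc": qc.markers_out,
        "bonferroni_threshold_neglog10p": rule.threshold_neglog10p,
        "n_significant_pupt_lp": int(rec["significant"].sum()),
    }
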