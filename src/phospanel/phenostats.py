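"""Derived traits, descriptive statistics, two-way ANOVA, variance
components, broad-sense heritability, and HP-vs-LP change metrics.

The ANOVA fits the balanced fixed-effects model

    y_itr = mu + E_r + G_i + T_t + (GT)_it + e_itr

(replication blocks E, genotypes G, treatments T).  Variance components
follow the mean-square method:

    sigma2_G  = (MSQ_G - MSQ_GT) / (T R)
    sigma2_GT = (MSQ_GT - MSQ_Re) / R
    sigma2_Re = MSQ_Re
    sigma2_P  = sigma2_G + sigma2_GT / T + sigma2_Re / (T R)
    H2_bs     = sigma2_G / sigma2_P

Negative raw component estimates are clamped to zero for reporting; the raw
values are retained for diagnostics.  The block term is tested but excluded
from the component formulas, exactly as the mean-square equations imply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PhenotypeTable, ValidationError

logger = logging.getLogger(__name__)

#: Derived trait -> (source traits, function over a wide per-record frame).
_DERIVATIONS = {
    # P uptake (mg): shoot P concentration [mg/100g] x shoot dry weight [g] / 100
    "Pupt": (("P_conc", "SDW"), lambda w: w["P_conc"] * w["SDW"] / 100.0),
    # P utilization efficiency (g/mg): shoot dry weight over P uptake; guard Pupt=0
    "PUE": (("SDW", "Pupt"), lambda w: w["SDW"] / w["Pupt"].replace(0.0, np.nan)),
    # root:shoot dry-weight ratio; guard SDW=0
    "RS_ratio": (("RDW", "SDW"), lambda w: w["RDW"] / w["SDW"].replace(0.0, np.nan)),
    "TotalFW": (("SFW", "RFW", "TFW"), lambda w: w["SFW"] + w["RFW"] + w["TFW"]),
    "TotalDW": (("SDW", "RDW", "TDW"), lambda w: w["SDW"] + w["RDW"] + w["TDW"]),
}


def derive_traits(table: PhenotypeTable) -> PhenotypeTable:
    """Add derived traits wherever their source traits exist.

    Pupt = P_conc x SDW / 100 [mg]; PUE = SDW / Pupt [g/mg] (missing when
    Pupt = 0); RS_ratio = RDW / SDW; TotalFW/TotalDW are sums of their
    components.  Pre-existing derived records are overwritten with a warning.
    """
    key = ["genotype_id", "treatment", "replicate"]
    wide = table.data.pivot_table(index=key, columns="trait", values="value", aggfunc="first")
    new_frames = []
    overwritten = []
    computed = []
    for trait, (sources, fn) in _DERIVATIONS.items():
        if not all(s in wide.columns for s in sources):
            continue
        computed.append(trait)
        if trait in wide.columns and wide[trait].notna().any():
            overwritten.append(trait)
        vals = fn(wide)
        wide[trait] = vals  # later derivations (PUE) consume earlier ones (Pupt)
        frame = vals.rename("value").reset_index()
        frame["trait"] = trait
        new_frames.append(frame)
    if overwritten:
        logger.warning("derive_traits: overwriting existing derived trait(s) %s", overwritten)
    base = table.data.loc[~table.data["trait"].isin(computed)].copy()
    out = pd.concat([base] + new_frames, ignore_index=True)
    return PhenotypeTable(out)


def genotype_means(table: PhenotypeTable) -> pd.DataFrame:
    """Replicate means per (genotype, treatment, trait).

    Missing replicates are excluded from the mean; ``n_reps`` records how
    many non-missing observations entered each mean.  Cells with no
    non-missing replicate at all are absent from the output (logged).
    """
    df = table.data
    grouped = df.groupby(["genotype_id", "treatment", "trait"])["value"]
    out = grouped.agg(mean="mean", n_reps="count").reset_index()
    empty = out["n_reps"] == 0
    if empty.any():
        logger.info("genotype_means: dropping %d cell(s) with no non-missing replicate", int(empty.sum()))
        out = out.loc[~empty].reset_index(drop=True)
    return out


def descriptive_stats(means: pd.DataFrame) -> pd.DataFrame:
    """Min / mean / max / sample SD over genotype means, per trait x treatment."""
    out = (
        means.groupby(["trait", "treatment"])["mean"]
        .agg(n="count", min="min", mean="mean", max="max", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2, ["trait", "treatment"]].to_dict("records")
        raise ValidationError(f"descriptive stats need >= 2 genotypes; offending cells: {bad}")
    return out


@dataclass
class AnovaResult:
    """Balanced two-way ANOVA partition for one trait."""

    trait: str
    table: pd.DataFrame  # term, ss, df, ms, F, p  (terms: block, genotype, treatment, gxt, residual)
    n_genotypes: int
    n_treatments: int
    n_replicates: int

    def ms(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "ms"])

    @property
    def msq_g(self) -> float:
        return self.ms("genotype")

    @property
    def msq_gt(self) -> float:
        return self.ms("gxt")

    @property
    def msq_re(self) -> float:
        return self.ms("residual")


def anova_two_way(table: PhenotypeTable, trait: str) -> AnovaResult:
    """Fixed-effects ANOVA of one trait on a balanced G x T x R design.

    Sums of squares are partitioned into replication block (E), genotype
    (G), treatment (T), G x T interaction, and residual; each term is
    F-tested against the residual mean square.  Unbalanced or incomplete
    designs are rejected (the variance-component formulas require balance);
    use the balance-enforcing subset option of the pipeline first.
    """
    df = table.subset_trait(trait).dropna(subset=["value"])
    if df.empty:
        raise ValidationError(f"no observations for trait {trait!r}")
    genos = np.sort(df["genotype_id"].unique())
    treats = np.sort(df["treatment"].unique())
    reps = np.sort(df["replicate"].unique())
    n_g, n_t, n_r = len(genos), len(treats), len(reps)
    if n_g < 2 or n_t < 2 or n_r < 2:
        raise ValidationError("ANOVA needs >= 2 genotypes, treatments and replicates")
    counts = df.groupby(["genotype_id", "treatment"])["value"].count()
    if len(counts) != n_g * n_t or (counts != n_r).any():
        raise ValidationError(
            f"trait {trait!r} is unbalanced: every genotype x treatment cell needs exactly "
            f"{n_r} observations; use the balance-enforcing subset option"
        )

    # cube genotypes x treatments x replicates
    cube = (
        df.set_index(["genotype_id", "treatment", "replicate"])["value"]
        .unstack(["treatment", "replicate"])
        .loc[genos]
        .to_numpy()
        .reshape(n_g, n_t, n_r)
    )
    grand = cube.mean()
    ss_total = float(((cube - grand) ** 2).sum())
    ss_g = n_t * n_r * float(((cube.mean(axis=(1, 2)) - grand) ** 2).sum())
    ss_t = n_g * n_r * float(((cube.mean(axis=(0, 2)) - grand) ** 2).sum())
    ss_e = n_g * n_t * float(((cube.mean(axis=(0, 1)) - grand) ** 2).sum())
    cell = cube.mean(axis=2)
    ss_gt = n_r * float(
        ((cell - cube.mean(axis=(1, 2))[:, None] - cube.mean(axis=(0, 2))[None, :] + grand) ** 2).sum()
    )
    ss_res = ss_total - ss_g - ss_t - ss_e - ss_gt

    rows = []
    df_res = n_g * n_t * n_r - 1 - (n_g - 1) - (n_t - 1) - (n_r - 1) - (n_g - 1) * (n_t - 1)
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    for term, ss, dfree in [
        ("block", ss_e, n_r - 1),
        ("genotype", ss_g, n_g - 1),
        ("treatment", ss_t, n_t - 1),
        ("gxt", ss_gt, (n_g - 1) * (n_t - 1)),
        ("residual", ss_res, df_res),
    ]:
        ms = ss / dfree if dfree > 0 else np.nan
        if term == "residual" or not np.isfinite(ms_res) or ms_res <= 0:
            f_stat, p = np.nan, np.nan
        else:
            f_stat = ms / ms_res
            p = float(stats.f.sf(f_stat, dfree, df_res))
        rows.append({"term": term, "ss": ss, "df": dfree, "ms": ms, "F": f_stat, "p": p})
    return AnovaResult(
        trait=trait,
        table=pd.DataFrame(rows),
        n_genotypes=n_g,
        n_treatments=n_t,
        n_replicates=n_r,
    )


@dataclass
class VarianceComponents:
    trait: str
    sigma2_g: float
    sigma2_gt: float
    sigma2_re: float
    sigma2_p: float
    h2_bs: float
    raw: dict[str, float] = field(default_factory=dict)  # pre-clamp values


def variance_components(a: AnovaResult, n_treatments: int | None = None, n_replicates: int | None = None) -> VarianceComponents:
    """Mean-square variance components and broad-sense heritability.

    Negative raw estimates are clamped to 0 for reporting (raw kept in
    ``raw``); H2_bs is sigma2_G / sigma2_P, missing when sigma2_P = 0.
    """
    t = n_treatments if n_treatments is not None else a.n_treatments
    r = n_replicates if n_replicates is not None else a.n_replicates
    if t < 2 or r < 2:
        raise ValidationError("variance components need T >= 2 and R >= 2")
    raw_g = (a.msq_g - a.msq_gt) / (t * r)
    raw_gt = (a.msq_gt - a.msq_re) / r
    raw_re = a.msq_re
    s_g, s_gt, s_re = (max(v, 0.0) for v in (raw_g, raw_gt, raw_re))
    s_p = s_g + s_gt / t + s_re / (t * r)
    h2 = s_g / s_p if s_p > 0 else np.nan
    return VarianceComponents(
        trait=a.trait,
        sigma2_g=s_g,
        sigma2_gt=s_gt,
        sigma2_re=s_re,
        sigma2_p=s_p,
        h2_bs=h2,
        raw={"sigma2_g": raw_g, "sigma2_gt": raw_gt, "sigma2_re": raw_re},
    )


def significance_stars(p: float) -> str:
    """Star coding used in the result tables (*** / ** / * / NS)."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class ChangeMetrics:
    """Per-genotype HP-to-LP change for one trait, plus panel summary."""

    trait: str
    per_genotype: pd.DataFrame  # genotype_id, hp, lp, delta, pct_reduction
    mean_pct_reduction: float   # mean of per-genotype percent reductions
    pct_reduction_of_means: float  # 100 * (mean HP - mean LP) / mean HP
    n_increased_under_lp: int
    increased_under_lp: list[str] = field(default_factory=list)


def change_metrics(means: pd.DataFrame, trait: str) -> ChangeMetrics:
    """HP - LP differences and percent reductions per genotype.

    Genotypes with LP > HP get negative reductions and are counted as
    "increased under LP".  Percent reduction is missing where the HP mean
    is 0.  The panel summary averages per-genotype percent reductions
    (ratio-of-means also reported).
    """
    sub = means.loc[means["trait"] == trait]
    wide = sub.pivot_table(index="genotype_id", columns="treatment", values="mean", aggfunc="first")
    if "HP" not in wide.columns or "LP" not in wide.columns:
        raise ValidationError(f"trait {trait!r} lacks HP or LP means")
    wide = wide.dropna(subset=["HP", "LP"])
    delta = wide["HP"] - wide["LP"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * delta / wide["HP"].replace(0.0, np.nan)
    per = pd.DataFrame(
        {
            "genotype_id": wide.index,
            "hp": wide["HP"].to_numpy(),
            "lp": wide["LP"].to_numpy(),
            "delta": delta.to_numpy(),
            "pct_reduction": pct.to_numpy(),
        }
    ).reset_index(drop=True)
    increased = per.loc[per["delta"] < 0, "genotype_id"].tolist()
    hp_mean = float(wide["HP"].mean())
    return ChangeMetrics(
        trait=trait,
        per_genotype=per,
        mean_pct_reduction=float(np.nanmean(per["pct_reduction"])),
        pct_reduction_of_means=100.0 * (hp_mean - float(wide["LP"].mean())) / hp_mean if hp_mean else np.nan,
        n_increased_under_lp=len(increased),
        increased_under_lp=sorted(increased),
    )


def summary_table(table: PhenotypeTable, traits: list[str] | None = None) -> pd.DataFrame:
    """Panel summary per trait: descriptive stats per treatment, ANOVA stars, H2.

    One row per trait with min/mean/max/SD under HP and LP, significance
    stars for the genotype, treatment, block and G x T terms, and H2_bs.
    """
    means = genotype_means(table)
    desc = descriptive_stats(means)
    traits = traits or table.traits
    rows = []
    for trait in traits:
        row: dict = {"trait": trait}
        for treat in ("HP", "LP"):
            d = desc.loc[(desc["trait"] == trait) & (desc["treatment"] == treat)]
            if len(d):
                d = d.iloc[0]
                row.update({f"{c}_{treat}": d[c] for c in ("min", "mean", "max", "sd")})
        try:
            a = anova_two_way(table, trait)
        except ValidationError:
            rows.append(row)
            continue
        terms = a.table.set_index("term")
        row.update(
            {
                "G": significance_stars(terms.loc["genotype", "p"]),
                "T": significance_stars(terms.loc["treatment", "p"]),
                "E": significance_stars(terms.loc["block", "p"]),
                "GxT": significance_stars(terms.loc["gxt", "p"]),
                "H2_bs": variance_components(a).h2_bs,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
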