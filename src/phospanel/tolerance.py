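"""Stress tolerance index (STI) and membership-function value (MFVP).

Per trait j and genotype i with replicate means Y_pi under control (HP) and
Y_si under stress (LP):

    STI_ij = (Y_pi * Y_si) / (mean Y_p)^2

where mean Y_p is the mean HP performance of all genotypes for that trait.
High STI marks genotypes performing well under both conditions.

The composite score min-max rescales each trait's STI and averages:

    U_ij = (STI_ij - STI_jmin) / (STI_jmax - STI_jmin),   U_i = (1/n) sum_j U_ij

U_i in [0, 1] is the membership-function value for P-stress tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ValidationError

logger = logging.getLogger(__name__)

#: Trait set the composite score uses by default: shoot/root/total dry
#: biomass and P uptake.
DEFAULT_MFVP_TRAITS = ("SDW", "RDW", "TotalDW", "Pupt")


@dataclass
class STITable:
    """Per-genotype STI for one trait, with the inputs retained."""

    trait: str
    data: pd.DataFrame          # genotype_id, y_p, y_s, sti
    mean_yp: float
    excluded: list[str] = field(default_factory=list)  # genotypes lacking a treatment


def compute_sti(means: pd.DataFrame, trait: str) -> STITable:
    """STI per genotype for one trait from replicate means.

    mean Y_p is taken over all genotypes with an HP value (not only those
    with complete HP+LP data); genotypes missing either treatment are
    excluded from the scored set and listed in ``excluded``.
    """
    sub = means.loc[means["trait"] == trait]
    wide = sub.pivot_table(index="genotype_id", columns="treatment", values="mean", aggfunc="first")
    if "HP" not in wide.columns:
        raise ValidationError(f"trait {trait!r} has no HP means")
    mean_yp = float(wide["HP"].mean())
    if mean_yp == 0 or not np.isfinite(mean_yp):
        raise ValidationError(f"mean HP performance for trait {trait!r} is zero or undefined")
    complete = wide.dropna(subset=["HP", "LP"]) if "LP" in wide.columns else wide.iloc[0:0]
    excluded = sorted(set(wide.index) - set(complete.index))
    if excluded:
        logger.info("compute_sti(%s): excluded %d genotype(s) missing a treatment", trait, len(excluded))
    data = pd.DataFrame(
        {
            "genotype_id": complete.index,
            "y_p": complete["HP"].to_numpy(),
            "y_s": complete["LP"].to_numpy(),
            "sti": (complete["HP"] * complete["LP"]).to_numpy() / mean_yp**2,
        }
    ).reset_index(drop=True)
    return STITable(trait=trait, data=data, mean_yp=mean_yp, excluded=excluded)


@dataclass
class MFVPTable:
    """Per-trait memberships U_ij and the composite U_i per genotype."""

    data: pd.DataFrame          # genotype_id, U_<trait>..., mfvp
    traits: list[str]           # traits actually averaged
    sti_min: dict[str, float]
    sti_max: dict[str, float]
    dropped_traits: list[str] = field(default_factory=list)  # constant-STI traits


def compute_mfvp(sti_tables: dict[str, STITable], traits: list[str] | None = None) -> MFVPTable:
    """Min-max rescale each trait's STI and average into the composite.

    Works on the intersection of genotypes scored for every trait
    (exclusions logged).  Traits whose STI is constant carry no ranking
    information and are dropped from the average with a warning (n reduced).
    """
    traits = list(traits) if traits is not None else list(sti_tables)
    if not traits:
        raise ValidationError("MFVP needs at least one trait")
    missing = [t for t in traits if t not in sti_tables]
    if missing:
        raise ValidationError(f"no STI table for trait(s) {missing}")

    common: set[str] | None = None
    for t in traits:
        genos = set(sti_tables[t].data["genotype_id"])
        common = genos if common is None else common & genos
    if not common:
        raise ValidationError("empty genotype intersection across STI tables")
    all_genos = set().union(*(set(sti_tables[t].data["genotype_id"]) for t in traits))
    if all_genos - common:
        logger.info("compute_mfvp: %d genotype(s) dropped from intersection", len(all_genos - common))
    index = sorted(common)

    u_cols = {}
    sti_min: dict[str, float] = {}
    sti_max: dict[str, float] = {}
    dropped = []
    for t in traits:
        s = sti_tables[t].data.set_index("genotype_id")["sti"].loc[index]
        lo, hi = float(s.min()), float(s.max())
        sti_min[t], sti_max[t] = lo, hi
        if hi == lo:
            dropped.append(t)
            logger.warning("compute_mfvp: trait %s has constant STI; dropped from the average", t)
            continue
        u_cols[t] = (s - lo) / (hi - lo)
    used = [t for t in traits if t not in dropped]
    if not used:
        raise ValidationError("all traits have constant STI; MFVP undefined")

    out = pd.DataFrame({"genotype_id": index})
    for t in used:
        out[f"U_{t}"] = u_cols[t].to_numpy()
    out["mfvp"] = out[[f"U_{t}" for t in used]].mean(axis=1)
    return MFVPTable(
        data=out, traits=used, sti_min=sti_min, sti_max=sti_max, dropped_traits=dropped
    )


def rank_select(mfvp: MFVPTable, k: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k and bottom-k genotypes by composite score.

    Sort is descending by score with ties broken by genotype_id
    (lexicographic), so output is deterministic across runs.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    n = len(mfvp.data)
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} scored genotypes")
    ranked = mfvp.data.sort_values(
        ["mfvp", "genotype_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, n + 1)
    top = ranked.head(k).copy()
    bottom = ranked.tail(k).sort_values("rank", ascending=False).reset_index(drop=True)
    return top, bottom
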