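"""Z-score standardization, hierarchical clustering of genotype trait
profiles, sub-cluster mean tables, and best/intermediate/worst classes.

Genotypes are clustered on their standardized (trait, treatment) mean
profiles - by default {SDW, RDW, TotalDW, Pupt} x {HP, LP} - using
agglomerative clustering on Euclidean distances.  Cutting the tree at
k_main (default 2) and k_sub (default 9) yields main and sub-cluster
assignments; sub-clusters are then ranked on their average trait rank and
split into terciles to label the best, intermediate and worst performers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_TRAITS = ("SDW", "RDW", "TotalDW", "Pupt")


@dataclass
class StandardizedTraitMatrix:
    """Genotypes x (trait, treatment) z-score matrix.

    Column stats (pre-scaling mean/SD) are retained; constant columns are
    set to zero, missing cells are imputed with the column mean before
    scaling (counts logged).
    """

    data: pd.DataFrame                 # index genotype_id, columns "TRAIT_TREATMENT"
    column_stats: pd.DataFrame         # column, mean, sd, n_imputed, constant
    n_imputed: int = 0


def standardize(
    means: pd.DataFrame,
    traits: tuple[str, ...] = DEFAULT_CLUSTER_TRAITS,
    treatments: tuple[str, ...] = ("HP", "LP"),
) -> StandardizedTraitMatrix:
    """Column-wise z-scores (sample SD) of the genotype x trait-mean matrix."""
    sub = means.loc[means["trait"].isin(traits) & means["treatment"].isin(treatments)]
    if sub.empty:
        raise ValidationError("no trait means selected for standardization")
    wide = sub.pivot_table(index="genotype_id", columns=["trait", "treatment"], values="mean", aggfunc="first")
    wide.columns = [f"{t}_{tr}" for t, tr in wide.columns]
    ordered = [f"{t}_{tr}" for t in traits for tr in treatments if f"{t}_{tr}" in wide.columns]
    wide = wide.loc[:, ordered]

    stats_rows = []
    total_imputed = 0
    for col in wide.columns:
        x = wide[col]
        n_missing = int(x.isna().sum())
        if n_missing:
            x = x.fillna(x.mean())
            total_imputed += n_missing
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        constant = not np.isfinite(sd) or sd == 0
        if constant:
            logger.warning("standardize: column %s is constant; set to all-zero", col)
            wide[col] = 0.0
        else:
            wide[col] = (x - mu) / sd
        stats_rows.append({"column": col, "mean": mu, "sd": sd, "n_imputed": n_missing, "constant": constant})
    if total_imputed:
        logger.info("standardize: imputed %d missing cell(s) with column means", total_imputed)
    return StandardizedTraitMatrix(
        data=wide, column_stats=pd.DataFrame(stats_rows), n_imputed=total_imputed
    )


@dataclass
class ClusterAssignment:
    """Main/sub-cluster labels per genotype plus the linkage tree."""

    data: pd.DataFrame          # genotype_id, main_cluster, sub_cluster
    linkage_matrix: np.ndarray
    linkage_method: str
    k_main: int
    k_sub: int


def _relabel_by_leaf_order(labels: np.ndarray, leaf_order: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k in order of first appearance along the
    dendrogram leaves, so label numbering is reproducible."""
    mapping: dict[int, int] = {}
    for leaf in leaf_order:
        lab = labels[leaf]
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[l] for l in labels])


def cluster_genotypes(
    z: StandardizedTraitMatrix,
    linkage: str = "complete",
    k_main: int = 2,
    k_sub: int = 9,
) -> ClusterAssignment:
    """Agglomerative clustering on Euclidean distances; cut at two levels.

    Default linkage is "complete"; assignments are deterministic given the
    input (SciPy's merge order breaks distance ties by candidate index).
    """
    n = len(z.data)
    if k_sub > n:
        raise ValidationError(f"k_sub={k_sub} exceeds {n} genotypes")
    if k_main > k_sub:
        raise ValidationError("k_main must be <= k_sub")
    lm = hierarchy.linkage(pdist(z.data.to_numpy(), metric="euclidean"), method=linkage)
    leaf_order = hierarchy.leaves_list(lm)
    main = hierarchy.fcluster(lm, t=k_main, criterion="maxclust")
    sub = hierarchy.fcluster(lm, t=k_sub, criterion="maxclust")
    data = pd.DataFrame(
        {
            "genotype_id": z.data.index,
            "main_cluster": _relabel_by_leaf_order(main, leaf_order),
            "sub_cluster": _relabel_by_leaf_order(sub, leaf_order),
        }
    ).reset_index(drop=True)
    return ClusterAssignment(data=data, linkage_matrix=lm, linkage_method=linkage, k_main=k_main, k_sub=k_sub)


@dataclass
class ClusterMeans:
    """Per-sub-cluster trait means with performance classes."""

    table: pd.DataFrame     # sub_cluster, n, <trait_treatment means...>, avg_rank, performance_class
    classes: dict[int, str] = field(default_factory=dict)


def cluster_means(
    assignment: ClusterAssignment,
    means: pd.DataFrame,
    traits: tuple[str, ...] = DEFAULT_CLUSTER_TRAITS,
    treatments: tuple[str, ...] = ("HP", "LP"),
) -> ClusterMeans:
    """Sub-cluster mean per (trait, treatment) and tercile performance class.

    Each sub-cluster is ranked within every column (1 = lowest mean); the
    average rank across columns is split into terciles: top third = "best",
    bottom third = "worst", middle = "intermediate".  A single cluster is
    "intermediate" by convention.  Empty clusters are excluded with a
    warning.
    """
    sub = means.loc[means["trait"].isin(traits) & means["treatment"].isin(treatments)]
    merged = sub.merge(assignment.data[["genotype_id", "sub_cluster"]], on="genotype_id", how="inner")
    if merged.empty:
        raise ValidationError("assignments do not cover the trait-mean genotypes")
    n_per = assignment.data.groupby("sub_cluster")["genotype_id"].count()
    covered = set(merged["sub_cluster"].unique())
    for c in n_per.index:
        if c not in covered:
            logger.warning("cluster_means: sub-cluster %s has no trait means; excluded", c)

    prof = merged.pivot_table(index="sub_cluster", columns=["trait", "treatment"], values="mean", aggfunc="mean")
    prof.columns = [f"{t}_{tr}" for t, tr in prof.columns]
    ranks = prof.rank(axis=0, method="average")
    avg_rank = ranks.mean(axis=1)

    k = len(prof)
    classes: dict[int, str] = {}
    if k == 1:
        classes[int(prof.index[0])] = "intermediate"
    else:
        order = list(avg_rank.sort_values(ascending=False, kind="mergesort").index)  # best first
        n_edge = max(1, round(k / 3))  # top/bottom tercile size, never empty
        for c in order[:n_edge]:
            classes[int(c)] = "best"
        for c in order[k - n_edge:]:
            classes[int(c)] = "worst"
        for c in order[n_edge:k - n_edge]:
            classes[int(c)] = "intermediate"

    out = prof.copy()
    out.insert(0, "n", n_per.reindex(prof.index).to_numpy())
    out["avg_rank"] = avg_rank
    out["performance_class"] = [classes[int(c)] for c in out.index]
    out = out.reset_index()
    return ClusterMeans(table=out, classes=classes)


def genotype_performance_classes(assignment: ClusterAssignment, cm: ClusterMeans) -> pd.DataFrame:
    """Propagate sub-cluster performance classes to genotypes."""
    out = assignment.data.copy()
    out["performance_class"] = out["sub_cluster"].map(lambda c: cm.classes.get(int(c), "intermediate"))
    return out
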