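#!/usr/bin/env python
"""Performance clustering: z-score standardization of the genotype x
(trait, treatment) mean matrix, hierarchical clustering into 2 main and 9
sub-clusters, per-cluster trait means, and best/intermediate/worst classes.

Reads scratch/panel/; writes assignments and cluster-mean tables under
results/.
"""

from pathlib import Path

from phospanel.cluster_profiles import (
    DEFAULT_CLUSTER_TRAITS,
    cluster_genotypes,
    cluster_means,
    genotype_performance_classes,
    standardize,
)
from phospanel.io_formats import read_phenotype_table, write_table
from phospanel.phenostats import derive_traits, genotype_means

RESULTS = Path("results")


def main() -> None:
    table = derive_traits(read_phenotype_table("scratch/panel/phenotypes.csv"))
    means = genotype_means(table)

    z = standardize(means, traits=DEFAULT_CLUSTER_TRAITS)
    assignment = cluster_genotypes(z, linkage="complete", k_main=2, k_sub=9)
    cm = cluster_means(assignment, means, traits=DEFAULT_CLUSTER_TRAITS)
    classes = genotype_performance_classes(assignment, cm)

    write_table(classes, RESULTS / "04_cluster_assignments.tsv")
    write_table(cm.table.round(3), RESULTS / "04_cluster_means.tsv")

    sizes = classes.groupby("main_cluster")["genotype_id"].count()
    print(f"2 main clusters of {sizes.tolist()} genotypes; 9 sub-clusters")
    for cls in ("best", "intermediate", "worst"):
        subs = sorted(c for c, lab in cm.classes.items() if lab == cls)
        print(f"  {cls:>12}: sub-clusters {subs}")
    print(f"tables -> {RESULTS}/04_*.tsv")


if __name__ == "__main__":
    main()
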