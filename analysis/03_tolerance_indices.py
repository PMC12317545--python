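#!/usr/bin/env python
"""P-stress tolerance scoring: per-trait stress tolerance indices (STI) for
shoot/root/total dry biomass and P uptake, the composite membership-function
value (MFVP), and the 20 most / least tolerant genotypes.

Reads scratch/panel/; writes the score and ranking tables under results/.
"""

from pathlib import Path

from phospanel.io_formats import read_phenotype_table, write_table
from phospanel.phenostats import derive_traits, genotype_means
from phospanel.tolerance import DEFAULT_MFVP_TRAITS, compute_mfvp, compute_sti, rank_select

RESULTS = Path("results")


def main() -> None:
    table = derive_traits(read_phenotype_table("scratch/panel/phenotypes.csv"))
    means = genotype_means(table)

    sti_tables = {t: compute_sti(means, t) for t in DEFAULT_MFVP_TRAITS}
    mfvp = compute_mfvp(sti_tables, list(DEFAULT_MFVP_TRAITS))
    top, bottom = rank_select(mfvp, 20)

    scores = mfvp.data.copy()
    for t, st in sti_tables.items():
        scores[f"STI_{t}"] = scores["genotype_id"].map(st.data.set_index("genotype_id")["sti"])
    write_table(scores.round(4), RESULTS / "03_tolerance_scores.tsv")
    write_table(top.round(4), RESULTS / "03_top20_tolerant.tsv")
    write_table(bottom.round(4), RESULTS / "03_bottom20_tolerant.tsv")

    pupt = sti_tables["Pupt"].data["sti"]
    print(f"STI(Pupt) range {pupt.min():.2f}-{pupt.max():.2f}; "
          f"MFVP range {mfvp.data['mfvp'].min():.2f}-{mfvp.data['mfvp'].max():.2f} "
          f"over {len(mfvp.data)} genotypes")
    print(f"most tolerant: {top.iloc[0]['genotype_id']} (MFVP {top.iloc[0]['mfvp']:.2f}); "
          f"least: {bottom.iloc[0]['genotype_id']} (MFVP {bottom.iloc[0]['mfvp']:.2f})")
    print(f"tables -> {RESULTS}/03_*.tsv")


if __name__ == "__main__":
    main()
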