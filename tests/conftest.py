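"""Shared fixtures: small hand-built tables and a simulated panel."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phospanel.containers import GenotypeMatrix, PhenotypeTable
from phospanel.phenostats import derive_traits, genotype_means
from phospanel.simulate import PhenoSimConfig, simulate_phenotypes


def make_phenotypes(rows: list[tuple]) -> PhenotypeTable:
    """rows of (genotype_id, treatment, replicate, trait, value)."""
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["genotype_id", "treatment", "replicate", "trait", "value"])
    )


@pytest.fixture(scope="session")
def sim_panel() -> tuple[PhenotypeTable, pd.DataFrame]:
    """A 60-genotype simulated panel with derived traits and its means."""
    table, _ = simulate_phenotypes(PhenoSimConfig(n_genotypes=60, seed=11))
    table = derive_traits(table)
    return table, genotype_means(table)


def make_genotypes(dosage: np.ndarray, chrom: str = "chr01") -> GenotypeMatrix:
    """Wrap a dosage array (samples x markers) with a synthetic marker map."""
    n, m = dosage.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"snp{j:03d}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"S{i:03d}" for i in range(n)], markers=markers, dosage=np.asarray(dosage, float)
    )


def anova_enumeration_oracle(df: pd.DataFrame) -> dict[str, float]:
    """Explicit sum-of-squares partition by direct enumeration.

    Independent of the implementation: loops over factor levels and
    accumulates squared deviations term by term.  Expects a balanced frame
    with columns genotype_id / treatment / replicate / value.
    """
    genos = sorted(df["genotype_id"].unique())
    treats = sorted(df["treatment"].unique())
    reps = sorted(df["replicate"].unique())
    grand = df["value"].mean()

    def level_mean(col, level):
        return df.loc[df[col] == level, "value"].mean()

    ss_g = len(treats) * len(reps) * sum((level_mean("genotype_id", g) - grand) ** 2 for g in genos)
    ss_t = len(genos) * len(reps) * sum((level_mean("treatment", t) - grand) ** 2 for t in treats)
    ss_e = len(genos) * len(treats) * sum((level_mean("replicate", r) - grand) ** 2 for r in reps)
    ss_gt = 0.0
    for g in genos:
        for t in treats:
            cell = df.loc[(df["genotype_id"] == g) & (df["treatment"] == t), "value"].mean()
            ss_gt += len(reps) * (cell - level_mean("genotype_id", g) - level_mean("treatment", t) + grand) ** 2
    ss_total = float(((df["value"] - grand) ** 2).sum())
    return {
        "genotype": ss_g,
        "treatment": ss_t,
        "block": ss_e,
        "gxt": ss_gt,
        "residual": ss_total - ss_g - ss_t - ss_e - ss_gt,
        "total": ss_total,
    }


def random_balanced_frame(rng: np.random.Generator, n_g=3, n_t=2, n_r=2) -> pd.DataFrame:
    rows = []
    for g in range(n_g):
        for t, treat in enumerate(["HP", "LP"][:n_t]):
            for r in range(n_r):
                rows.append((f"G{g}", treat, r + 1, "SDW", 5.0 + rng.normal()))
    return pd.DataFrame(rows, columns=["genotype_id", "treatment", "replicate", "trait", "value"])
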