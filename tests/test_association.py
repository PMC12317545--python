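"""Marker QC, imputation, PCA covariates, the least-squares scan (vs a
closed-form oracle), Bonferroni control, PVE, and gene-window queries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phospanel.association import (
    apply_bonferroni,
    candidate_genes,
    compute_pve,
    glm_scan,
    impute_mean,
    marker_qc,
    pca_covariates,
    SignificanceRule,
)
from phospanel.containers import GeneAnnotationSet, ValidationError
from phospanel.simulate import GenoSimConfig, simulate_genotypes

from conftest import make_genotypes


class TestMarkerQC:
    def test_low_call_rate_removed(self):
        # 2/10 missing -> call rate 0.80 < 0.85
        col = np.array([0, 1, 2, 1, 0, 1, 2, 1, np.nan, np.nan])
        good = np.tile([0, 1, 2, 1, 0], 2).astype(float)
        g = make_genotypes(np.column_stack([col, good]))
        kept, rep = marker_qc(g)
        assert rep.removed_call_rate == 1
        assert kept.markers["marker_id"].tolist() == ["snp001"]

    def test_monomorphic_removed_by_maf(self):
        mono = np.zeros(10)
        good = np.tile([0, 1, 2, 1, 0], 2).astype(float)
        g = make_genotypes(np.column_stack([mono, good]))
        kept, rep = marker_qc(g)
        assert rep.removed_maf == 1
        assert kept.n_markers == 1

    def test_boundary_markers_kept_hand_enumeration(self):
        # 10 samples; thresholds are strict ("lower than"), so markers at
        # exactly 0.85 call rate or exactly 0.05 MAF stay.
        n = 20
        cols = {
            # call rate exactly 0.85 (17/20), MAF fine
            "at_call": np.array([np.nan] * 3 + [0, 1, 2, 1] * 4 + [1]),
            # call rate 0.80 -> removed by call-rate filter
            "below_call": np.array([np.nan] * 4 + [0, 1, 2, 1] * 4),
            # MAF exactly 0.05: 2 alt alleles in 40 -> kept
            "at_maf": np.array([1, 1] + [0] * 18, dtype=float),
            # MAF 0.025 -> removed by MAF filter
            "below_maf": np.array([1] + [0] * 19, dtype=float),
            # also below call rate AND monomorphic: counted once, at call-rate stage
            "both": np.array([np.nan] * 4 + [0] * 16),
            "clean": np.tile([0, 1, 2, 1], 5).astype(float),
        }
        g = make_genotypes(np.column_stack(list(cols.values())))
        id_of = dict(zip(g.markers["marker_id"], cols.keys()))
        kept, rep = marker_qc(g)
        kept_names = {id_of[m] for m in kept.markers["marker_id"]}
        assert kept_names == {"at_call", "at_maf", "clean"}
        assert rep.removed_call_rate == 2  # below_call, both
        assert rep.removed_maf == 1        # below_maf
        assert rep.markers_in == 6 and rep.markers_out == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_reconcile_on_random_input(self, seed):
        g, _ = simulate_genotypes(GenoSimConfig(n_samples=40, n_markers=150, missing_rate=0.2, seed=seed))
        _, rep = marker_qc(g)
        assert rep.markers_in == rep.markers_out + rep.removed_call_rate + rep.removed_maf

    def test_all_markers_removed_is_an_error(self):
        g = make_genotypes(np.zeros((10, 3)))
        with pytest.raises(ValidationError):
            marker_qc(g)


class TestImputeMean:
    def test_hand_value(self):
        g = make_genotypes(np.array([[0.0], [2.0], [np.nan]]))
        out = impute_mean(g)
        assert out.dosage[2, 0] == pytest.approx(1.0)

    def test_no_missing_is_identity(self):
        x = np.tile([0.0, 1.0, 2.0], (4, 1))
        out = impute_mean(make_genotypes(x))
        assert np.array_equal(out.dosage, x)

    def test_column_means_preserved(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, size=(200, 500)).astype(float)
        x[rng.random(x.shape) < 0.05] = np.nan
        before = np.nanmean(x, axis=0)
        out = impute_mean(make_genotypes(x))
        assert np.isfinite(out.dosage).all()
        assert np.allclose(out.dosage.mean(axis=0), before)


class TestPCACovariates:
    def test_separated_subpopulations_split_on_pc1(self):
        g, truth = simulate_genotypes(
            GenoSimConfig(n_samples=80, n_markers=600, n_subpopulations=2,
                          divergence_f=0.4, missing_rate=0.0, seed=4)
        )
        scores, _ = pca_covariates(g, n_pc=2)
        signs = np.sign(scores[:, 0])
        # PC1 sign should separate the two subpopulations almost perfectly
        agreement = max(
            (signs[truth.subpopulation == 0] > 0).mean() + (signs[truth.subpopulation == 1] < 0).mean(),
            (signs[truth.subpopulation == 0] < 0).mean() + (signs[truth.subpopulation == 1] > 0).mean(),
        ) / 2
        assert agreement > 0.95

    def test_rank_one_matrix_pc1_explains_everything(self):
        u = np.arange(10, dtype=float)[:, None]
        v = np.array([[1.0, 2.0, 0.5]])
        g = make_genotypes(np.clip(u @ v / 10, 0, 2))
        _, evr = pca_covariates(g, n_pc=1)
        assert evr[0] == pytest.approx(1.0)

    def test_variance_fractions_sorted_and_bounded(self):
        g, _ = simulate_genotypes(GenoSimConfig(n_samples=50, n_markers=300, missing_rate=0.0, seed=9))
        _, evr = pca_covariates(g, n_pc=5)
        assert evr.sum() <= 1 + 1e-12
        assert (np.diff(evr) <= 1e-12).all()


class TestGlmScan:
    def test_matches_closed_form_simple_regression(self):
        # 10-sample hand dataset, no covariates: beta and SE must equal the
        # textbook least-squares formulas.
        x = np.array([0, 1, 2, 1, 0, 2, 1, 0, 1, 2], dtype=float)
        y = np.array([1.0, 1.5, 2.9, 1.7, 0.8, 3.2, 1.4, 1.1, 1.6, 2.8])
        g = make_genotypes(x[:, None])
        rec = glm_scan(g, y).iloc[0]
        sxx = ((x - x.mean()) ** 2).sum()
        beta = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - y.mean() - beta * (x - x.mean())
        se = np.sqrt((resid**2).sum() / (len(x) - 2) / sxx)
        assert rec["beta"] == pytest.approx(beta)
        assert rec["se"] == pytest.approx(se)
        from scipy import stats

        assert rec["p"] == pytest.approx(2 * stats.t.sf(abs(beta / se), len(x) - 2))

    def test_constant_phenotype_gives_zero_effect(self):
        g, _ = simulate_genotypes(GenoSimConfig(n_samples=30, n_markers=40, missing_rate=0.0, seed=2))
        rec = glm_scan(g, np.full(30, 2.5))
        ok = rec.loc[~rec["degenerate"]]
        assert len(ok) > 30
        assert np.allclose(ok["beta"], 0.0)

    def test_constant_marker_flagged_degenerate(self):
        x = np.column_stack([np.ones(12), np.tile([0, 1, 2], 4)])
        rec = glm_scan(make_genotypes(x), np.random.default_rng(0).normal(size=12))
        assert bool(rec.loc[0, "degenerate"])
        assert np.isnan(rec.loc[0, "p"])
        assert not rec.loc[1, "degenerate"]

    def test_sample_permutation_invariance(self):
        g, _ = simulate_genotypes(GenoSimConfig(n_samples=40, n_markers=60, missing_rate=0.0, seed=7))
        y = np.random.default_rng(1).normal(size=40)
        scores, _ = pca_covariates(g, n_pc=2)
        rec1 = glm_scan(g, y, covariates=scores)
        perm = np.random.default_rng(2).permutation(40)
        import dataclasses

        g2 = dataclasses.replace(
            g, sample_ids=[g.sample_ids[i] for i in perm], dosage=g.dosage[perm]
        )
        rec2 = glm_scan(g2, y[perm], covariates=scores[perm])
        assert np.allclose(rec1["beta"], rec2["beta"])
        assert np.allclose(rec1["p"], rec2["p"], equal_nan=True)

    def test_misaligned_phenotype_rejected(self):
        g, _ = simulate_genotypes(GenoSimConfig(n_samples=10, n_markers=5, missing_rate=0.0, seed=1))
        with pytest.raises(ValidationError, match="aligned"):
            glm_scan(g, np.ones(9))


class TestBonferroni:
    def test_threshold_matches_printed_expression(self):
        rule = SignificanceRule(alpha=0.05, n_tests=4796)
        assert rule.threshold_neglog10p == pytest.approx(-np.log10(0.05 / 4796))
        assert rule.threshold_neglog10p == pytest.approx(4.982, abs=5e-4)

    def test_boundary_p_not_significant(self):
        rec = pd.DataFrame({"p": [0.05 / 10, 0.049 / 10] + [0.5] * 8})
        out, rule = apply_bonferroni(rec, alpha=0.05)
        assert rule.n_tests == 10
        assert not out.loc[0, "significant"]  # p == alpha/M exactly
        assert out.loc[1, "significant"]

    def test_doubling_m_never_creates_significance(self):
        rng = np.random.default_rng(12)
        p = rng.random(50)
        small, _ = apply_bonferroni(pd.DataFrame({"p": p}))
        big, _ = apply_bonferroni(pd.DataFrame({"p": np.concatenate([p, rng.random(50)])}))
        gained = ~small["significant"].to_numpy() & big["significant"].to_numpy()[:50]
        assert not gained.any()

    def test_missing_p_excluded_from_m(self):
        rec = pd.DataFrame({"p": [0.001, np.nan, 0.5]})
        out, rule = apply_bonferroni(rec)
        assert rule.n_tests == 2
        assert not out.loc[1, "significant"]


class TestPVE:
    def test_zero_effect_gives_zero(self):
        assert compute_pve(0.0, 0.1, 0.3, 100, "shim") == 0.0
        assert compute_pve(0.0, 0.1, 0.3, 100, "as_printed") == 0.0

    def test_hand_arithmetic_both_variants(self):
        # beta=1, SE=0.1, f=0.5, N=200: shim 0.5/1.5, as-printed 0.5/2.0
        assert compute_pve(1.0, 0.1, 0.5, 200, "shim") == pytest.approx(1 / 3)
        assert compute_pve(1.0, 0.1, 0.5, 200, "as_printed") == pytest.approx(0.25)

    def test_monotonic_in_effect_size(self):
        betas = np.linspace(0.05, 2.0, 30)
        for variant in ("shim", "as_printed"):
            pve = compute_pve(betas, 0.2, 0.3, 150, variant)
            assert (np.diff(pve) > 0).all()

    @given(
        beta=st.floats(-3, 3), se=st.floats(0.01, 2), maf=st.floats(0.01, 0.5),
        n=st.integers(10, 1000),
    )
    @settings(max_examples=200, deadline=None)
    def test_shim_reduces_to_maf_free_identity(self, beta, se, maf, n):
        # the f(1-f) factor cancels: PVE_shim = b^2 / (b^2 + N SE^2); both
        # variants stay in [0, 1].
        shim = compute_pve(beta, se, maf, n, "shim")
        assert shim == pytest.approx(beta**2 / (beta**2 + n * se**2), rel=1e-9)
        printed = compute_pve(beta, se, maf, n, "as_printed")
        assert 0.0 <= shim <= 1.0 and 0.0 <= printed <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            compute_pve(1.0, 0.1, 0.0, 100)
        with pytest.raises(ValidationError):
            compute_pve(1.0, 0.1, 0.6, 100)
        with pytest.raises(ValidationError):
            compute_pve(1.0, 0.0, 0.3, 100)


def genes_from(rows):
    return GeneAnnotationSet(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "description"])
    )


class TestCandidateGenes:
    MARKER = {"marker_id": "m1", "chrom": "chr01", "pos": 2_000_000}

    def test_window_interval_arithmetic(self):
        genes = genes_from(
            [
                ("outside_left", "chr01", 900_000, 950_000, ""),    # end < pos - 1 Mb
                ("inside_window", "chr01", 1_050_000, 1_060_000, ""),
                ("other_chrom", "chr02", 1_500_000, 1_600_000, ""),
            ]
        )
        hit = candidate_genes(self.MARKER, genes)
        assert hit["gene_id"].tolist() == ["inside_window"]
        assert hit.loc[0, "distance"] == 2_000_000 - 1_060_000

    def test_boundary_overlap_inclusive(self):
        genes = genes_from(
            [
                ("ends_at_edge", "chr01", 990_000, 1_000_000, ""),   # end == pos - window
                ("starts_at_edge", "chr01", 3_000_000, 3_100_000, ""),  # start == pos + window
            ]
        )
        hit = candidate_genes(self.MARKER, genes)
        assert hit["gene_id"].tolist() == ["ends_at_edge", "starts_at_edge"]

    def test_spanning_gene_distance_zero_first(self):
        genes = genes_from(
            [
                ("nearby", "chr01", 2_100_000, 2_200_000, ""),
                ("spanning", "chr01", 1_900_000, 2_100_000, ""),
            ]
        )
        hit = candidate_genes(self.MARKER, genes)
        assert hit.loc[0, "gene_id"] == "spanning"
        assert hit.loc[0, "distance"] == 0

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(33)
        rows = []
        for i in range(1000):
            chrom = f"chr{rng.integers(1, 4):02d}"
            start = int(rng.integers(1, 10_000_000))
            rows.append((f"gene{i:04d}", chrom, start, start + int(rng.integers(100, 50_000)), ""))
        genes = genes_from(rows)
        marker = {"marker_id": "m", "chrom": "chr02", "pos": 5_000_000}
        hit = set(candidate_genes(marker, genes, window_bp=1_000_000)["gene_id"])
        lo, hi = 4_000_000, 6_000_000
        brute = {
            gid for gid, chrom, start, end, _ in rows
            if chrom == "chr02" and end >= lo and start <= hi
        }
        assert hit == brute

    def test_empty_result_allowed(self):
        genes = genes_from([("far", "chr05", 1, 100, "")])
        assert len(candidate_genes(self.MARKER, genes)) == 0
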