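"""Marker preprocessing, heritability, linkage statistics, permutation
p-values, FDR, cis/trans classification, and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from aspnet.containers import EqtlHit
from aspnet.qtl import (
    T_DEGENERATE,
    DegenerateGroupWarning,
    benjamini_hochberg,
    classify_cis_trans,
    estimate_heritability,
    knn_impute_expression,
    linkage_t,
    map_qtls,
    merge_identical_markers,
)
from conftest import make_genotypes


class TestMergeIdenticalMarkers:
    def test_adjacent_identical_run_collapses(self):
        geno = make_genotypes([[0, 1, 0], [0, 1, 0], [0, 1, 0], [1, 1, 0]])
        merged, mmap = merge_identical_markers(geno)
        assert list(merged.markers) == ["m1", "m4"]
        assert mmap["m1"] == ["m1", "m2", "m3"]

    def test_identical_on_different_chromosomes_not_merged(self):
        geno = make_genotypes([[0, 1], [0, 1]], chroms=["chr1", "chr2"])
        merged, _ = merge_identical_markers(geno)
        assert len(merged.markers) == 2

    def test_non_adjacent_duplicates_not_merged(self):
        geno = make_genotypes([[0, 1], [1, 0], [0, 1]])
        merged, _ = merge_identical_markers(geno)
        assert len(merged.markers) == 3

    def test_matches_run_length_oracle_on_simulated_panel(self, small_dataset):
        geno = small_dataset[0]
        merged, mmap = merge_identical_markers(geno)
        # independent run-length scan
        arr = geno.calls.to_numpy()
        chroms = geno.marker_map["chromosome"].to_numpy()
        runs = 1
        for i in range(1, len(arr)):
            if chroms[i] != chroms[i - 1] or not np.array_equal(arr[i], arr[i - 1]):
                runs += 1
        assert len(merged.markers) == runs
        # merge map inverts the merge
        expanded = [m for rep in merged.markers for m in mmap[rep]]
        assert expanded == list(geno.markers)


class TestHeritability:
    def test_constant_parents_give_h2_one(self):
        rec = estimate_heritability([1, 2, 3, 4], {"A": [2, 2], "B": [3, 3]},
                                    n_perm=50, seed=0)
        assert rec.h2 == pytest.approx(1.0)

    def test_equal_variances_give_h2_zero(self):
        seg = [1.0, 2.0, 3.0]  # var 1
        rec = estimate_heritability(seg, {"A": [0, 1, 2], "B": [5, 6, 7]},
                                    n_perm=50, seed=0)
        assert rec.h2 == pytest.approx(0.0)

    def test_hand_computed_oracle(self):
        # seg var = 5/3; parent vars = 2 and 2, pooled (df-weighted) = 2
        rec = estimate_heritability([1, 2, 3, 4], {"A": [1, 3], "B": [2, 4]},
                                    n_perm=50, seed=0)
        s2_seg = np.var([1, 2, 3, 4], ddof=1)
        assert rec.sigma2_seg == pytest.approx(s2_seg)
        assert rec.sigma2_parent_pooled == pytest.approx(2.0)
        assert rec.h2 == pytest.approx((s2_seg - 2.0) / s2_seg)

    def test_zero_segregant_variance_flagged_not_raised(self):
        rec = estimate_heritability([2, 2, 2], {"A": [1, 2], "B": [3, 4]},
                                    n_perm=10, seed=0)
        assert not rec.defined

    def test_strong_signal_has_small_permutation_p(self):
        rng = np.random.default_rng(1)
        seg = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 20)])
        rec = estimate_heritability(seg, {"A": rng.normal(0, 0.1, 4),
                                          "B": rng.normal(5, 0.1, 4)},
                                    n_perm=200, seed=2)
        assert rec.p_perm < 0.05


class TestLinkageT:
    def test_equal_means_give_zero(self):
        assert linkage_t([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1]) == 0.0

    def test_textbook_pooled_variance_value(self):
        t = linkage_t([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        # pooled s^2 = 1, t = 3 / sqrt(2/3)
        assert t == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert t == pytest.approx(3.674, abs=1e-3)
        # agrees with the standard equal-variance t-test
        ref = stats.ttest_ind([4, 5, 6], [1, 2, 3], equal_var=True).statistic
        assert t == pytest.approx(ref)

    def test_sign_follows_group1_minus_group0(self):
        assert linkage_t([5, 5, 5, 1, 1, 2], [0, 0, 0, 1, 1, 1]) < 0

    def test_monomorphic_marker_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            linkage_t([1, 2, 3], [0, 0, 0])

    def test_degenerate_variance_returns_large_finite_with_warning(self):
        with pytest.warns(DegenerateGroupWarning):
            t = linkage_t([1, 1, 2, 2], [0, 0, 1, 1])
        assert np.isfinite(t) and abs(t) == T_DEGENERATE

    def test_label_permutation_leaves_abs_t_distribution_invariant(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        g = np.array([0] * 10 + [1] * 10)
        t_obs = abs(linkage_t(y, g))
        perms = [abs(linkage_t(y, rng.permutation(g))) for _ in range(500)]
        # observed |t| is a typical draw from the permutation distribution
        rank = np.mean([p >= t_obs for p in perms])
        assert 0.01 < rank < 1.0


class TestMapQtls:
    def test_observed_beyond_all_nulls_gives_p_zero(self):
        rng = np.random.default_rng(4)
        g = np.tile([0, 1], 20)
        geno = make_genotypes(g.reshape(1, -1))
        y = g * 10.0 + rng.normal(0, 0.01, 40)
        traits = pd.DataFrame([y], index=["t1"], columns=geno.strains)
        hits, table = map_qtls(geno, traits, n_perm=100, seed=5, return_all=True)
        assert table["p_perm"].iloc[0] == 0.0
        assert len(hits) == 1

    def test_converges_to_analytic_t_test(self):
        """Large permutation counts recover the two-sided t-test p-value."""
        rng = np.random.default_rng(6)
        g = np.array([0] * 15 + [1] * 15)
        geno = make_genotypes(g.reshape(1, -1))
        y = g * 1.2 + rng.normal(0, 1, 30)
        traits = pd.DataFrame([y], index=["t1"], columns=geno.strains)
        _, table = map_qtls(geno, traits, n_perm=100_000, seed=7, return_all=True)
        p_perm = table["p_perm"].iloc[0]
        p_exact = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True).pvalue
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 100_000)
        assert abs(p_perm - p_exact) < max(2 * mc_se, 5e-3)

    def test_null_p_values_superuniform(self):
        """Under the global null, permutation p-values are (super-)uniform."""
        rng = np.random.default_rng(8)
        G = rng.integers(0, 2, size=(20, 50))
        geno = make_genotypes(G)
        traits = pd.DataFrame(rng.normal(size=(10, 50)),
                              index=[f"t{i}" for i in range(10)],
                              columns=geno.strains)
        _, table = map_qtls(geno, traits, n_perm=200, seed=9, return_all=True)
        frac = (table["p_perm"] < 0.05).mean()
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(table))

    def test_rejects_bad_n_perm(self):
        geno = make_genotypes(np.tile([0, 1], 5).reshape(1, -1))
        traits = pd.DataFrame(np.zeros((1, 10)), index=["t1"],
                              columns=geno.strains)
        with pytest.raises(ValueError):
            map_qtls(geno, traits, n_perm=0)


class TestCisTrans:
    @staticmethod
    def _setup(marker_pos, gene_start, gene_end, same_chrom=True):
        mmap = pd.DataFrame({"chromosome": ["chr1"], "position": [marker_pos]},
                            index=["m1"])
        gpos = pd.DataFrame(
            {"chromosome": ["chr1" if same_chrom else "chr2"],
             "start": [gene_start], "end": [gene_end]}, index=["g1"])
        hit = EqtlHit("m1", "g1", 5.0, 0.001, 0.01)
        return classify_cis_trans([hit], mmap, gpos)[0].cis

    def test_marker_inside_gene_is_cis(self):
        assert self._setup(5000, 4000, 6000) == "cis"

    def test_boundary_10000_is_cis_10001_is_trans(self):
        assert self._setup(16_000, 1000, 6000) == "cis"  # exactly 10 kb
        assert self._setup(16_001, 1000, 6000) == "trans"

    def test_different_chromosome_is_trans(self):
        assert self._setup(5000, 4000, 6000, same_chrom=False) == "trans"

    def test_unplaced_gene_is_unknown(self):
        mmap = pd.DataFrame({"chromosome": ["chr1"], "position": [1]},
                            index=["m1"])
        gpos = pd.DataFrame(columns=["chromosome", "start", "end"])
        hit = EqtlHit("m1", "gX", 5.0, 0.001, 0.01)
        assert classify_cis_trans([hit], mmap, gpos)[0].cis == "unknown"

    def test_matches_brute_force_distance_scan(self):
        rng = np.random.default_rng(10)
        mmap = pd.DataFrame({
            "chromosome": rng.choice(["chr1", "chr2"], 30),
            "position": rng.integers(1, 200_000, 30)},
            index=[f"m{i}" for i in range(30)])
        starts = rng.integers(1, 200_000, 20)
        gpos = pd.DataFrame({"chromosome": rng.choice(["chr1", "chr2"], 20),
                             "start": starts, "end": starts + 1500},
                            index=[f"g{i}" for i in range(20)])
        hits = [EqtlHit(f"m{i}", f"g{j}", 1.0, 0.1, 0.1)
                for i in range(30) for j in range(20)]
        labelled = classify_cis_trans(hits, mmap, gpos)
        for h in labelled:
            m, g = mmap.loc[h.marker], gpos.loc[h.trait]
            if m["chromosome"] != g["chromosome"]:
                want = "trans"
            else:
                d = max(0, max(g["start"] - m["position"],
                               m["position"] - g["end"]))
                want = "cis" if d <= 10_000 else "trans"
            assert h.cis == want


class TestKnnImpute:
    def test_complete_matrix_unchanged(self):
        m = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        assert knn_impute_expression(m, k=2).equals(m)

    def test_twin_row_restores_masked_entry(self):
        base = [1.0, 2.0, 3.0, 4.0]
        m = pd.DataFrame([base, [1.0, 2.0, np.nan, 4.0], [9, 9, 9, 9]],
                         index=["a", "b", "c"])
        out = knn_impute_expression(m, k=1)
        assert out.loc["b", 2] == pytest.approx(3.0)

    def test_beats_column_mean_imputation(self):
        rng = np.random.default_rng(11)
        latent = rng.normal(size=(8, 1)) @ rng.normal(size=(1, 40))
        full = np.repeat(latent, 5, axis=0) + rng.normal(0, 0.2, (40, 40))
        mask = rng.random(full.shape) < 0.05
        masked = full.copy()
        masked[mask] = np.nan
        df = pd.DataFrame(masked)
        knn = knn_impute_expression(df, k=3).to_numpy()
        colmean = df.fillna(df.mean()).to_numpy()
        rmse = lambda x: np.sqrt(np.mean((x[mask] - full[mask]) ** 2))
        assert rmse(knn) < rmse(colmean)

    def test_all_missing_row_raises_with_row_name(self):
        m = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan]], index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            knn_impute_expression(m, k=1)


class TestBenjaminiHochberg:
    def test_single_p_is_its_own_q(self):
        assert benjamini_hochberg([0.042])[0] == pytest.approx(0.042)

    def test_step_up_recurrence_by_hand(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        # second hand case: q_(i) = min over j>=i of p_(j) m / j
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.04, 0.9]),
                                   [0.03, 0.06, 0.9])

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_q_monotone_in_p_and_bounded(self, ps):
        q = benjamini_hochberg(ps)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(ps) / len(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
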