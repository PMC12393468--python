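"""Rank-sum testing, BH adjustment, marker selection and composition tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spotcell import stats


def exact_rank_sum_p(a, b):
    """Enumeration oracle: exact two-sided Mann-Whitney p for tie-free data."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    total = 0
    at_least = 0
    mean_u = na * nb / 2
    dev = abs(u_obs - mean_u)
    for comb in itertools.combinations(range(na + nb), na):
        r = sum(c + 1 for c in comb)
        u = r - na * (na + 1) / 2
        total += 1
        if abs(u - mean_u) >= dev - 1e-12:
            at_least += 1
    return at_least / total


class TestRankSumTest:
    def test_extreme_separation_hand_example(self):
        # a=(1,2,3) vs b=(4,5,6): U=0 and exact p = 2 * 1/C(6,3) = 0.1
        U, p = stats.rank_sum_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert U == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one_exact(self):
        _, p = stats.rank_sum_test([1, 2, 3], [1, 2, 3], mode="exact")
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("na,nb", [(n, m) for n in range(1, 7) for m in range(n, 7)])
    def test_exact_mode_matches_enumeration_all_small_sizes(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = rng.permutation(np.arange(1, na + nb + 1))[:na].astype(float)
        b = np.setdiff1d(np.arange(1, na + nb + 1), a).astype(float)
        _, p = stats.rank_sum_test(a, b, mode="exact")
        assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_auto_picks_exact_for_small_tie_free(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        assert stats.rank_sum_test(a, b, "auto") == stats.rank_sum_test(a, b, "exact")

    def test_normal_path_type_one_error_sanity(self):
        """Quick 1,000-replicate calibration check of the asymptotic path
        (the full 10,000-replicate band is an acceptance criterion)."""
        rng = np.random.default_rng(0)
        data = rng.normal(size=(1000, 60))
        from scipy.stats import mannwhitneyu

        res = mannwhitneyu(
            data[:, :30], data[:, 30:], axis=1, alternative="two-sided",
            method="asymptotic",
        )
        rate = (res.pvalue < 0.05).mean()
        assert 0.03 < rate < 0.08

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.rank_sum_test([], [1.0])


class TestBHAdjust:
    def test_single_p_identity(self):
        assert stats.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        out = stats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(stats.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_never_decreases_and_dominates_bonferroni(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = stats.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        bonf = np.minimum(p * len(p), 1.0)
        alpha = 0.1
        assert set(np.flatnonzero(bonf < alpha)) <= set(np.flatnonzero(adj < alpha))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])


class TestRankMarkers:
    def test_constructed_separation_is_significant(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(5, 15, size=(40, 10))
        counts[:20, 0] += 200  # gene g0 expressed far higher in the target
        labels = np.array(["in"] * 20 + ["out"] * 20, dtype=object)
        table = stats.rank_markers(counts, labels, "in", [f"g{i}" for i in range(10)])
        row = table[table["gene"] == "g0"].iloc[0]
        assert row["log2FC"] > 2
        assert row["p_adj"] < 0.05

    def test_identical_groups_zero_log2fc(self):
        counts = np.tile(np.arange(1, 6), (8, 1))
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        table = stats.rank_markers(counts, labels, "a", [f"g{i}" for i in range(5)])
        assert np.allclose(table["log2FC"], 0.0, atol=1e-12)

    def test_agrees_with_scanpy_rank_genes_groups(self):
        """Independent oracle: scanpy's Wilcoxon rank_genes_groups on the
        same counts ranks genes the same way."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.3, size=(60, 25)).astype(float)
        counts[:30, :5] *= 3
        labels = np.array(["T", "R"]).repeat(30)
        adata = ad.AnnData(counts.copy())
        adata.obs["grp"] = pd.Categorical(labels)
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        sc.tl.rank_genes_groups(adata, "grp", groups=["T"], reference="R",
                                method="wilcoxon", tie_correct=True)
        sc_p = pd.Series(
            np.asarray(adata.uns["rank_genes_groups"]["pvals"]["T"]),
            index=[int(n) for n in adata.uns["rank_genes_groups"]["names"]["T"]],
        ).sort_index()
        table = stats.rank_markers(
            counts, labels, "T", list(range(25))
        ).set_index("gene").sort_index()
        # same gene ranking by evidence and tightly correlated log-p values
        ours = -np.log10(np.maximum(table["p"].to_numpy(), 1e-300))
        theirs = -np.log10(np.maximum(sc_p.to_numpy(), 1e-300))
        rho = pd.Series(ours).corr(pd.Series(theirs), method="spearman")
        assert rho > 0.95
        assert set(table.nsmallest(5, "p").index) == set(sc_p.nsmallest(5).index)

    def test_small_group_rejected(self):
        counts = np.ones((3, 4), dtype=int)
        with pytest.raises(ValueError, match="2 observations"):
            stats.rank_markers(counts, ["a", "b", "b"], "a", list("wxyz"))


class TestPickDomainMarker:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "group", "log2FC", "U", "p", "p_adj"]
        )

    def test_highest_fold_change_wins(self):
        t = self._table(
            [
                ["g1", "d", 2.0, 1, 1e-6, 1e-5],
                ["g2", "d", 5.0, 1, 1e-4, 1e-3],
                ["g3", "d", 3.0, 1, 1e-8, 1e-7],
            ]
        )
        assert stats.pick_domain_marker(t) == "g2"

    def test_tie_broken_by_smaller_p_then_gene(self):
        t = self._table(
            [
                ["gB", "d", 3.0, 1, 1e-4, 1e-3],
                ["gA", "d", 3.0, 1, 1e-6, 1e-5],
            ]
        )
        assert stats.pick_domain_marker(t) == "gA"
        t2 = self._table(
            [
                ["gB", "d", 3.0, 1, 1e-4, 1e-3],
                ["gA", "d", 3.0, 1, 1e-4, 1e-3],
            ]
        )
        assert stats.pick_domain_marker(t2) == "gA"

    def test_no_significant_rows_returns_none(self):
        t = self._table([["g1", "d", 2.0, 1, 0.5, 0.9], ["g2", "d", -3.0, 1, 1e-9, 1e-8]])
        assert stats.pick_domain_marker(t) is None


class TestUniqueUpSets:
    @staticmethod
    def _tables(up_part_vs_ac=True, up_part_vs_ad=True):
        def tbl(gene, fc, padj):
            return pd.DataFrame(
                {"gene": [gene], "log2FC": [fc], "p_adj": [padj]}
            )

        return {
            ("AC", "PART"): tbl("g", -2.0 if up_part_vs_ac else 0.5,
                                0.001 if up_part_vs_ac else 0.8),
            ("PART", "AD"): tbl("g", 2.0 if up_part_vs_ad else -0.5,
                                0.001 if up_part_vs_ad else 0.8),
            ("AC", "AD"): tbl("g", 0.0, 1.0),
        }

    def test_gene_up_vs_both_others_included(self):
        sets = stats.unique_up_sets(self._tables(True, True))
        assert sets["PART"] == {"g"}
        assert sets["AC"] == set() and sets["AD"] == set()

    def test_gene_up_vs_one_only_excluded(self):
        sets = stats.unique_up_sets(self._tables(True, False))
        assert sets["PART"] == set()

    def test_missing_contrast_rejected(self):
        tables = self._tables()
        del tables[("AC", "AD")]
        with pytest.raises(ValueError, match="missing contrast"):
            stats.unique_up_sets(tables)

    def test_null_data_rarely_yields_genes(self):
        rng = np.random.default_rng(4)
        empty = 0
        for _ in range(10):
            counts = rng.integers(5, 40, size=(90, 30))
            labels = np.array(["AC", "PART", "AD"]).repeat(30)
            tables = stats.pairwise_group_dge(
                counts, labels, [f"g{i}" for i in range(30)],
                groups=["AC", "PART", "AD"],
            )
            sets = stats.unique_up_sets(tables)
            if all(len(s) == 0 for s in sets.values()):
                empty += 1
        assert empty >= 9


class TestCompositionTest:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(5)
        th = rng.dirichlet(np.ones(3), size=20)
        theta = np.vstack([th, th])
        domains = np.array(["CA1"] * 40, dtype=object)
        groups = np.array(["AC"] * 20 + ["AD"] * 20, dtype=object)
        out = stats.composition_test(theta, domains, groups, ["A", "B", "C"])
        assert np.allclose(out["t"], 0.0, atol=1e-12)
        assert np.allclose(out["p"], 1.0)

    def test_welch_matches_textbook_formula(self):
        a = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
        b = np.array([0.4, 0.35, 0.5, 0.45, 0.3])
        theta = np.concatenate([a, b])[:, None]
        domains = np.array(["CA1"] * 10, dtype=object)
        groups = np.array(["AC"] * 5 + ["AD"] * 5, dtype=object)
        out = stats.composition_test(theta, domains, groups, ["Exc"])
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        assert out.loc[0, "t"] == pytest.approx(t_hand, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_shift_detected(self, seed):
        """Exc mean 0.6 -> 0.4 at concentration 50, 100 spots per group:
        significant negative t in the shifted direction."""
        rng = np.random.default_rng(1000 + seed)
        a = rng.dirichlet(50 * np.array([0.6, 0.3, 0.1]), size=100)
        b = rng.dirichlet(50 * np.array([0.4, 0.5, 0.1]), size=100)
        theta = np.vstack([b, a])  # AC has the lower Exc mean
        domains = np.array(["CA1"] * 200, dtype=object)
        groups = np.array(["AC"] * 100 + ["AD"] * 100, dtype=object)
        out = stats.composition_test(theta, domains, groups, ["Exc", "Oth", "R"])
        row = out[(out["cell_type"] == "Exc")].iloc[0]
        assert row["t"] < 0
        assert row["p_adj"] < 0.05

    def test_degenerate_variance_flagged(self):
        theta = np.full((8, 1), 0.5)
        domains = np.array(["CA1"] * 8, dtype=object)
        groups = np.array(["AC"] * 4 + ["AD"] * 4, dtype=object)
        out = stats.composition_test(theta, domains, groups, ["Exc"])
        assert out.loc[0, "degenerate"]
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_too_few_spots_rejected(self):
        theta = np.full((3, 1), 0.5)
        with pytest.raises(ValueError, match="CA1"):
            stats.composition_test(
                theta,
                np.array(["CA1"] * 3, dtype=object),
                np.array(["AC", "AC", "AD"], dtype=object),
                ["Exc"],
            )
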