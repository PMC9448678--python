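"""Hit-calling statistics against hand arithmetic and enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from screenforge import (
    CountsTable,
    SimConfig,
    call_hits,
    compute_sgrna_phenotypes,
    empirical_fdr_threshold,
    gene_pvalue_mannwhitney,
    make_quasi_genes,
    simulate_survival_screen,
    standardize_phenotypes,
)
from conftest import mw_permutation_oracle


def toy_counts(toy_manifest, col_a, col_b):
    return CountsTable(
        toy_manifest.sgrna_ids, ["a", "b"],
        np.column_stack([col_a, col_b]).astype(np.int64),
    )


class TestPhenotypes:
    def test_identical_samples_give_zero(self, toy_manifest):
        col = np.arange(10) * 10 + 50
        table = toy_counts(toy_manifest, col, col)
        pheno = compute_sgrna_phenotypes(table, toy_manifest, "a", "b")
        np.testing.assert_allclose(pheno["phenotype"], 0.0)

    def test_hand_computed_enrichment(self, toy_manifest):
        """One sgRNA 100->400 against flat NTCs is a ~2.0 log2 phenotype after
        NTC centering; the oracle is direct arithmetic on the definition."""
        a = np.full(10, 100)
        b = np.full(10, 100)
        b[0] = 400
        table = toy_counts(toy_manifest, a, b)
        pheno = compute_sgrna_phenotypes(table, toy_manifest, "a", "b", pseudocount=1.0)

        # independent arithmetic: CPM, pseudocount, log2 ratio, NTC median
        cpm_a = a / a.sum() * 1e6
        cpm_b = b / b.sum() * 1e6
        raw = np.log2((cpm_b + 1) / (cpm_a + 1))
        ntc = [i for i, e in enumerate(toy_manifest.entries) if e.is_ntc]
        expected = raw[0] - np.median(raw[ntc])
        assert pheno["phenotype"].iloc[0] == pytest.approx(expected)
        assert pheno["phenotype"].iloc[0] == pytest.approx(2.0, abs=1e-3)

    def test_depth_scaling_invariance_is_exact(self, toy_manifest):
        rng = np.random.default_rng(0)
        a = rng.integers(50, 500, size=10)
        b = rng.integers(50, 500, size=10)
        p1 = compute_sgrna_phenotypes(toy_counts(toy_manifest, a, b), toy_manifest, "a", "b")
        p2 = compute_sgrna_phenotypes(toy_counts(toy_manifest, a, b * 10), toy_manifest, "a", "b")
        np.testing.assert_allclose(p1["phenotype"], p2["phenotype"], rtol=0, atol=1e-12)

    def test_ntc_median_centered_to_zero(self, toy_manifest):
        rng = np.random.default_rng(1)
        table = toy_counts(
            toy_manifest, rng.integers(10, 1000, 10), rng.integers(10, 1000, 10)
        )
        pheno = compute_sgrna_phenotypes(table, toy_manifest, "a", "b")
        # even NTC count: median is a float midpoint, exact only to rounding
        assert np.median(pheno.loc[pheno["is_ntc"], "phenotype"]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_ntc_median_exact_zero_odd_count(self):
        from screenforge import LibraryManifest, SgrnaEntry, NTC_LABEL
        from screenforge.library_io import synthetic_protospacer

        entries = [SgrnaEntry("t1", synthetic_protospacer(0), "G1", False)] + [
            SgrnaEntry(f"n{j}", synthetic_protospacer(j), NTC_LABEL, True)
            for j in range(1, 6)
        ]
        m = LibraryManifest(entries)
        rng = np.random.default_rng(2)
        table = CountsTable(
            m.sgrna_ids, ["a", "b"],
            np.column_stack([rng.integers(10, 1000, 6), rng.integers(10, 1000, 6)]),
        )
        pheno = compute_sgrna_phenotypes(table, m, "a", "b")
        assert np.median(pheno.loc[pheno["is_ntc"], "phenotype"]) == 0.0

    def test_low_count_flagging(self, toy_manifest):
        a = np.full(10, 100)
        a[2] = 5
        pheno = compute_sgrna_phenotypes(
            toy_counts(toy_manifest, a, np.full(10, 100)), toy_manifest, "a", "b"
        )
        assert pheno["low_count"].iloc[2]
        assert pheno["low_count"].sum() == 1

    def test_missing_sample_errors(self, toy_manifest):
        table = toy_counts(toy_manifest, np.full(10, 1), np.full(10, 1))
        with pytest.raises(KeyError):
            compute_sgrna_phenotypes(table, toy_manifest, "a", "t15")

    def test_no_ntc_errors(self):
        from screenforge import LibraryManifest, SgrnaEntry

        m = LibraryManifest([SgrnaEntry("s1", "ACGT", "G1", False)])
        table = CountsTable(["s1"], ["a", "b"], np.array([[5, 5]]))
        with pytest.raises(ValueError, match="NTC"):
            compute_sgrna_phenotypes(table, m, "a", "b")


class TestMannWhitney:
    def test_separated_triples(self):
        assert gene_pvalue_mannwhitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        assert gene_pvalue_mannwhitney([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0)

    def test_constant_data_gives_one(self):
        assert gene_pvalue_mannwhitney([5, 5], [5, 5, 5]) == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            gene_pvalue_mannwhitney([], [1, 2])

    @pytest.mark.parametrize("n1", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("n2", [3, 8, 14, 20])
    def test_exact_path_matches_exhaustive_enumeration(self, n1, n2):
        """The exact p equals brute-force enumeration of all labelings for
        every small-group configuration (tie-free data)."""
        rng = np.random.default_rng(100 * n1 + n2)
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert gene_pvalue_mannwhitney(x, y) == pytest.approx(
                mw_permutation_oracle(x, y), abs=1e-12
            )

    def test_asymptotic_path_matches_monte_carlo_permutations(self):
        """5 vs 500: normal approximation with tie/continuity correction agrees
        with a 1e5-draw Monte-Carlo permutation p within 0.01."""
        rng = np.random.default_rng(42)
        y = rng.normal(size=500)
        x = rng.normal(loc=0.9, size=5)
        p_impl = gene_pvalue_mannwhitney(x, y)

        from scipy.stats import rankdata

        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        n1 = 5
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * 500 / 2
        hits = 0
        n_perm = 100_000
        chunk = 10_000
        for start in range(0, n_perm, chunk):
            keys = rng.random((chunk, pooled.size))
            pick = np.argpartition(keys, n1, axis=1)[:, :n1]
            u = ranks[pick].sum(axis=1) - n1 * (n1 + 1) / 2
            hits += int((np.abs(u - mu) >= abs(u_obs - mu)).sum())
        p_mc = hits / n_perm
        assert p_impl == pytest.approx(p_mc, abs=0.01)


class TestQuasiGenes:
    def test_groups_have_five_members_from_ntc_pool(self, toy_manifest):
        qs = make_quasi_genes(toy_manifest, n_groups=10, seed=1)
        ntc = set(toy_manifest.ntc_ids)
        assert len(qs) == 10
        for group in qs.groups:
            assert len(group) == 5
            assert set(group) <= ntc

    def test_sampling_is_with_replacement(self, toy_manifest):
        # 4 NTCs, groups of 5: pigeonhole forces a repeat in every group
        qs = make_quasi_genes(toy_manifest, n_groups=5, seed=2)
        assert all(len(set(g)) < 5 for g in qs.groups)

    def test_single_ntc_degenerate(self):
        from screenforge import LibraryManifest, SgrnaEntry, NTC_LABEL

        m = LibraryManifest(
            [SgrnaEntry("t", "ACGT", "G1", False), SgrnaEntry("n", "AAAA", NTC_LABEL, True)]
        )
        qs = make_quasi_genes(m, n_groups=3, seed=0)
        assert all(g == ("n",) * 5 for g in qs.groups)

    def test_same_seed_identical(self, toy_manifest):
        a = make_quasi_genes(toy_manifest, n_groups=20, seed=9)
        b = make_quasi_genes(toy_manifest, n_groups=20, seed=9)
        assert a.groups == b.groups

    def test_no_ntc_errors(self):
        from screenforge import LibraryManifest, SgrnaEntry

        m = LibraryManifest([SgrnaEntry("t", "ACGT", "G1", False)])
        with pytest.raises(ValueError, match="NTC"):
            make_quasi_genes(m)

    def test_default_group_count_matches_genes(self, toy_manifest):
        qs = make_quasi_genes(toy_manifest)
        assert len(qs) == len(toy_manifest.target_genes)


class TestStandardize:
    def test_forced_arithmetic(self):
        z = standardize_phenotypes([0.5], [0.1, 0.2, 0.3])
        assert z[0] == pytest.approx(3.0)  # (0.5 - 0.2) / 0.1 with sample sd

    def test_median_raw_maps_to_zero(self):
        assert standardize_phenotypes([0.2], [0.1, 0.2, 0.3])[0] == 0.0

    def test_standardized_quasi_have_median_zero_sd_one(self):
        rng = np.random.default_rng(3)
        quasi = rng.normal(size=101)
        z = standardize_phenotypes(quasi, quasi)
        assert np.median(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError, match="standard deviation"):
            standardize_phenotypes([1.0], [0.5, 0.5, 0.5])


def fdr_oracle(genes, quasi, target):
    """Brute-force hit set: scan every threshold on the pooled score grid and
    apply the add-one FDR estimate per tail by direct counting."""
    genes = np.asarray(genes, float)
    quasi = np.asarray(quasi, float)
    hit = np.zeros(genes.size, dtype=bool)
    for sign in (1.0, -1.0):
        g, q = sign * genes, sign * quasi
        candidates = np.unique(np.concatenate([g, q]))
        best = None
        for c in sorted(candidates[candidates > 0]):
            n_beyond = (g >= c).sum()
            if n_beyond == 0:
                continue
            est = (1 + (q >= c).sum()) / (q.size + 1) * g.size / n_beyond
            if est <= target:
                best = c
                break
        if best is not None:
            hit |= g >= best
    return hit


class TestEmpiricalFdr:
    def test_separated_null_all_hits(self):
        """Genes far beyond a well-resolved all-zero quasi null are all called."""
        quasi = np.zeros(100)
        genes = np.array([5.0, 4.0, 3.0])
        pos, neg, hit, direction = empirical_fdr_threshold(genes, quasi, 0.1)
        assert hit.all()
        assert (direction == "positive").all()
        assert pos == 3.0 and neg is None

    @pytest.mark.parametrize("target", [0.05, 0.1, 0.4, 0.6])
    def test_toy_scan_matches_enumeration_oracle(self, target):
        genes = np.array([3.0, 2.5, 1.0])
        quasi = np.array([2.6, 0.2, 0.1, 0.0])
        _, _, hit, _ = empirical_fdr_threshold(genes, quasi, target)
        np.testing.assert_array_equal(hit, fdr_oracle(genes, quasi, target))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_scores_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = rng.normal(size=30)
        quasi = rng.normal(size=90)
        for target in (0.05, 0.1, 0.25):
            _, _, hit, _ = empirical_fdr_threshold(genes, quasi, target)
            np.testing.assert_array_equal(hit, fdr_oracle(genes, quasi, target))

    def test_null_genes_rarely_called(self):
        """Gene scores drawn from the quasi distribution produce ~no hits."""
        rng = np.random.default_rng(7)
        total = 0
        for _ in range(50):
            genes = rng.normal(size=50)
            quasi = rng.normal(size=150)
            _, _, hit, _ = empirical_fdr_threshold(genes, quasi, 0.1)
            total += int(hit.sum())
        assert total <= 0.1 * 50 * 50 * 0.2  # far below the nominal budget

    def test_bad_target_errors(self):
        with pytest.raises(ValueError):
            empirical_fdr_threshold([1.0], [0.0, 0.1], 1.5)


class TestCallHits:
    def recovery_run(self, seed):
        gamma = np.zeros(50)
        gamma[:5] = -1.0
        cfg = SimConfig(n_genes=50, gamma=gamma, depth=1_000_000, seed=seed)
        table, truth = simulate_survival_screen(cfg)
        res = call_hits(table, truth.manifest, "t0", "tF", seed=seed)
        return res, truth

    def test_gene_score_identity_and_sign(self):
        res, _ = self.recovery_run(0)
        np.testing.assert_allclose(
            res["gene_score"], res["phenotype_score"] * res["neg_log10_p"]
        )
        nz = res["p_value"] < 1
        assert (
            np.sign(res.loc[nz, "gene_score"]) == np.sign(res.loc[nz, "phenotype_score"])
        ).all()
        assert (res.loc[res["p_value"] == 1.0, "gene_score"] == 0).all()

    def test_quasi_rows_never_hits(self):
        res, _ = self.recovery_run(1)
        assert not res.loc[res["is_quasi"], "hit"].any()
        assert (res["is_quasi"].sum()) == 3 * 50

    def test_recovers_strong_depletion_hits(self):
        res, truth = self.recovery_run(2)
        merged = res[~res["is_quasi"]].merge(truth.genes, on="gene")
        assert (merged.loc[merged["is_hit"], "hit"]).all()
        assert (merged.loc[merged["hit"], "direction"] == "negative").all()
        assert int((merged["hit"] & ~merged["is_hit"]).sum()) <= 1

    def test_sgrna_row_permutation_invariance(self):
        gamma = np.zeros(10)
        gamma[0] = -1.0
        cfg = SimConfig(n_genes=10, n_ntc=30, coverage=100, gamma=gamma,
                        depth=300_000, seed=5)
        table, truth = simulate_survival_screen(cfg)
        res1 = call_hits(table, truth.manifest, "t0", "tF", seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table.sgrna_ids))
        shuffled = CountsTable(
            [table.sgrna_ids[i] for i in perm], table.samples, table.counts[perm]
        )
        res2 = call_hits(shuffled, truth.manifest, "t0", "tF", seed=5)
        pd.testing.assert_frame_equal(res1, res2)

    def test_topk_aggregation_mode(self):
        res, truth = self.recovery_run(3)
        table, truth2 = simulate_survival_screen(truth.config)
        res_topk = call_hits(table, truth2.manifest, "t0", "tF", seed=3,
                             aggregation="topk")
        # top-3-of-5 aggregation amplifies raw phenotypes of true hits
        merged = res_topk[~res_topk["is_quasi"]].merge(truth.genes, on="gene")
        hits = merged[merged["is_hit"]]
        base = res[~res["is_quasi"]].merge(truth.genes, on="gene")
        base_hits = base[base["is_hit"]]
        lhs = hits.set_index("gene")["raw_phenotype"].abs().sort_index()
        rhs = base_hits.set_index("gene")["raw_phenotype"].abs().sort_index()
        assert (lhs >= rhs - 1e-9).all()
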