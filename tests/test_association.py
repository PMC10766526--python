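"""Variant QC, the dimension scan against an OLS oracle, lead-locus
collapsing, directional replication and gene-set enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import nspace as ns


def _geno(dosages, chrom=None, pos=None, ids=None):
    n, m = dosages.shape
    return ns.GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variants=pd.DataFrame(
            {
                "id": ids or [f"rs{j}" for j in range(m)],
                "chrom": chrom or ["1"] * m,
                "pos": pos or [1000 * (j + 1) for j in range(m)],
                "ea": ["A"] * m,
                "oa": ["G"] * m,
            }
        ),
        dosages=np.asarray(dosages, dtype=float),
    )


class TestQcFilter:
    def test_rare_variant_dropped(self):
        rng = np.random.default_rng(0)
        common = rng.binomial(2, 0.3, size=(500, 1)).astype(float)
        rare = rng.binomial(2, 0.004, size=(500, 1)).astype(float)
        G = _geno(np.hstack([common, rare]))
        kept = ns.qc_filter(G)
        assert list(kept.variants["id"]) == ["rs0"]

    def test_hwe_violator_dropped(self):
        rng = np.random.default_rng(1)
        ok = rng.binomial(2, 0.5, size=(600, 1)).astype(float)
        # all heterozygotes: gross HWE violation at p=0.5
        bad = np.ones((600, 1))
        G = _geno(np.hstack([ok, bad]))
        kept = ns.qc_filter(G)
        assert list(kept.variants["id"]) == ["rs0"]

    def test_all_pass_is_identity(self, genotypes):
        kept = ns.qc_filter(genotypes, maf_min=0.0, hwe_p_min=0.0)
        assert kept.n_variants == genotypes.n_variants


class TestGwasScan:
    def _tiny(self, n=10, m=3, seed=0):
        rng = np.random.default_rng(seed)
        G = _geno(rng.binomial(2, 0.4, size=(n, m)).astype(float))
        traits = pd.DataFrame(
            rng.normal(size=(n, 2)),
            index=G.sample_ids,
            columns=["T1", "T2"],
        )
        cov = pd.DataFrame(
            {"age": rng.uniform(40, 60, size=n), "sex": rng.integers(0, 2, n).astype(float)},
            index=G.sample_ids,
        )
        return G, traits, cov

    def test_matches_full_ols_oracle(self):
        # residualized per-variant scan must equal the full joint OLS fit
        G, traits, cov = self._tiny()
        out = ns.gwas_scan(G, traits, cov, dimension=1)
        for j, r in out.iterrows():
            X = sm.add_constant(
                np.column_stack([G.dosages[:, j], cov.to_numpy()])
            )
            fit = sm.OLS(traits["T1"].to_numpy(), X).fit()
            assert r["beta"] == pytest.approx(fit.params[1], abs=1e-9)
            assert r["se"] == pytest.approx(fit.bse[1], abs=1e-9)
            assert r["p"] == pytest.approx(fit.pvalues[1], abs=1e-9)

    def test_no_covariates_matches_simple_ols(self):
        G, traits, _ = self._tiny(seed=2)
        out = ns.gwas_scan(G, traits, None, dimension=2)
        X = sm.add_constant(G.dosages[:, 0])
        fit = sm.OLS(traits["T2"].to_numpy(), X).fit()
        assert out["beta"].iloc[0] == pytest.approx(fit.params[1], abs=1e-9)
        assert out["p"].iloc[0] == pytest.approx(fit.pvalues[1], abs=1e-9)

    def test_monomorphic_variant_gives_nan(self):
        G, traits, cov = self._tiny()
        G.dosages[:, 1] = 2.0
        out = ns.gwas_scan(G, traits, cov, dimension=1)
        assert np.isnan(out["p"].iloc[1]) and np.isnan(out["beta"].iloc[1])
        assert np.isfinite(out["p"].iloc[0])

    def test_sample_alignment_by_id(self):
        # shuffling trait rows must not change the result
        G, traits, cov = self._tiny(n=30, seed=4)
        a = ns.gwas_scan(G, traits, cov, dimension=1)
        shuffled = traits.sample(frac=1.0, random_state=0)
        b = ns.gwas_scan(G, shuffled, cov, dimension=1)
        pd.testing.assert_frame_equal(a, b)

    def test_disjoint_samples_rejected(self):
        G, traits, cov = self._tiny()
        traits.index = [f"other{i}" for i in range(len(traits))]
        with pytest.raises(ValueError, match="overlapping"):
            ns.gwas_scan(G, traits, cov, dimension=1)

    def test_planted_cohort_variant_reaches_genome_wide(
        self, genotypes, traits, truth
    ):
        # the generator's strongest causal variant should clear 5e-8 on at
        # least one dimension trait at n=5,000
        qc = ns.qc_filter(genotypes)
        best = np.inf
        for dim in range(1, 4):
            out = ns.gwas_scan(qc, traits, None, dimension=dim)
            hit = out[out["variant"].isin(truth.causal["variant"])]
            best = min(best, hit["p"].min())
        assert best < ns.GENOME_WIDE_P


class TestGenomicControl:
    def test_uniform_p_gives_lambda_one(self):
        rng = np.random.default_rng(0)
        lam = ns.genomic_control_lambda(rng.uniform(size=200_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_inflated_chi2_gives_lambda_above_one(self):
        rng = np.random.default_rng(1)
        chi2 = 1.5 * stats.chi2.rvs(df=1, size=100_000, random_state=rng)
        lam = ns.genomic_control_lambda(stats.chi2.sf(chi2, df=1))
        assert lam == pytest.approx(1.5, abs=0.05)


class TestLeadLoci:
    def _results(self, rows):
        return pd.DataFrame(
            rows,
            columns=["variant", "chrom", "pos", "ea", "beta", "se", "p", "n", "dimension"],
        )

    def test_window_absorbs_neighbor(self):
        rng = np.random.default_rng(0)
        G = _geno(
            rng.binomial(2, 0.4, size=(100, 3)).astype(float),
            pos=[10_000, 12_000, 300_000],
        )
        res = self._results(
            [
                ("rs0", "1", 10_000, "A", 0.5, 0.05, 1e-12, 100, 1),
                ("rs1", "1", 12_000, "A", 0.4, 0.05, 1e-9, 100, 1),
                ("rs2", "1", 300_000, "A", 0.3, 0.05, 1e-8, 100, 1),
            ]
        )
        leads = ns.select_lead_loci(res, G)
        assert [l.variant for l in leads] == ["rs0", "rs2"]
        assert leads[0].members == ["rs1"]

    def test_ld_absorbs_distant_correlate(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.5, size=100).astype(float)
        b = a.copy()  # perfect LD, far away
        c = rng.binomial(2, 0.5, size=100).astype(float)
        G = _geno(np.column_stack([a, b, c]), pos=[10_000, 900_000, 2_000_000])
        res = self._results(
            [
                ("rs0", "1", 10_000, "A", 0.5, 0.05, 1e-12, 100, 1),
                ("rs1", "1", 900_000, "A", 0.5, 0.05, 1e-11, 100, 1),
                ("rs2", "1", 2_000_000, "A", 0.3, 0.05, 1e-9, 100, 1),
            ]
        )
        leads = ns.select_lead_loci(res, G)
        assert [l.variant for l in leads] == ["rs0", "rs2"]

    def test_threshold_is_strict(self):
        G = _geno(np.random.default_rng(0).binomial(2, 0.4, (50, 1)).astype(float))
        res = self._results([("rs0", "1", 1000, "A", 0.5, 0.05, 5e-8, 50, 1)])
        assert ns.select_lead_loci(res, G) == []

    def test_dimensions_kept_separate(self):
        rng = np.random.default_rng(1)
        G = _geno(rng.binomial(2, 0.4, size=(100, 1)).astype(float), pos=[10_000])
        res = self._results(
            [
                ("rs0", "1", 10_000, "A", 0.5, 0.05, 1e-12, 100, 1),
                ("rs0", "1", 10_000, "A", 0.5, 0.05, 1e-12, 100, 2),
            ]
        )
        leads = ns.select_lead_loci(res, G)
        assert sorted(l.dimension for l in leads) == [1, 2]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        G = _geno(
            rng.binomial(2, 0.4, size=(200, 4)).astype(float),
            pos=[10_000, 13_000, 500_000, 502_000],
        )
        rows = [
            ("rs0", "1", 10_000, "A", 0.5, 0.05, 1e-12, 200, 1),
            ("rs1", "1", 13_000, "A", 0.4, 0.05, 1e-10, 200, 1),
            ("rs2", "1", 500_000, "A", 0.3, 0.05, 1e-9, 200, 1),
            ("rs3", "1", 502_000, "A", 0.2, 0.05, 1e-8 * 0.5, 200, 1),
        ]
        fwd = ns.select_lead_loci(self._results(rows), G)
        rev = ns.select_lead_loci(self._results(rows[::-1]), G)
        assert [l.variant for l in fwd] == [l.variant for l in rev]


class TestReplicate:
    def _frames(self):
        disc = pd.DataFrame(
            {
                "variant": ["rs0", "rs1", "rs2"],
                "dimension": [1, 1, 2],
                "beta": [0.5, -0.3, 0.2],
                "p": [1e-10, 1e-9, 1e-8],
            }
        )
        rep = pd.DataFrame(
            {
                "variant": ["rs0", "rs1"],
                "dimension": [1, 1],
                "beta": [0.4, 0.1],
                "p": [1e-4, 0.3],
            }
        )
        return disc, rep

    def test_summary_counts(self):
        disc, rep = self._frames()
        tested, summary = ns.replicate(disc, rep)
        assert summary["n_discovery"] == 3
        assert summary["n_missing_in_replication"] == 1
        assert summary["n_tested"] == 2
        assert summary["n_direction_concordant"] == 1

    def test_half_p_rule(self):
        disc, rep = self._frames()
        tested, _ = ns.replicate(disc, rep)
        row_c = tested[tested["variant"] == "rs0"].iloc[0]
        row_d = tested[tested["variant"] == "rs1"].iloc[0]
        assert row_c["p_one_sided"] == pytest.approx(1e-4 / 2)
        assert row_d["p_one_sided"] == pytest.approx(1 - 0.3 / 2)

    def test_sign_matched_plus_opposed_sum_to_one(self):
        disc = pd.DataFrame(
            {"variant": ["rs0"], "dimension": [1], "beta": [0.5], "p": [1e-9]}
        )
        rep_pos = pd.DataFrame(
            {"variant": ["rs0"], "dimension": [1], "beta": [0.2], "p": [0.08]}
        )
        rep_neg = rep_pos.assign(beta=[-0.2])
        p_pos = ns.replicate(disc, rep_pos)[0]["p_one_sided"].iloc[0]
        p_neg = ns.replicate(disc, rep_neg)[0]["p_one_sided"].iloc[0]
        assert p_pos + p_neg == pytest.approx(1.0)

    def test_strong_concordant_association_replicates(self):
        disc, rep = self._frames()
        tested, summary = ns.replicate(disc, rep)
        assert bool(tested[tested["variant"] == "rs0"]["replicated"].iloc[0])
        assert not bool(tested[tested["variant"] == "rs1"]["replicated"].iloc[0])
        assert summary["n_replicated"] == 1

    def test_split_cohort_replication_end_to_end(self, genotypes, traits, truth):
        # split the cohort in half; a strong causal signal discovered in one
        # half should replicate directionally in the other
        ids = list(traits.index)
        half = len(ids) // 2
        qc = ns.qc_filter(genotypes)
        scans = []
        for part in (ids[:half], ids[half:]):
            sub = traits.loc[part]
            frames = [
                ns.gwas_scan(qc, sub, None, dimension=d) for d in range(1, 3)
            ]
            scans.append(pd.concat(frames, ignore_index=True))
        disc = scans[0][scans[0]["p"] < 1e-6]
        if len(disc) == 0:
            pytest.skip("no discovery-half signal at this cohort size")
        tested, summary = ns.replicate(disc, scans[1])
        assert summary["n_replicated"] >= 1


class TestEnrichment:
    def test_matches_hypergeom_oracle_small(self):
        background = {f"g{i}" for i in range(12)}
        query = {"g0", "g1", "g2", "g3"}
        gene_set = {"g0", "g1", "g2", "g8", "g9"}
        out = ns.enrichment_test(query, {"s": gene_set}, background)
        expect = stats.hypergeom.sf(2, 12, 5, 4)
        assert out["p"].iloc[0] == pytest.approx(expect, abs=1e-12)
        assert out["overlap"].iloc[0] == 3

    def test_enriched_vs_random_set(self):
        rng = np.random.default_rng(0)
        background = {f"g{i}" for i in range(1000)}
        query = {f"g{i}" for i in range(30)}
        enriched = {f"g{i}" for i in range(25)} | {
            f"g{i}" for i in rng.integers(100, 1000, 25)
        }
        random_set = {f"g{i}" for i in rng.integers(100, 1000, 50)}
        out = ns.enrichment_test(
            query, {"hit": enriched, "null": random_set}, background
        )
        by = out.set_index("gene_set")
        assert bool(by.loc["hit", "significant"])
        assert not bool(by.loc["null", "significant"])

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            ns.enrichment_test({"x"}, {"s": {"x"}}, {"y"})

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            ns.enrichment_test(set(), {"s": {"x"}}, {"x"})

    def test_suggestive_genes_mapping(self):
        res = pd.DataFrame(
            {"variant": ["rs0", "rs1", "rs2"], "p": [1e-7, 1e-4, 1e-6]}
        )
        snp_map = pd.DataFrame(
            {"variant": ["rs0", "rs1", "rs2"], "gene": ["A", "B", "C"]}
        )
        assert ns.suggestive_genes(res, snp_map) == {"A", "C"}
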