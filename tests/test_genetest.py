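import math

import numpy as np
import pytest
from scipy import stats

from conftest import random_correlation
from jepeg import (
    AnnotationDB,
    CorrelationMatrix,
    EnrichmentModel,
    FunctionalAnnotation,
    GeneContext,
    SummaryDataset,
    SummaryRecord,
    WeightMatrix,
    assemble_gene,
    category_pvalues,
    category_scores,
    enrichment_adjust,
    enrichment_lambda,
    fdr_adjust,
    gene_statistic,
    run_jepeg,
)
from jepeg.simulate import SimConfig, simulate_panel


def make_ctx(z, s, sigma, y=None, ridge=0.0):
    z = np.asarray(z, dtype=float)
    s = np.atleast_2d(np.asarray(s, dtype=float))
    m = len(z)
    ids = tuple(f"s{i}" for i in range(m))
    cats = tuple(f"C{j}" for j in range(s.shape[0]))
    y = np.ones(m) if y is None else np.asarray(y, dtype=float)
    wm = WeightMatrix(categories=cats, snp_ids=ids, values=s)
    cm = CorrelationMatrix(list(ids), np.asarray(sigma, dtype=float), ridge=ridge)
    return GeneContext(
        gene="G", z=z, y=y, s=wm, sigma_g=cm, snp_ids=ids, categories=cats
    )


class TestCategoryScores:
    def test_scalar_algebra(self):
        ctx = make_ctx([2.5], [[0.8]], [[1.0]])
        cs = category_scores(ctx)
        assert cs.u[0] == pytest.approx(2.0)
        assert cs.sigma_u[0, 0] == pytest.approx(0.64)
        assert cs.k_eff == 1

    def test_imputation_downweighting(self):
        ctx = make_ctx([2.5], [[0.8]], [[1.0]], y=[0.5])
        cs = category_scores(ctx)
        assert cs.u[0] == pytest.approx(1.0)
        assert cs.sigma_u[0, 0] == pytest.approx(0.16)

    def test_duplicate_categories_rank_deficient(self):
        ctx = make_ctx([1.0, 2.0], [[0.5, 0.3], [0.5, 0.3]], np.eye(2))
        cs = category_scores(ctx)
        assert cs.k_eff == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_against_dense_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, k = 5, 3
        sigma = random_correlation(m, rng)
        s = rng.standard_normal((k, m))
        y = rng.uniform(0.5, 1.0, m)
        z = rng.standard_normal(m)
        cs = category_scores(make_ctx(z, s, sigma, y=y))
        # brute-force triple product with explicit loops
        w = np.array([[s[j, i] * y[i] for i in range(m)] for j in range(k)])
        u_expected = [sum(w[j][i] * z[i] for i in range(m)) for j in range(k)]
        su_expected = [
            [
                sum(
                    w[a][i] * sigma[i][j2] * w[b][j2]
                    for i in range(m)
                    for j2 in range(m)
                )
                for b in range(k)
            ]
            for a in range(k)
        ]
        np.testing.assert_allclose(cs.u, u_expected, atol=1e-10)
        np.testing.assert_allclose(cs.sigma_u, su_expected, atol=1e-10)


class TestGeneStatistic:
    def test_chi2_1df_tail(self):
        cs = category_scores(make_ctx([2.0], [[1.0]], [[1.0]]))
        t, df, p = gene_statistic(cs)
        assert (t, df) == (pytest.approx(4.0), 1)
        assert p == pytest.approx(0.0455, abs=5e-5)

    def test_printed_table_arithmetic(self):
        # chi2 = 26.5 on 2 df: closed form exp(-t/2)
        cs = category_scores(make_ctx([np.sqrt(13.25), np.sqrt(13.25)], np.eye(2), np.eye(2)))
        t, df, p = gene_statistic(cs)
        assert t == pytest.approx(26.5)
        assert p == pytest.approx(math.exp(-26.5 / 2), rel=1e-12)
        assert p == pytest.approx(1.76e-6, rel=0.05)

    def test_duplicate_categories_same_t_as_single(self):
        single = gene_statistic(category_scores(make_ctx([1.7], [[0.6]], [[1.0]])))
        dup = gene_statistic(
            category_scores(make_ctx([1.7], [[0.6], [0.6]], [[1.0]]))
        )
        assert dup[0] == pytest.approx(single[0], abs=1e-10)
        assert dup[1] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_against_pseudoinverse_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        sigma = random_correlation(6, rng)
        s = rng.standard_normal((3, 6))
        z = rng.standard_normal(6)
        cs = category_scores(make_ctx(z, s, sigma))
        t, df, p = gene_statistic(cs)
        t_oracle = float(cs.u @ np.linalg.pinv(cs.sigma_u) @ cs.u)
        assert t == pytest.approx(t_oracle, abs=1e-8)

    def test_single_snp_single_category_t_is_z_squared(self):
        z = 1.234
        cs = category_scores(make_ctx([z], [[0.37]], [[1.0]]))
        t, df, p = gene_statistic(cs)
        assert t == pytest.approx(z**2, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)

    def test_degenerate_zero_score_raises(self):
        cs = category_scores(make_ctx([0.0], [[1.0]], [[1.0]], y=[0.0]))
        with pytest.raises(ValueError):
            gene_statistic(cs)


class TestCategoryPvalues:
    def test_standard_normal_tail(self):
        cs = category_scores(make_ctx([1.96], [[1.0]], [[1.0]]))
        [(label, p)] = category_pvalues(cs)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_zero_score_p_one(self):
        cs = category_scores(make_ctx([0.0, 1.0], np.eye(2), np.eye(2)))
        ps = dict(category_pvalues(cs))
        assert ps["C0"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_against_standardization_oracle(self, seed):
        rng = np.random.default_rng(seed + 99)
        sigma = random_correlation(4, rng)
        s = rng.standard_normal((2, 4))
        z = rng.standard_normal(4)
        cs = category_scores(make_ctx(z, s, sigma))
        for (label, p), j in zip(category_pvalues(cs), range(2)):
            se = math.sqrt(cs.sigma_u[j, j])
            assert p == pytest.approx(
                2 * (1 - stats.norm.cdf(abs(cs.u[j]) / se)), abs=1e-12
            )


class TestEnrichment:
    def test_lambda_zero_at_null_calibration(self):
        assert enrichment_lambda([(1.0, 1), (2.0, 2), (3.0, 3)]).lambda_enrich == 0.0

    def test_lambda_floor_at_zero(self):
        assert enrichment_lambda([(0.5, 1), (1.0, 2)]).lambda_enrich == 0.0

    def test_lambda_hand_arithmetic(self):
        model = enrichment_lambda([(4, 1), (2, 2), (9, 3)])
        assert model.lambda_enrich == pytest.approx(5 / 3)
        assert model.n_genes == 3

    def test_central_limit_at_lambda_zero(self):
        model = EnrichmentModel(0.0, 10)
        assert enrichment_adjust(7.3, 2, model) == stats.chi2.sf(7.3, 2)

    def test_enriched_p_exceeds_raw(self):
        model = EnrichmentModel(0.8, 10)
        assert enrichment_adjust(7.3, 2, model) > stats.chi2.sf(7.3, 2)

    def test_noncentral_series_oracle(self):
        # Poisson-mixture summation of the noncentral chi-square tail
        t, df, lam = 10.0, 2, 1.0
        ncp = lam * df
        oracle = sum(
            math.exp(-ncp / 2)
            * (ncp / 2) ** j
            / math.factorial(j)
            * stats.chi2.sf(t, df + 2 * j)
            for j in range(80)
        )
        assert enrichment_adjust(t, df, EnrichmentModel(lam, 5)) == pytest.approx(
            oracle, abs=1e-12
        )

    def test_monotone_in_t_and_lambda(self):
        m1, m2 = EnrichmentModel(0.5, 5), EnrichmentModel(1.5, 5)
        assert enrichment_adjust(8.0, 2, m1) <= enrichment_adjust(6.0, 2, m1)
        assert enrichment_adjust(6.0, 2, m1) <= enrichment_adjust(6.0, 2, m2)


class TestFDR:
    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_known_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_single_p(self):
        assert fdr_adjust([0.07])[0] == pytest.approx(0.07)

    @pytest.mark.parametrize("seed", range(5))
    def test_against_rank_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, 20)
        q = fdr_adjust(p)
        # exhaustive step-up recomputation
        order = np.argsort(p)
        n = len(p)
        q_oracle = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * n / (rank + 1))
            q_oracle[i] = running
        np.testing.assert_allclose(q, q_oracle, atol=1e-12)


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_category_weight_rescaling(self, seed):
        rng = np.random.default_rng(seed + 7)
        sigma = random_correlation(5, rng)
        s = rng.standard_normal((3, 5))
        z = rng.standard_normal(5)
        t0 = gene_statistic(category_scores(make_ctx(z, s, sigma)))[0]
        s2 = s.copy()
        s2[1] *= 13.7  # rescale one category's weights
        t1 = gene_statistic(category_scores(make_ctx(z, s2, sigma)))[0]
        assert t1 == pytest.approx(t0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_allele_flip(self, seed):
        rng = np.random.default_rng(seed + 13)
        sigma = random_correlation(5, rng)
        s = rng.standard_normal((2, 5))
        z = rng.standard_normal(5)
        cs0 = category_scores(make_ctx(z, s, sigma))
        t0 = gene_statistic(cs0)[0]
        i = int(rng.integers(5))
        zf = z.copy()
        zf[i] *= -1
        sf = s.copy()
        sf[:, i] *= -1
        sigf = sigma.copy()
        sigf[i, :] *= -1
        sigf[:, i] *= -1
        cs1 = category_scores(make_ctx(zf, sf, sigf))
        np.testing.assert_allclose(cs1.u, cs0.u, atol=1e-10)
        np.testing.assert_allclose(cs1.sigma_u, cs0.sigma_u, atol=1e-10)
        assert gene_statistic(cs1)[0] == pytest.approx(t0, abs=1e-10)


class TestNullDistribution:
    def test_t_over_df_mean_near_one(self):
        """With panel LD treated as truth and no ridge, T/df is calibrated."""
        cfg = SimConfig(n_panel=1500, n_snps=6, seed=23)
        panel = simulate_panel(cfg)
        sigma = np.corrcoef(panel.dosages, rowvar=False)
        rng = np.random.default_rng(5)
        s = rng.standard_normal((2, 6))
        L = np.linalg.cholesky(sigma + 1e-12 * np.eye(6))
        reps = 1500
        ratios = np.empty(reps)
        for r in range(reps):
            z = L @ rng.standard_normal(6)
            t, df, _ = gene_statistic(category_scores(make_ctx(z, s, sigma)))
            ratios[r] = t / df
        se = ratios.std(ddof=1) / np.sqrt(reps)
        assert abs(ratios.mean() - 1.0) < 3 * se


class TestAssembleAndPipeline:
    def _inputs(self, seed=31):
        cfg = SimConfig(n_panel=300, n_snps=40, seed=seed)
        panel = simulate_panel(cfg)
        entries = []
        for j, cat in [(10, "CIS"), (12, "CIS"), (14, "TRN")]:
            entries.append(
                FunctionalAnnotation(
                    panel.snp_ids[j],
                    "1",
                    int(panel.pos[j]),
                    panel.ref[j],
                    panel.alt[j],
                    "GENE1",
                    cat,
                    0.6,
                )
            )
        db = AnnotationDB(entries)
        records = [
            SummaryRecord(s, "1", int(panel.pos[i]), panel.alt[i], panel.ref[i], 0.5)
            for i, s in enumerate(panel.snp_ids)
        ]
        return panel, db, SummaryDataset(records)

    def test_assemble_shapes_and_y(self):
        panel, db, ss = self._inputs()
        ctx = assemble_gene("GENE1", ss, db, panel, ridge=0.0)
        assert ctx.m == 3 and ctx.k == 2
        np.testing.assert_array_equal(ctx.y, 1.0)
        assert ctx.chrom == "1" and ctx.start < ctx.end

    def test_assemble_sqrt_info_for_imputed(self):
        panel, db, ss = self._inputs()
        target = db.entries[1]
        kept = [r for r in ss if r.pos != target.pos]
        imputed = SummaryRecord(
            target.snp_id,
            "1",
            target.pos,
            panel.alt[12],
            panel.ref[12],
            0.4,
            info=0.64,
            origin="imputed",
        )
        ctx = assemble_gene(
            "GENE1", SummaryDataset(kept + [imputed]), db, panel, ridge=0.0
        )
        assert ctx.y[list(ctx.snp_ids).index(target.snp_id)] == pytest.approx(0.8)

    def test_missing_gene_returns_none(self):
        panel, db, ss = self._inputs()
        assert assemble_gene("ABSENT", ss, db, panel) is None

    def test_run_jepeg_single_gene_completes(self):
        panel, db, ss = self._inputs()
        results = run_jepeg(ss, db, panel, enrichment=True)
        (g,) = results
        assert g.gene == "GENE1"
        assert 0 < g.p_raw <= 1 and 0 < g.p_enrich <= 1 and 0 < g.q_value <= 1
        assert g.p_enrich >= g.p_raw - 1e-15
        assert g.n_snps == 3
        assert g.top_category[0] in ("CIS", "TRN")

    def test_empty_intersection_errors(self):
        panel, db, _ = self._inputs()
        far = SummaryDataset(
            [SummaryRecord("rsX", "9", 10, "A", "G", 1.0)]
        )
        with pytest.raises(ValueError):
            run_jepeg(far, db, panel, impute=False)
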