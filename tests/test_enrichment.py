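"""Univariate Cox ranking, GSEA running sums, concordance, ssGSEA, log ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pairedsurv.enrichment import (
    cross_cohort_concordance,
    enrichment_score,
    geneset_survival_pvalues,
    gsea_preranked,
    normal_tumor_log_ratio,
    recurrent_pathways,
    single_sample_scores,
    univariate_cox_from_matrix,
    univariate_cox_ranking,
)
from pairedsurv.io import SurvivalTable, expression_view
from _oracles import gsea_es_oracle, make_expr, ssgsea_score_oracle


def _surv(time, event):
    return SurvivalTable([f"S{i:03d}" for i in range(len(time))],
                         np.asarray(time, float), np.asarray(event, int))


class TestUnivariateCox:
    def test_matches_independent_cox_implementation(self):
        """Vectorized Newton z/p agree with lifelines on tie-free data."""
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(0)
        n, g = 120, 4
        X = rng.normal(size=(g, n))
        lp = 0.8 * X[0]
        time = rng.exponential(1.0 / np.exp(lp))
        event = (rng.random(n) < 0.8).astype(int)
        surv = _surv(time, event)
        ranking = univariate_cox_from_matrix(X, [f"g{i}" for i in range(g)], surv)
        for i in range(g):
            x = (X[i] - X[i].mean()) / X[i].std()
            df = pd.DataFrame({"x": x, "T": time, "E": event})
            cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
            assert ranking.table.iloc[i]["coef"] == pytest.approx(
                cph.params_["x"], abs=1e-3)
            assert ranking.table.iloc[i]["z"] == pytest.approx(
                cph.summary["z"]["x"], abs=1e-3)

    def test_negating_gene_flips_z_exactly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1, 80))
        surv = _surv(rng.exponential(1, 80), np.ones(80))
        z_pos = univariate_cox_from_matrix(X, ["g"], surv).table["z"].iloc[0]
        z_neg = univariate_cox_from_matrix(-X, ["g"], surv).table["z"].iloc[0]
        assert z_neg == pytest.approx(-z_pos, rel=1e-10)

    def test_gene_equal_to_linear_predictor_ranks_first(self, small_cohort):
        cohort, surv, _, truth, _ = small_cohort
        expr = expression_view(cohort, "normal")
        values = np.vstack([expr.values, truth.linear_predictor])
        ids = expr.gene_ids + ["LP_GENE"]
        ranking = univariate_cox_from_matrix(values, ids, surv.reorder(expr.sample_ids))
        assert ranking.table["z"].abs().idxmax() == "LP_GENE"

    def test_zero_variance_rows_dropped(self, caplog):
        rng = np.random.default_rng(2)
        X = np.vstack([np.ones(30), rng.normal(size=30)])
        surv = _surv(rng.exponential(1, 30), np.ones(30))
        with caplog.at_level("INFO", logger="pairedsurv.enrichment"):
            ranking = univariate_cox_from_matrix(X, ["flat", "ok"], surv)
        assert ranking.gene_ids == ["ok"]

    def test_no_events_rejected(self):
        X = np.random.default_rng(3).normal(size=(2, 10))
        with pytest.raises(ValueError, match="event"):
            univariate_cox_from_matrix(X, ["a", "b"], _surv(np.ones(10), np.zeros(10)))

    def test_z_is_signed_probit_of_p(self):
        from scipy.stats import norm
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 60))
        surv = _surv(rng.exponential(1, 60), np.ones(60))
        t = univariate_cox_from_matrix(X, list("abcde"), surv).table
        recon = np.sign(t["coef"]) * norm.isf(t["p"] / 2.0)
        np.testing.assert_allclose(t["z"], recon, rtol=1e-8)


class TestEnrichmentScore:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_running_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z = np.sort(rng.normal(size=20))[::-1]
        pos = rng.choice(20, size=5, replace=False)
        mask = np.zeros(20, dtype=bool)
        mask[pos] = True
        assert enrichment_score(z, pos) == pytest.approx(
            gsea_es_oracle(z, mask), abs=1e-12)

    def test_top_k_set_is_extremal(self):
        rng = np.random.default_rng(5)
        z = np.sort(rng.normal(size=10))[::-1]
        top = enrichment_score(z, np.arange(3))
        for combo in itertools.combinations(range(10), 3):
            assert enrichment_score(z, np.array(combo)) <= top + 1e-12

    def test_improper_set_rejected(self):
        z = np.arange(5.0)[::-1]
        with pytest.raises(ValueError):
            enrichment_score(z, np.arange(5))

    def test_cross_check_against_gseapy(self):
        """ES agrees with the reference preranked implementation."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(6)
        genes = [f"g{i:03d}" for i in range(50)]
        z = np.sort(rng.normal(size=50))[::-1]
        members = [genes[i] for i in (0, 3, 7, 20, 33, 41)]
        rnk = pd.DataFrame({"gene": genes, "z": z}).set_index("gene")
        res = gseapy.prerank(rnk=rnk, gene_sets={"S": members}, permutation_num=5,
                             min_size=2, max_size=50, weight=1.0, seed=0,
                             outdir=None, no_plot=True, threads=1)
        ours = enrichment_score(z, np.array([0, 3, 7, 20, 33, 41]))
        theirs = float(res.res2d["ES"].iloc[0])
        assert ours == pytest.approx(theirs, abs=1e-6)


@pytest.fixture(scope="module")
def planted(small_cohort):
    cohort, surv, _, truth, _ = small_cohort
    from pairedsurv.simulate import make_gene_set_collection
    ranking = univariate_cox_ranking(expression_view(cohort, "normal"), surv)
    sets, planted_names = make_gene_set_collection(
        cohort.gene_ids, truth.signal_genes, n_planted=3, n_null=12,
        set_size=15, seed=3)
    res = gsea_preranked(ranking, sets, n_perm=300, seed=0, min_size=5)
    return res, planted_names


class TestGseaPreranked:
    def test_planted_sets_enriched(self, planted):
        res, names = planted
        hits = res[res["set"].isin(names)]
        assert (hits["q"] <= 0.25).mean() >= 2 / 3

    def test_direction_flips_with_ranking_sign(self, small_cohort):
        cohort, surv, _, truth, _ = small_cohort
        from pairedsurv.enrichment import GeneRanking
        from pairedsurv.simulate import make_gene_set_collection
        ranking = univariate_cox_ranking(expression_view(cohort, "normal"), surv)
        flipped = GeneRanking(ranking.table.assign(
            z=-ranking.table["z"], coef=-ranking.table["coef"]))
        sets, names = make_gene_set_collection(
            cohort.gene_ids, truth.signal_genes, n_planted=2, n_null=8,
            set_size=15, seed=4)
        a = gsea_preranked(ranking, sets, n_perm=100, seed=0, min_size=5)
        b = gsea_preranked(flipped, sets, n_perm=100, seed=0, min_size=5)
        merged = a.merge(b, on="set", suffixes=("_a", "_b"))
        strong = merged[merged["q_a"] < 0.25]
        assert (strong["direction_a"] == -strong["direction_b"]).all()

    def test_seed_determinism(self, small_cohort):
        cohort, surv, _, truth, _ = small_cohort
        from pairedsurv.simulate import make_gene_set_collection
        ranking = univariate_cox_ranking(expression_view(cohort, "tumor"), surv)
        sets, _ = make_gene_set_collection(cohort.gene_ids, truth.signal_genes,
                                           n_planted=1, n_null=5, set_size=10, seed=5)
        a = gsea_preranked(ranking, sets, n_perm=50, seed=9, min_size=5)
        b = gsea_preranked(ranking, sets, n_perm=50, seed=9, min_size=5)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_collection_rejected(self, small_cohort):
        cohort, surv, *_ = small_cohort
        ranking = univariate_cox_ranking(expression_view(cohort, "tumor"), surv)
        with pytest.raises(ValueError, match="size filtering"):
            gsea_preranked(ranking, {"TINY": ["g00000"]}, n_perm=10, min_size=5)


class TestRecurrentPathways:
    def _results(self, hits_per_set):
        rows = []
        for name, n_hits in hits_per_set.items():
            for i in range(18):
                rows.append({
                    "set": name,
                    "q": 0.1 if i < n_hits else 0.9,
                    "direction": 1,
                    "cohort": f"c{i // 3}",
                    "view": ["tumor", "normal", "foldchange"][i % 3],
                })
        return pd.DataFrame(rows)

    def test_boundary_five_hits_included_four_excluded(self):
        out = recurrent_pathways(self._results({"FIVE": 5, "FOUR": 4}),
                                 fdr_cut=0.25, min_hits=5)
        assert "FIVE" in out.index and "FOUR" not in out.index

    def test_counts_match_brute_force_tally(self):
        res = self._results({"A": 7, "B": 5, "C": 2})
        out = recurrent_pathways(res, fdr_cut=0.25, min_hits=5)
        for name in out.index:
            expected = ((res["set"] == name) & (res["q"] <= 0.25)).sum()
            assert out.loc[name, ("n_hits", "")] == expected


class TestCrossCohortConcordance:
    def _res(self, selections):
        rows = []
        for cohort, sets in selections.items():
            for s in sets:
                rows.append({"set": s, "q": 0.1, "direction": 1,
                             "cohort": cohort, "view": "normal"})
        return pd.DataFrame(rows)

    def test_identical_selections_give_one(self):
        res = self._res({"a": ["S1", "S2"], "b": ["S1", "S2"]})
        out = cross_cohort_concordance(res, "normal", 1, [0.25])
        assert out["concordance"].iloc[0] == 1.0

    def test_disjoint_selections_give_zero(self):
        res = self._res({"a": ["S1"], "b": ["S2"]})
        out = cross_cohort_concordance(res, "normal", 1, [0.25])
        assert out["concordance"].iloc[0] == 0.0

    def test_empty_selection_gives_missing(self):
        res = self._res({"a": ["S1"], "b": ["S2"]})
        out = cross_cohort_concordance(res, "normal", 1, [0.01])
        assert np.isnan(out["concordance"].iloc[0])

    def test_overlap_coefficient_value(self):
        res = self._res({"a": ["S1", "S2", "S3"], "b": ["S2", "S3", "S4", "S5"]})
        out = cross_cohort_concordance(res, "normal", 1, [0.25])
        assert out["concordance"].iloc[0] == pytest.approx(2 / 3)


class TestSingleSampleScores:
    def test_matches_cdf_walk_oracle(self):
        rng = np.random.default_rng(7)
        expr = make_expr(rng.normal(size=(15, 4)))
        members = [expr.gene_ids[i] for i in (1, 4, 8, 9, 12)]
        scores = single_sample_scores(expr, {"S": members}, min_size=3,
                                      normalize=False)
        mask = np.isin(expr.gene_ids, members)
        for s in range(4):
            expected = ssgsea_score_oracle(expr.values[:, s], mask)
            assert scores.iloc[0, s] == pytest.approx(expected, abs=1e-10)

    def test_top_expressed_set_is_maximal(self):
        rng = np.random.default_rng(8)
        expr = make_expr(np.sort(rng.normal(size=(20, 1)), axis=0)[::-1])
        genes = expr.gene_ids
        top_set = {"TOP": genes[:5]}
        others = {f"R{i}": [genes[j] for j in rng.choice(20, 5, replace=False)]
                  for i in range(10)}
        scores = single_sample_scores(expr, {**top_set, **others}, min_size=3,
                                      normalize=False)
        assert scores.loc["TOP"].iloc[0] == scores.iloc[:, 0].max()

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(9)
        expr = make_expr(rng.normal(size=(12, 3)))
        members = [expr.gene_ids[i] for i in (0, 5, 7, 11)]
        a = single_sample_scores(expr, {"S": members}, min_size=3)
        perm = rng.permutation(12)
        expr2 = make_expr(expr.values[perm],
                          genes=[expr.gene_ids[i] for i in perm])
        b = single_sample_scores(expr2, {"S": members}, min_size=3)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_constant_sample_rejected(self):
        expr = make_expr(np.ones((10, 1)))
        with pytest.raises(ValueError, match="unrankable"):
            single_sample_scores(expr, {"S": [f"g{i:05d}" for i in range(5)]},
                                 min_size=3)


class TestGenesetSurvival:
    def test_duplicated_set_identical_p(self, small_cohort):
        cohort, surv, _, truth, _ = small_cohort
        expr = expression_view(cohort, "normal")
        sets = {"A": truth.signal_genes[:10], "A_COPY": truth.signal_genes[:10]}
        scores = single_sample_scores(expr, sets, min_size=3)
        pv = geneset_survival_pvalues(scores, surv)
        assert pv.loc["A", "p"] == pv.loc["A_COPY", "p"]

    def test_planted_set_most_predictive(self, small_cohort):
        cohort, surv, _, truth, _ = small_cohort
        from pairedsurv.simulate import make_gene_set_collection
        sets, planted = make_gene_set_collection(
            cohort.gene_ids, truth.signal_genes, n_planted=2, n_null=10,
            set_size=15, seed=6)
        scores = single_sample_scores(expression_view(cohort, "normal"), sets,
                                      min_size=5)
        pv = geneset_survival_pvalues(scores, surv)
        assert pv["p"].idxmin() in planted


class TestNormalTumorLogRatio:
    def test_equal_pvalues_all_zero_sorted_by_name(self):
        p = pd.Series([0.1, 0.2, 0.3], index=["c", "a", "b"])
        out = normal_tumor_log_ratio(p, p.copy(), top_n=3)
        assert (out["log_ratio"] == 0.0).all()
        assert list(out.index) == ["a", "b", "c"]

    def test_definition_case(self):
        pn = pd.Series({"S": 1e-6})
        pt = pd.Series({"S": 1e-2})
        out = normal_tumor_log_ratio(pn, pt)
        assert out.loc["S", "log_ratio"] == pytest.approx(np.log(1e4))
        assert out.loc["S", "label"] == "Normal Associated"

    def test_top_n_matches_sort_oracle(self):
        rng = np.random.default_rng(10)
        names = [f"SET_{i:03d}" for i in range(150)]
        pn = pd.Series(rng.uniform(1e-6, 1, 150), index=names)
        pt = pd.Series(rng.uniform(1e-6, 1, 150), index=names)
        out = normal_tumor_log_ratio(pn, pt, top_n=100)
        ratios = np.log(pt / pn)
        expected = set(ratios.abs().nlargest(100).index)
        assert set(out.index) == expected

    def test_zero_pvalue_clipped_with_warning(self, caplog):
        pn = pd.Series({"S": 0.0})
        pt = pd.Series({"S": 0.5})
        with caplog.at_level("WARNING", logger="pairedsurv.enrichment"):
            out = normal_tumor_log_ratio(pn, pt)
        assert np.isfinite(out.loc["S", "log_ratio"])
        assert "clipped" in caplog.text
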