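import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from checs import (
    DataError,
    ParameterError,
    SchemaError,
    ScreenModel,
    build_manifest,
    enrichment_scores,
    fisher_combine,
    gene_pvalues,
    gene_scores,
    normalize_counts,
    null_params,
    poisson_pvalues,
    rank_genes,
    simulate_screen,
)

from conftest import toy_counts


def chi2_sf_even_df(statistic: float, df: int) -> float:
    """Closed-form chi-squared survival for even df: the Erlang tail
    exp(-s/2) * sum_{j<k} (s/2)^j / j!  — independent of scipy.chi2."""
    assert df % 2 == 0
    k = df // 2
    half = statistic / 2.0
    term, total = 1.0, 1.0
    for j in range(1, k):
        term *= half / j
        total += term
    return math.exp(-half) * total


class TestNormalize:
    def test_single_guide_lane(self):
        cm = toy_counts({"rep1_pos": [10]}, ["g"])
        assert normalize_counts(cm).iloc[0, 0] == 1.0

    def test_direct_arithmetic(self):
        cm = toy_counts({"rep1_pos": [2, 3, 5]}, list("abc"))
        assert normalize_counts(cm)["rep1_pos"].tolist() == [0.2, 0.3, 0.5]

    def test_scale_invariance(self):
        a = toy_counts({"rep1_pos": [2, 3, 5]}, list("abc"))
        b = toy_counts({"rep1_pos": [4, 6, 10]}, list("abc"))
        pd.testing.assert_frame_equal(normalize_counts(a), normalize_counts(b))

    def test_all_zero_sample_named(self):
        cm = toy_counts({"rep1_pos": [0, 0]}, list("ab"))
        with pytest.raises(DataError, match="rep1_pos"):
            normalize_counts(cm)


class TestEnrichment:
    def test_depletion_floor_is_exactly_1e_minus_3(self):
        cm = toy_counts(
            {"rep1_pos": [0, 10, 10], "rep1_neg": [5, 10, 5]}, list("abc")
        )
        table = enrichment_scores(normalize_counts(cm), cm)
        assert table.loc["a", "ratio_rep1"] == 1e-3
        assert table.loc["a", "n_floored"] == 1

    def test_zero_denominator_capped(self):
        cm = toy_counts(
            {"rep1_pos": [5, 10, 5], "rep1_neg": [0, 10, 10]}, list("abc")
        )
        table = enrichment_scores(normalize_counts(cm), cm)
        assert table.loc["a", "ratio_rep1"] == 1e3
        assert table.loc["a", "n_capped"] == 1

    def test_geometric_mean_fixed_point(self):
        cols = {}
        for r in (1, 2, 3, 4, 5):
            cols[f"rep{r}_pos"] = [30, 10]
            cols[f"rep{r}_neg"] = [10, 30]
        cm = toy_counts(cols, ["a", "b"])
        table = enrichment_scores(normalize_counts(cm), cm)
        # normalised ratio is the same r in every replicate -> AES == r
        assert table.loc["a", "aes"] == pytest.approx(table.loc["a", "ratio_rep1"])

    def test_aes_closed_form_cube_root(self):
        # per-replicate ratios 1, 2, 4 -> geometric mean exactly 2
        cols = {
            "rep1_pos": [10, 10], "rep1_neg": [10, 10],
            "rep2_pos": [20, 10], "rep2_neg": [10, 20],
            "rep3_pos": [40, 10], "rep3_neg": [10, 40],
        }
        cm = toy_counts(cols, ["a", "b"])
        norm = normalize_counts(cm)
        ratios = [norm[f"rep{r}_pos"]["a"] / norm[f"rep{r}_neg"]["a"] for r in (1, 2, 3)]
        table = enrichment_scores(norm, cm)
        expected = np.prod(ratios) ** (1 / 3)
        assert table.loc["a", "aes"] == pytest.approx(expected, rel=1e-12)

    def test_missing_population_schema_error(self):
        cm = toy_counts({"rep1_pos": [1, 2]}, ["a", "b"])
        with pytest.raises(SchemaError, match="rep1_neg"):
            enrichment_scores(normalize_counts(cm), cm)

    def test_depth_rescaling_leaves_aes_unchanged(self, small_screen):
        counts, _ = small_screen
        norm = normalize_counts(counts)
        a = enrichment_scores(norm, counts)
        doubled = toy_counts(
            {c: (counts.counts[c] * (3 if "pos" in c else 7)).tolist()
             for c in counts.counts.columns},
            counts.counts.index.tolist(),
        )
        b = enrichment_scores(normalize_counts(doubled), doubled)
        pd.testing.assert_series_equal(a["aes"], b["aes"])

    def test_reciprocal_screen_inverts_aes(self):
        cols = {
            "rep1_pos": [12, 7, 9], "rep1_neg": [3, 14, 9],
            "rep2_pos": [6, 8, 10], "rep2_neg": [9, 4, 11],
        }
        cm = toy_counts(cols, list("abc"))
        swapped = toy_counts(
            {c.replace("pos", "X").replace("neg", "pos").replace("X", "neg"): v
             for c, v in cols.items()},
            list("abc"),
        )
        a = enrichment_scores(normalize_counts(cm), cm)["aes"]
        b = enrichment_scores(normalize_counts(swapped), swapped)["aes"]
        np.testing.assert_allclose(a * b, 1.0, rtol=1e-12)


class TestGeneScores:
    def test_log_identity_single_guide(self):
        m = build_manifest(1, (1, 1), 0, seed=0)
        enrich = pd.DataFrame(
            {"aes": [math.e]}, index=pd.Index(m.frame["guide_id"], name="guide_id")
        )
        genes, _ = gene_scores(enrich, m)
        assert genes["log_gene_score"].iloc[0] == pytest.approx(1.0)

    def test_sum_oracle(self):
        m = build_manifest(1, (3, 3), 0, seed=0)
        enrich = pd.DataFrame(
            {"aes": [1.0, 2.0, 3.0]},
            index=pd.Index(m.frame["guide_id"], name="guide_id"),
        )
        genes, _ = gene_scores(enrich, m)
        assert genes["gene_score"].iloc[0] == pytest.approx(6.0)
        assert genes["log_gene_score"].iloc[0] == pytest.approx(math.log(6.0))
        mean_genes, _ = gene_scores(enrich, m, mode="mean")
        assert mean_genes["gene_score"].iloc[0] == pytest.approx(2.0)

    def test_controls_reported_separately(self, small_manifest, small_screen):
        counts, _ = small_screen
        enrich = enrichment_scores(normalize_counts(counts), counts)
        genes, controls = gene_scores(enrich, small_manifest)
        assert len(controls) == 2
        assert len(genes) == 20
        assert "CONTROL" not in set(genes["gene_id"])

    def test_unknown_guide_named(self, small_manifest):
        enrich = pd.DataFrame({"aes": [1.0]}, index=pd.Index(["mystery"], name="guide_id"))
        with pytest.raises(DataError, match="mystery"):
            gene_scores(enrich, small_manifest)


class TestPoisson:
    def test_observed_zero_gives_p_one(self):
        cm = toy_counts({"rep1_pos": [0, 100], "rep1_neg": [50, 50]}, ["a", "b"])
        p = poisson_pvalues(cm)
        assert p.loc["a", "p_rep1"] == 1.0

    def test_direct_series_summation_oracle(self):
        # lambda = 5 from the neg frequency; observed 10
        cm = toy_counts({"rep1_pos": [10, 90], "rep1_neg": [5, 95]}, ["a", "b"])
        p = poisson_pvalues(cm)
        lam = 5 / 100 * 100
        expected = 1.0 - sum(
            math.exp(-lam) * lam ** x / math.factorial(x) for x in range(10)
        )
        assert p.loc["a", "p_rep1"] == pytest.approx(expected, rel=1e-12)

    def test_equal_counts_near_half_for_large_counts(self):
        cm = toy_counts(
            {"rep1_pos": [40000, 60000], "rep1_neg": [40000, 60000]}, ["a", "b"]
        )
        p = poisson_pvalues(cm)
        assert p.loc["a", "p_rep1"] == pytest.approx(0.5, abs=0.01)

    def test_zero_reference_floors_lambda(self):
        cm = toy_counts({"rep1_pos": [10, 90], "rep1_neg": [0, 100]}, ["a", "b"])
        p = poisson_pvalues(cm)
        expected = stats.poisson.sf(9, 0.5)
        assert p.loc["a", "p_rep1"] == pytest.approx(expected, rel=1e-12)
        assert 0 < p.loc["a", "p_rep1"] < 1

    def test_monotone_in_observed_count(self):
        # raising a guide's pos count must not raise its P-value
        base = 50
        pvals = []
        for obs in (base, base + 10, base + 50, base + 200):
            cm = toy_counts(
                {"rep1_pos": [obs, 1000], "rep1_neg": [base, 1000]}, ["a", "b"]
            )
            pvals.append(poisson_pvalues(cm).loc["a", "p_rep1"])
        assert all(x >= y for x, y in zip(pvals, pvals[1:]))


class TestFisher:
    def test_single_test_identity(self):
        stat, df, p = fisher_combine([0.2])
        assert df == 2
        assert p == pytest.approx(0.2, rel=1e-12)

    def test_null_boundary(self):
        stat, df, p = fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0 and df == 6 and p == 1.0

    def test_two_tests_closed_form(self):
        stat, df, p = fisher_combine([0.05, 0.05])
        assert stat == pytest.approx(-2 * 2 * math.log(0.05), rel=1e-12)
        assert df == 4
        assert p == pytest.approx(chi2_sf_even_df(stat, 4), rel=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-10, 1.0), min_size=1, max_size=12))
    def test_matches_independent_survival_oracle(self, pvals):
        stat, df, p = fisher_combine(pvals)
        assert p == pytest.approx(chi2_sf_even_df(stat, df), rel=1e-9, abs=1e-12)
        # and scipy's own Fisher combination agrees
        res = stats.combine_pvalues(pvals, method="fisher")
        assert stat == pytest.approx(res.statistic, rel=1e-12)
        assert p == pytest.approx(res.pvalue, rel=1e-9, abs=1e-12)

    def test_monte_carlo_null_agreement(self, rng):
        # brute-force null: how often does a random uniform triple beat the
        # observed statistic?
        observed = [0.3, 0.1, 0.6]
        stat, df, p = fisher_combine(observed)
        n = 200_000
        draws = -2 * np.log(rng.random((n, 3))).sum(axis=1)
        mc = (draws >= stat).mean()
        assert abs(mc - p) < 4 * math.sqrt(p * (1 - p) / n)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ParameterError):
            fisher_combine(bad)


class TestGenePvalues:
    def test_bonferroni_arithmetic_and_df(self, small_manifest, small_screen):
        counts, _ = small_screen
        pois = poisson_pvalues(counts)
        table = gene_pvalues(pois, small_manifest)
        assert len(table) == 20  # controls excluded
        m = len(table)
        np.testing.assert_allclose(
            table["bonferroni_p"], np.minimum(1.0, table["combined_p"] * m)
        )
        assert (table["bonferroni_p"] <= 1.0).all()
        # df = 2 * n_guides * n_replicates for each gene
        n_guides = small_manifest.targets.groupby("gene_id").size()
        expected_df = (2 * n_guides * 5).reindex(table["gene_id"]).to_numpy()
        assert (table["fisher_df"].to_numpy() == expected_df).all()

    def test_single_gene_m_is_one(self):
        m = build_manifest(1, (2, 2), 0, seed=0)
        pois = pd.DataFrame(
            {"p_rep1": [0.5, 0.5]},
            index=pd.Index(m.frame["guide_id"], name="guide_id"),
        )
        table = gene_pvalues(pois, m)
        assert table["bonferroni_p"].iloc[0] == table["combined_p"].iloc[0]


class TestRanking:
    def _scores(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "gene_score"])
        df["n_guides"] = 1
        df["log_gene_score"] = np.log(df["gene_score"])
        return df[["gene_id", "n_guides", "gene_score", "log_gene_score"]]

    def _pvals(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "combined_p"])
        df["fisher_statistic"] = 1.0
        df["fisher_df"] = 2
        df["bonferroni_p"] = np.minimum(1.0, df["combined_p"] * len(df))
        return df

    def test_single_gene_rank_one(self):
        t = rank_genes(self._scores([("g", 2.0)]), self._pvals([("g", 0.5)]))
        assert t["rank"].tolist() == [1]
        assert t["direction"].iloc[0] == "positive"

    def test_tie_broken_by_combined_p(self):
        scores = self._scores([("a", 2.0), ("b", 2.0)])
        pvals = self._pvals([("a", 0.5), ("b", 0.01)])
        t = rank_genes(scores, pvals)
        assert t["gene_id"].tolist() == ["b", "a"]

    def test_direction_by_sign(self):
        t = rank_genes(
            self._scores([("a", 2.0), ("b", 0.5)]),
            self._pvals([("a", 0.5), ("b", 0.5)]),
        )
        assert t.set_index("gene_id")["direction"].to_dict() == {
            "a": "positive", "b": "negative"
        }

    def test_mismatched_gene_sets_listed(self):
        with pytest.raises(SchemaError, match="extra"):
            rank_genes(self._scores([("a", 2.0)]), self._pvals([("extra", 0.5)]))


class TestScreenModel:
    def test_planted_hits_rank_top(self, small_manifest, small_screen):
        counts, truth = small_screen
        res = ScreenModel(counts, small_manifest).fit()
        hits = set(truth.genes.loc[truth.genes["is_hit"], "gene_id"])
        top = set(res.gene_table.head(len(hits))["gene_id"])
        assert hits == top

    def test_null_log_gene_scores_centre_on_zero(self):
        # AES ~ 1 under the null, so the mean-mode log gene score sits at 0
        m = build_manifest(50, (4, 6), 0, seed=21)
        p = null_params(n_genes=50, n_controls=0, n_cells=100_000,
                        reads_per_sample=500_000, n_guides_total=None, seed=21)
        counts, _ = simulate_screen(m, p)
        res = ScreenModel(counts, m, gene_score_mode="mean").fit()
        assert abs(res.gene_table["log_gene_score"].mean()) < 0.05

    def test_summary_mentions_scored_genes(self, small_manifest, small_screen):
        counts, _ = small_screen
        res = ScreenModel(counts, small_manifest).fit()
        assert "genes scored: 20" in res.summary()

    def test_save_writes_tables(self, tmp_path, small_manifest, small_screen):
        counts, _ = small_screen
        ScreenModel(counts, small_manifest).fit().save(tmp_path)
        assert (tmp_path / "gene_scores.tsv").exists()
        assert (tmp_path / "guide_scores.tsv").exists()
        back = pd.read_csv(tmp_path / "gene_scores.tsv", sep="\t")
        assert list(back["rank"]) == sorted(back["rank"])
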