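"""CERNO statistic, FDR, Fisher aggregation and Wilcoxon comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cellsig as cs
from cellsig.exceptions import ConfigError
from cellsig.qc import LAYER_LOGNORM
from oracle_utils import (
    bh_oracle,
    chi2_upper_tail_even_df,
    cerno_oracle,
    fisher_greater_oracle,
    fisher_two_sided_oracle,
    wilcoxon_two_sided_oracle,
)


def _cerno_adata(make, values, condition=None):
    values = np.asarray(values, dtype=float)
    adata = make(np.zeros_like(values, dtype=int), condition=condition)
    adata.layers[LAYER_LOGNORM] = values
    return adata


class TestCernoStatistic:
    def test_worst_possible_ranks_give_zero_statistic(self):
        assert cs.cerno_from_ranks(np.array([10.0, 10.0]), 10) == 0.0
        assert stats.chi2.sf(0.0, 4) == 1.0

    def test_top_ranks_match_direct_formula(self):
        f = cs.cerno_from_ranks(np.array([1.0, 2.0]), 10)
        assert f == pytest.approx(cerno_oracle([1, 2], 10), abs=1e-12)
        assert f == pytest.approx(-2 * (np.log(0.1) + np.log(0.2)), abs=1e-12)
        # p via an independent closed-form chi-square upper tail (even df)
        p = stats.chi2.sf(f, 4)
        assert p == pytest.approx(chi2_upper_tail_even_df(f, 4), abs=1e-12)

    def test_mean_statistic_under_uniform_ranks_is_2n(self):
        rng = np.random.default_rng(12345)
        n, n_tot, cells = 5, 1000, 10_000
        ranks = rng.integers(1, n_tot + 1, size=(cells, n)).astype(float)
        f = cs.cerno_from_ranks(ranks, n_tot)
        assert f.mean() == pytest.approx(2 * n, rel=0.02)

    def test_invalid_ranks_rejected(self):
        with pytest.raises(ConfigError):
            cs.cerno_from_ranks(np.array([0.5]), 10)
        with pytest.raises(ConfigError):
            cs.cerno_from_ranks(np.array([11.0]), 10)

    def test_cerno_cell_uses_descending_ranks(self, adata_factory):
        # one cell; g0 has the highest expression -> rank 1
        adata = _cerno_adata(adata_factory, [[5.0, 1.0, 0.5, 0.2]])
        res = cs.cerno_cell(adata, cs.GeneSignature("s", ("g0",)))
        assert res.table["F"].iloc[0] == pytest.approx(cerno_oracle([1], 4))
        worst = cs.cerno_cell(adata, cs.GeneSignature("s", ("g3",)))
        assert worst.table["F"].iloc[0] == pytest.approx(cerno_oracle([4], 4))

    def test_improving_ranks_increases_f_and_decreases_p(self, adata_factory):
        sig = cs.GeneSignature("s", ("g4", "g5"))
        better = [[0.1, 0.2, 0.3, 0.4, 5.0, 6.0]]  # signature genes on top
        low = [[6.0, 5.0, 4.0, 3.0, 0.2, 0.1]]     # signature genes at bottom
        r_better = cs.cerno_cell(_cerno_adata(adata_factory, better), sig)
        r_low = cs.cerno_cell(_cerno_adata(adata_factory, low), sig)
        assert r_better.table["F"].iloc[0] > r_low.table["F"].iloc[0]
        assert r_better.table["p"].iloc[0] < r_low.table["p"].iloc[0]

    def test_chi2_calibration_on_continuous_tie_free_null(self, adata_factory):
        rng = np.random.default_rng(7)
        n_cells, n_genes = 5000, 2000
        adata = _cerno_adata(adata_factory, rng.normal(size=(n_cells, n_genes)))
        sig = cs.GeneSignature(
            "s", tuple(f"g{i}" for i in rng.choice(n_genes, 50, replace=False))
        )
        res = cs.cerno_cell(adata, sig)
        ks = stats.kstest(res.table["p"], "uniform").statistic
        assert ks < 0.05
        assert res.table["F"].mean() == pytest.approx(100.0, rel=0.05)


class TestFdr:
    def test_single_cell_condition_q_equals_p(self, adata_factory):
        adata = _cerno_adata(adata_factory, [[1.0, 2.0]], condition=["A"])
        res = cs.fdr_correct(cs.cerno_cell(adata, cs.GeneSignature("s", ("g0",))))
        assert res.table["q"].iloc[0] == pytest.approx(res.table["p"].iloc[0])

    def test_bh_step_up_matches_longhand_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        table = pd.DataFrame({"condition": "A", "F": 0.0, "p": p},
                             index=[f"c{i}" for i in range(4)])
        res = cs.fdr_correct(cs.CernoResult("s", 1, 10, table))
        assert np.allclose(res.table["q"], 0.04)
        assert np.allclose(res.table["q"], bh_oracle(p))
        rng = np.random.default_rng(5)
        p2 = rng.uniform(size=57)
        table2 = pd.DataFrame({"condition": "A", "F": 0.0, "p": p2},
                              index=[f"c{i}" for i in range(57)])
        res2 = cs.fdr_correct(cs.CernoResult("s", 1, 10, table2))
        assert np.allclose(res2.table["q"], bh_oracle(p2), atol=1e-12)

    def test_adjustment_is_per_condition_and_order_invariant(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=40)
        cond = np.array(["A", "B"] * 20)
        table = pd.DataFrame({"condition": cond, "F": 0.0, "p": p},
                             index=[f"c{i}" for i in range(40)])
        res = cs.fdr_correct(cs.CernoResult("s", 1, 10, table))
        for lab in ("A", "B"):
            sub = res.table[res.table["condition"] == lab]
            assert np.allclose(sub["q"], bh_oracle(sub["p"].to_numpy()))
            # q nondecreasing in p within the condition
            s = sub.sort_values("p")
            assert np.all(np.diff(s["q"]) >= -1e-12)
        assert np.all(res.table["q"] >= res.table["p"] - 1e-12)
        shuffled = table.sample(frac=1.0, random_state=1)
        res_shuffled = cs.fdr_correct(cs.CernoResult("s", 1, 10, shuffled))
        assert np.allclose(res.table["q"].sort_index(),
                           res_shuffled.table["q"].sort_index())

    def test_all_ones_stay_ones(self):
        table = pd.DataFrame({"condition": "A", "F": 0.0, "p": np.ones(5)},
                             index=[f"c{i}" for i in range(5)])
        res = cs.fdr_correct(cs.CernoResult("s", 1, 10, table))
        assert np.all(res.table["q"] == 1.0)


class TestFisherConditionEnrichment:
    def _result(self, q_a, q_b):
        q = np.concatenate([q_a, q_b])
        cond = ["A"] * len(q_a) + ["B"] * len(q_b)
        table = pd.DataFrame(
            {"condition": cond, "F": 0.0, "p": q, "q": q},
            index=[f"c{i}" for i in range(len(q))],
        )
        return cs.CernoResult("s", 1, 10, table)

    def test_balanced_table_is_null(self):
        res = self._result(np.r_[np.zeros(5), np.ones(5)],
                           np.r_[np.zeros(5), np.ones(5)])
        out = cs.fisher_condition_enrichment(res)
        assert out.odds_ratio == pytest.approx(1.0)
        assert out.p == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        from math import comb

        res = self._result(np.zeros(10), np.ones(10))
        out = cs.fisher_condition_enrichment(res)
        assert np.array_equal(out.table, [[10, 0], [0, 10]])
        assert out.p == pytest.approx(2 / comb(20, 10), abs=1e-15)
        assert out.enriched_condition == "A"

    def test_two_eight_table_matches_enumeration(self):
        res = self._result(np.r_[np.zeros(2), np.ones(8)],
                           np.r_[np.zeros(8), np.ones(2)])
        out = cs.fisher_condition_enrichment(res)
        assert out.p == pytest.approx(4252 / 184756, abs=1e-12)
        assert out.p == pytest.approx(fisher_two_sided_oracle(2, 8, 8, 2),
                                      abs=1e-12)

    def test_one_sided_option_matches_enumeration(self):
        from cellsig._stats import fisher_exact_2x2

        _, p = fisher_exact_2x2([[8, 2], [3, 7]], alternative="greater")
        assert p == pytest.approx(fisher_greater_oracle(8, 2, 3, 7), abs=1e-12)

    def test_random_tables_match_enumeration(self):
        from cellsig._stats import fisher_exact_2x2

        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                      abs=1e-12)

    def test_requires_q_and_two_conditions(self):
        table = pd.DataFrame({"condition": "A", "F": 0.0, "p": [0.5]},
                             index=["c0"])
        with pytest.raises(ConfigError):
            cs.fisher_condition_enrichment(cs.CernoResult("s", 1, 10, table))
        res = self._result(np.zeros(3), np.zeros(0))
        with pytest.raises(ConfigError):
            cs.fisher_condition_enrichment(res)


class TestWilcoxon:
    def test_separated_groups_match_full_enumeration(self):
        _, p = cs.wilcoxon_score_test(
            np.array([1.0, 2, 3, 4, 5, 6]), ["A", "A", "A", "B", "B", "B"]
        )
        assert p == pytest.approx(0.1, abs=1e-12)
        assert wilcoxon_two_sided_oracle([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        _, p = cs.wilcoxon_score_test(
            np.array([1.0, 2, 3, 1, 2, 3]), ["A"] * 3 + ["B"] * 3
        )
        assert p == pytest.approx(1.0)

    def test_exact_path_matches_full_enumeration_at_n8(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=8)
        y = rng.normal(loc=0.8, size=8)
        p_oracle = wilcoxon_two_sided_oracle(list(x), list(y))
        _, p = cs.wilcoxon_score_test(np.r_[x, y], ["A"] * 8 + ["B"] * 8)
        assert p == pytest.approx(p_oracle, abs=1e-9)  # exact path, no ties
        p_asym = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(p_oracle - p_asym) < 0.01

    def test_empty_group_is_an_error(self):
        with pytest.raises(ConfigError):
            cs.wilcoxon_score_test(np.array([1.0, 2.0]), ["A", "A"])


class TestSignatureEnrichmentModel:
    def test_fit_recovers_planted_enrichment(self, planted_dataset):
        adata, _, sig = planted_dataset
        res = cs.SignatureEnrichment(adata, sig).fit()
        assert res.cerno_p < 1e-6
        assert res.condition_test.enriched_condition == "shSELP"
        assert res.wilcoxon_p < 1e-6
        assert np.all(res.cerno.table["q"] >= res.cerno.table["p"] - 1e-12)
        summary = res.summary()
        assert "planted" in summary and "shSELP" in summary
        means = res.score_means()
        assert means.loc["shSELP", "combined"] > means.loc["shNC", "combined"]

    def test_model_validates_condition_column(self, adata_factory):
        adata = adata_factory(np.ones((4, 5), dtype=int))
        with pytest.raises(ConfigError):
            cs.SignatureEnrichment(adata, cs.GeneSignature("s", ("g0",)),
                                   condition_key="missing")
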