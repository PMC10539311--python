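"""Delocalization scores: far counts, EB posterior, tails and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import logit

from chartographer.contacts import ContactRecord
from chartographer.delocalization import (beta_exceedance, combine_and_classify,
                                          compute_far_counts,
                                          delocalization_score, posterior_rate,
                                          raw_score, tail_probability)
from chartographer.genome import GenomeLayout
from conftest import random_records


class _FakeFit:
    """Minimal stand-in exposing the fitted-null interface used downstream."""

    def __init__(self, pi, gamma):
        self._pi, self.gamma = pi, gamma

    @property
    def prior_concentration(self):
        return 1.0 / self.gamma - 1.0

    def predict(self, chrom, expr):
        return np.full(len(np.atleast_1d(chrom)), self._pi)


class TestFarCounts:
    def test_trans_counts_match_per_record_oracle(self, genome, gene_models):
        rng = np.random.default_rng(0)
        records = random_records(rng, genome, gene_models, 100)
        out = compute_far_counts(records, gene_models, mode="trans").set_index("gene_id")
        chrom_of = {g.gene_id: g.chrom for g in gene_models}
        for gid in out.index:
            own = [r for r in records if r.rna_gene_id == gid]
            far = sum(1 for r in own if r.dna_chrom != chrom_of[gid])
            assert out.loc[gid, "N"] == len(own)
            assert out.loc[gid, "N_far"] == far

    def test_all_contacts_on_source_chromosome_gives_zero_far(self, gene_models):
        recs = [ContactRecord(f"r{i}", "GENE0001", "chr1", 1_000_000, "+",
                              "chr1", 2_000_000 + i, "+", "exon", "S")
                for i in range(5)]
        out = compute_far_counts(recs, gene_models, mode="trans")
        assert out["N_far"].iloc[0] == 0

    def test_cis_partition_at_threshold(self, gene_models):
        # |delta| = 10 kb and 2 Mb with D = 1 Mb -> one near, one far
        recs = [
            ContactRecord("r1", "GENE0001", "chr1", 1_000_000, "+", "chr1",
                          1_010_000, "+", "exon", "S"),
            ContactRecord("r2", "GENE0001", "chr1", 1_000_000, "+", "chr1",
                          3_000_000, "+", "exon", "S"),
        ]
        out = compute_far_counts(recs, gene_models, mode="cis", D=1_000_000)
        assert out["N_near"].iloc[0] == 1 and out["N_far"].iloc[0] == 1

    def test_boundary_distance_counts_as_near(self, gene_models):
        recs = [ContactRecord("r1", "GENE0001", "chr1", 1_000_000, "+", "chr1",
                              2_000_000, "+", "exon", "S")]
        out = compute_far_counts(recs, gene_models, mode="cis", D=1_000_000)
        assert out["N_near"].iloc[0] == 1


class TestRawScore:
    def test_worked_density_ratio(self):
        # L_cis 100 Mb of a 1 Gb genome, 90 near / 10 far contacts
        genome = GenomeLayout(tuple(f"c{i}" for i in range(10)),
                              (100_000_000,) * 10)
        inputs = pd.DataFrame({"chrom": ["c0"], "N_near": [90], "N_far": [10],
                               "N": [100], "mode": "trans"})
        score = raw_score(inputs, genome, mode="trans")
        assert score.iloc[0] == pytest.approx(np.log2((10 / 900e6) / (90 / 100e6)),
                                              abs=1e-12)
        assert score.iloc[0] == pytest.approx(-6.34, abs=0.01)

    def test_equal_densities_score_zero(self):
        genome = GenomeLayout(("c0", "c1"), (100, 100))
        inputs = pd.DataFrame({"chrom": ["c0"], "N_near": [50], "N_far": [50],
                               "N": [100]})
        assert raw_score(inputs, genome, mode="trans").iloc[0] == pytest.approx(0.0)

    def test_doubling_far_counts_adds_one(self):
        genome = GenomeLayout(("c0", "c1", "c2"), (100, 100, 100))
        base = pd.DataFrame({"chrom": ["c0", "c0"], "N_near": [50, 50],
                             "N_far": [10, 20], "N": [60, 70]})
        s = raw_score(base, genome, mode="trans")
        assert s.iloc[1] - s.iloc[0] == pytest.approx(1.0)

    def test_zero_far_counts_yield_nan(self):
        genome = GenomeLayout(("c0", "c1"), (100, 100))
        inputs = pd.DataFrame({"chrom": ["c0"], "N_near": [50], "N_far": [0],
                               "N": [50]})
        assert np.isnan(raw_score(inputs, genome, mode="trans").iloc[0])


class TestPosterior:
    def test_prior_parameters_from_gamma(self):
        # pi_model 0.2, gamma 0.1 -> alpha+beta = 9 -> Beta(1.8, 7.2)
        inputs = pd.DataFrame({"chrom": ["c"], "lnN": [5.0], "N": [0], "N_far": [0]})
        post = posterior_rate(_FakeFit(0.2, 0.1), inputs)
        assert post["alpha0"].iloc[0] == pytest.approx(1.8)
        assert post["beta0"].iloc[0] == pytest.approx(7.2)

    def test_conjugate_update_closed_form(self):
        # prior Beta(2, 8) (pi=0.2, gamma=1/11), N=10, k=5 -> Beta(7, 13)
        inputs = pd.DataFrame({"chrom": ["c"], "lnN": [np.log(10)], "N": [10],
                               "N_far": [5]})
        post = posterior_rate(_FakeFit(0.2, 1.0 / 11.0), inputs)
        assert post["alpha_post"].iloc[0] == pytest.approx(7.0)
        assert post["beta_post"].iloc[0] == pytest.approx(13.0)
        assert post["pi_post"].iloc[0] == pytest.approx(0.35)

    def test_no_data_returns_prior(self):
        inputs = pd.DataFrame({"chrom": ["c"], "lnN": [0.0], "N": [0], "N_far": [0]})
        post = posterior_rate(_FakeFit(0.3, 0.05), inputs)
        assert post["pi_post"].iloc[0] == pytest.approx(post["pi_model"].iloc[0])

    def test_posterior_mean_matches_grid_integration(self):
        """Conjugate posterior mean vs numeric integration of likelihood x
        prior on 50 random parameter sets (|dpi| < 1e-6)."""
        rng = np.random.default_rng(1)
        grid = np.linspace(1e-9, 1 - 1e-9, 400_001)
        for _ in range(50):
            pi = rng.uniform(0.05, 0.9)
            gamma = rng.uniform(0.01, 0.3)
            N = int(rng.integers(1, 300))
            k = int(rng.integers(0, N + 1))
            inputs = pd.DataFrame({"chrom": ["c"], "lnN": [np.log(max(N, 1))],
                                   "N": [N], "N_far": [k]})
            post = posterior_rate(_FakeFit(pi, gamma), inputs)
            s = 1 / gamma - 1
            log_dens = ((pi * s - 1 + k) * np.log(grid)
                        + ((1 - pi) * s - 1 + N - k) * np.log1p(-grid))
            dens = np.exp(log_dens - log_dens.max())
            grid_mean = np.trapezoid(grid * dens, grid) / np.trapezoid(dens, grid)
            assert abs(post["pi_post"].iloc[0] - grid_mean) < 1e-6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(pi=st.floats(0.05, 0.95), gamma=st.floats(0.01, 0.4),
           N=st.integers(1, 1000), frac=st.floats(0, 1))
    def test_posterior_is_convex_combination(self, pi, gamma, N, frac):
        k = int(round(frac * N))
        inputs = pd.DataFrame({"chrom": ["c"], "lnN": [np.log(N)],
                               "N": [N], "N_far": [k]})
        post = posterior_rate(_FakeFit(pi, gamma), inputs)
        lo, hi = sorted([pi, k / N])
        assert lo - 1e-12 <= post["pi_post"].iloc[0] <= hi + 1e-12


class TestScore:
    def test_score_examples(self):
        post = pd.DataFrame({"pi_post": [0.2, 1 / 3, 0.35],
                             "pi_model": [0.2, 0.2, 0.2]})
        delta = delocalization_score(post)
        assert delta.iloc[0] == pytest.approx(0.0)
        # odds 0.5 vs 0.25: exactly one doubling
        assert delta.iloc[1] == pytest.approx(1.0)
        assert delta.iloc[2] == pytest.approx(
            (logit(0.35) - logit(0.2)) / np.log(2))
        assert delta.iloc[2] == pytest.approx(1.107, abs=1e-3)

    def test_natural_log_flag(self):
        post = pd.DataFrame({"pi_post": [0.35], "pi_model": [0.2]})
        assert (delocalization_score(post, base="ln").iloc[0]
                == pytest.approx(logit(0.35) - logit(0.2)))


class TestTailProbability:
    def test_identical_posterior_and_prior_gives_half(self):
        post = pd.DataFrame({"alpha_post": [3.0], "beta_post": [7.0],
                             "alpha0": [3.0], "beta0": [7.0]})
        assert tail_probability(post).iloc[0] == pytest.approx(0.5, abs=1e-8)

    def test_stochastic_dominance_extreme(self):
        assert beta_exceedance(500, 1, 1, 500)[0] == pytest.approx(1.0, abs=1e-9)

    def test_quadrature_agrees_with_monte_carlo(self):
        """Quadrature within 3 MC standard errors on 50 random parameter sets."""
        rng = np.random.default_rng(2)
        n_mc = 1_000_000
        for _ in range(50):
            a1, b1 = rng.uniform(1, 300, size=2)
            a2, b2 = rng.uniform(0.5, 100, size=2)
            exact, ok = beta_exceedance(a1, b1, a2, b2)
            assert ok
            x = rng.beta(a1, b1, n_mc)
            y = rng.beta(a2, b2, n_mc)
            mc = np.mean(x > y)
            se = np.sqrt(max(exact * (1 - exact), 1.0 / n_mc) / n_mc)
            assert abs(exact - mc) < 3 * se

    def test_small_p_means_rate_above_null(self):
        # posterior far above the prior -> near-zero delocalization p-value
        post = pd.DataFrame({"alpha_post": [80.0], "beta_post": [20.0],
                             "alpha0": [2.0], "beta0": [8.0]})
        assert tail_probability(post).iloc[0] < 1e-3


class TestCombineAndClassify:
    def _table(self, pvals, gene="g1", state="ES"):
        return pd.DataFrame({"gene_id": gene, "state": state,
                             "p_deloc": pvals, "delta": 1.0})

    def test_unit_pvalues_combine_to_one(self):
        res = combine_and_classify(self._table([1.0, 1.0]))
        assert res["p_deloc"].iloc[0] == pytest.approx(1.0)

    def test_fisher_statistic_example(self):
        # p = [0.05, 0.05]: -2 sum ln p = 11.98, chi2(4) -> 0.0175
        res = combine_and_classify(self._table([0.05, 0.05]))
        stat = -2 * np.log(0.05) * 2
        assert stat == pytest.approx(11.983, abs=1e-3)
        assert res["p_deloc"].iloc[0] == pytest.approx(
            stats.chi2.sf(stat, df=4), abs=1e-12)
        assert res["p_deloc"].iloc[0] == pytest.approx(0.0175, abs=1e-3)

    def test_adjusted_p_below_threshold_is_delocalized(self):
        table = pd.concat([
            self._table([1e-6, 1e-6], gene="hot"),
            self._table([0.8, 0.9], gene="cold"),
        ])
        res = combine_and_classify(table, fdr=0.05).set_index("gene_id")
        assert res.loc["hot", "category"] == "delocalized"
        assert res.loc["cold", "category"] == "neither"

    def test_ultralocalized_side_uses_complement(self):
        table = self._table([1 - 1e-9, 1 - 1e-9], gene="anchored")
        res = combine_and_classify(table, fdr=0.05)
        assert res["category"].iloc[0] == "ultralocalized"

    def test_delta_is_replicate_mean(self):
        table = pd.DataFrame({"gene_id": "g", "state": "ES",
                              "p_deloc": [0.5, 0.5], "delta": [1.0, 3.0]})
        res = combine_and_classify(table)
        assert res["delta"].iloc[0] == pytest.approx(2.0)
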