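"""Differential engine: size factors, filters, NB GLM, and the 3 analyses."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from chartographer.contacts import BinScheme, ContactMatrix
from chartographer.differential import (DesignSpec, InteractionCountTable,
                                        InteractionModel, build_design,
                                        build_interaction_table,
                                        chromatin_association,
                                        estimate_size_factors,
                                        expression_only_map,
                                        flag_model_deviations,
                                        flag_relocalization)
from chartographer.genome import GenomeLayout


def _table(counts, covariates):
    counts = pd.DataFrame(counts, columns=covariates.index)
    counts.index = pd.MultiIndex.from_arrays(
        [[f"g{i}" for i in range(len(counts))], ["L"] * len(counts)],
        names=["gene_id", "locus"])
    return InteractionCountTable(counts, covariates)


def _maps(count_arrays, genome=None):
    genome = genome or GenomeLayout(("chr1",), (400,))
    scheme = BinScheme(genome, bin_size=100)
    out = {}
    for name, arr in count_arrays.items():
        out[name] = ContactMatrix(sp.csr_matrix(np.asarray(arr)),
                                  pd.Index([f"R{i}" for i in range(len(arr))]),
                                  scheme, sample_id=name)
    return out


class TestSizeFactors:
    def test_median_of_ratios_arithmetic(self):
        counts = pd.DataFrame([[2, 4], [3, 6], [10, 20]], columns=["a", "b"])
        sf = estimate_size_factors(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame([[5, 5], [9, 9]], columns=["a", "b"])
        np.testing.assert_allclose(estimate_size_factors(counts), [1.0, 1.0])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 3)) + 1,
                              columns=list("abc"))
        sf = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["b"] *= 3
        sf2 = estimate_size_factors(scaled)
        # ratio of b's factor to the others triples
        assert (sf2["b"] / sf2["a"]) / (sf["b"] / sf["a"]) == pytest.approx(3.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(30, size=(50, 4)) + 1)
        perm = counts.sample(frac=1, random_state=2)
        np.testing.assert_allclose(estimate_size_factors(counts),
                                   estimate_size_factors(perm))

    def test_matches_pydeseq2_reference(self):
        """Independent oracle: DESeq2's median-of-ratios as implemented in
        pydeseq2 on a random count table."""
        from pydeseq2.preprocessing import deseq2_norm
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(40, size=(200, 6)) + 1)
        # pydeseq2 expects samples as rows
        _, ref = deseq2_norm(counts.T)
        sf = estimate_size_factors(counts)
        # same up to the geometric-mean-1 rescale
        ref = np.asarray(ref, dtype=float).ravel()
        ref = ref / np.exp(np.mean(np.log(ref)))
        np.testing.assert_allclose(sf.to_numpy(), ref, rtol=1e-10)

    def test_no_all_positive_rows_errors(self):
        counts = pd.DataFrame([[0, 5], [3, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="positive in every sample"):
            estimate_size_factors(counts)


class TestInteractionTable:
    def test_min_count_filter_rules(self):
        maps = _maps({f"s{i}": [[0, 0, 0, 0]] for i in range(4)})
        arrs = {"s0": [[12, 9, 0, 0]], "s1": [[3, 9, 0, 0]],
                "s2": [[10, 9, 0, 0]], "s3": [[0, 9, 0, 0]]}
        maps = _maps(arrs)
        cov = pd.DataFrame({"cell": ["ES", "ES", "DE", "DE"]},
                           index=list(arrs))
        table = build_interaction_table(maps, cov, min_count=10, min_samples=2)
        loci = table.counts.index.get_level_values("locus")
        # bin 0: counts [12, 3, 10, 0] -> >=10 in 2 samples -> retained
        # bin 1: counts [9, 9, 9, 9] -> excluded
        assert len(table.counts) == 1
        assert table.counts.iloc[0].tolist() == [12, 3, 10, 0]
        assert table.n_filtered == 1

    def test_empty_maps_give_empty_table(self):
        maps = _maps({"s0": [[0, 0, 0, 0]], "s1": [[0, 0, 0, 0]]})
        cov = pd.DataFrame({"cell": ["ES", "DE"]}, index=["s0", "s1"])
        table = build_interaction_table(maps, cov)
        assert len(table.counts) == 0

    def test_missing_covariates_error(self):
        maps = _maps({"s0": [[11, 11, 0, 0]], "s1": [[11, 11, 0, 0]]})
        cov = pd.DataFrame({"cell": ["ES"]}, index=["s0"])
        with pytest.raises(ValueError, match="without covariates"):
            build_interaction_table(maps, cov)


class TestExpressionOnlyMap:
    def test_row_constant_with_total(self):
        maps = _maps({"s": [[3, 0, 4, 0], [0, 0, 0, 0]]})
        em = expression_only_map(maps["s"])
        dense = np.asarray(em.counts.todense())
        assert (dense[0] == 7).all()
        assert (dense[1] == 0).all()

    def test_row_constancy_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            arr = rng.poisson(2, size=(5, 4))
            em = expression_only_map(_maps({"s": arr})["s"])
            dense = np.asarray(em.counts.todense())
            assert (dense.max(axis=1) == dense.min(axis=1)).all()
            assert (dense[:, 0] == arr.sum(axis=1)).all()


class TestDesign:
    def test_singular_design_rejected(self):
        cov = pd.DataFrame({"cell": ["ES", "DE"]}, index=["a", "b"])
        cov["dup"] = cov["cell"]      # perfectly collinear factor
        with pytest.raises(ValueError, match="singular"):
            build_design(cov, DesignSpec(("cell", "dup"), "cell[ES]",
                                         reference={"cell": "DE", "dup": "DE"}))

    def test_reference_switch_changes_columns(self):
        cov = pd.DataFrame({"cell": ["ES", "DE"]}, index=["a", "b"])
        spec = DesignSpec(("cell",), "cell[ES]", reference={"cell": "DE"})
        X, names = build_design(cov, spec)
        assert names == ["Intercept", "cell[ES]"]
        spec2 = DesignSpec(("cell",), "cell[DE]", reference={"cell": "ES"})
        X2, names2 = build_design(cov, spec2)
        assert names2 == ["Intercept", "cell[DE]"]


class TestNBEngine:
    def test_identical_counts_give_zero_lfc(self):
        cov = pd.DataFrame({"cell": ["ES", "ES", "DE", "DE"]},
                           index=list("abcd"))
        table = _table(np.full((10, 4), 5), cov)
        res = InteractionModel(table, DesignSpec(("cell",), "cell[ES]",
                                                 reference={"cell": "DE"}),
                               size_factors=pd.Series(1.0, index=list("abcd"))
                               ).fit()
        np.testing.assert_allclose(res.frame["lfc"], 0.0, atol=1e-8)

    def test_all_zero_rows_are_na(self):
        cov = pd.DataFrame({"cell": ["ES", "DE"]}, index=list("ab"))
        counts = np.array([[5, 5], [0, 0]])
        table = _table(counts, cov)
        res = InteractionModel(table, DesignSpec(("cell",), "cell[ES]",
                                                 reference={"cell": "DE"}),
                               size_factors=pd.Series(1.0, index=list("ab"))
                               ).fit()
        assert np.isnan(res.frame["pvalue"].iloc[1])

    def test_planted_fourfold_lfc_recovered(self):
        rng = np.random.default_rng(5)
        disp, n_rows = 0.1, 2000
        Y = np.column_stack([
            rng.negative_binomial(1 / disp, 1 / (1 + disp * 400), size=(n_rows, 2)),
            rng.negative_binomial(1 / disp, 1 / (1 + disp * 100), size=(n_rows, 2)),
        ])
        cov = pd.DataFrame({"cell": ["ES", "ES", "DE", "DE"]}, index=list("abcd"))
        res = InteractionModel(_table(Y, cov),
                               DesignSpec(("cell",), "cell[ES]",
                                          reference={"cell": "DE"}),
                               size_factors=pd.Series(1.0, index=list("abcd"))
                               ).fit()
        assert 1.8 <= res.frame["lfc"].median() <= 2.2

    def test_shrunken_lfc_moves_toward_zero(self):
        rng = np.random.default_rng(6)
        disp = 0.05
        Y = np.column_stack([
            rng.negative_binomial(1 / disp, 1 / (1 + disp * 200), size=(500, 2)),
            rng.negative_binomial(1 / disp, 1 / (1 + disp * 100), size=(500, 2)),
        ])
        cov = pd.DataFrame({"cell": ["ES", "ES", "DE", "DE"]}, index=list("abcd"))
        res = InteractionModel(_table(Y, cov),
                               DesignSpec(("cell",), "cell[ES]",
                                          reference={"cell": "DE"}),
                               size_factors=pd.Series(1.0, index=list("abcd"))
                               ).fit()
        f = res.frame.dropna()
        assert (f["lfc_shrunk"].abs() <= f["lfc"].abs() + 1e-12).all()


class TestAnalyses:
    def test_observed_identical_to_model_yields_no_flags(self):
        rng = np.random.default_rng(7)
        arr = rng.poisson(30, size=(3, 4))
        observed = _maps({"ES_rep1": arr, "ES_rep2": arr,
                          "DE_rep1": arr, "DE_rep2": arr})
        model = _maps({"ES_rep1": arr, "ES_rep2": arr,
                       "DE_rep1": arr, "DE_rep2": arr})
        states = {"ES_rep1": "ES", "ES_rep2": "ES",
                  "DE_rep1": "DE", "DE_rep2": "DE"}
        flags, per_rna = flag_model_deviations(observed, model, states)
        assert not flags["flagged"].any()
        assert (per_rna["n_flagged"] == 0).all()

    def test_uniform_scaling_between_states_yields_no_relocalization(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(40, size=(3, 4))
        observed = _maps({"ES_rep1": base, "ES_rep2": base,
                          "DE_rep1": base * 3, "DE_rep2": base * 3})
        expr = {s: expression_only_map(m) for s, m in observed.items()}
        states = {"ES_rep1": "ES", "ES_rep2": "ES",
                  "DE_rep1": "DE", "DE_rep2": "DE"}
        res = flag_relocalization(observed, expr, states)
        assert not res["flagged"].any()

    def test_chromatin_association_null_gene_unlabeled(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(200)]
        mu = rng.uniform(20, 200, size=200)
        char = pd.DataFrame({f"char_{s}_{r}": rng.poisson(mu)
                             for s in ("ES", "DE") for r in (1, 2)}, index=genes)
        rna = pd.DataFrame({f"rna_{s}_{r}": rng.poisson(mu)
                            for s in ("ES", "DE") for r in (1, 2)}, index=genes)
        res = chromatin_association(
            char, rna,
            {c: ("ES" if "_ES_" in c else "DE") for c in char.columns},
            {c: ("ES" if "_ES_" in c else "DE") for c in rna.columns})
        assert (res["label_ES"] == "none").mean() > 0.95
        assert res["score_ES"].abs().median() < 0.5

    def test_low_count_genes_excluded(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(50)] + ["tiny"]
        mu = np.append(rng.uniform(50, 100, size=50), 0.2)
        char = pd.DataFrame({f"char_{s}_{r}": rng.poisson(mu)
                             for s in ("ES", "DE") for r in (1, 2)}, index=genes)
        rna = pd.DataFrame({f"rna_{s}_{r}": rng.poisson(mu)
                            for s in ("ES", "DE") for r in (1, 2)}, index=genes)
        res = chromatin_association(
            char, rna,
            {c: ("ES" if "_ES_" in c else "DE") for c in char.columns},
            {c: ("ES" if "_ES_" in c else "DE") for c in rna.columns},
            min_total=10)
        assert "tiny" not in res.index
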