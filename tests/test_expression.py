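"""Count filtering, CPM, tau specificity, and NB QL differential expression."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genome_workbench import expression as ex, synthetic as syn


def _meta(tissues, conditions, reps):
    rows = []
    for t in tissues:
        for c in conditions:
            for r in range(reps[c] if isinstance(reps, dict) else reps):
                rows.append((f"{t}_{c}_r{r}", t, c))
    return pd.DataFrame(rows, columns=["sample", "tissue", "condition"]
                        ).set_index("sample")


class TestFilterCounts:
    def test_length_filter_is_strict(self):
        meta = _meta(["t1"], ["c1", "c2"], 2)
        counts = pd.DataFrame(20, index=["g199", "g200"],
                              columns=meta.index)
        lengths = pd.Series({"g199": 199, "g200": 200})
        out = ex.filter_counts(counts, meta, lengths)
        assert list(out.index) == ["g200"]

    def test_low_expression_rule_with_unbalanced_conditions(self):
        # conditions of 4 and 2 replicates -> X = 2: a gene needs >= 2
        # samples with counts >= 10 to survive
        meta = _meta(["t1"], ["c1", "c2"], {"c1": 4, "c2": 2})
        counts = pd.DataFrame(
            [[12, 11, 0, 0, 0, 0],
             [12, 0, 0, 0, 0, 0],
             [9, 9, 9, 9, 9, 9],
             [10, 0, 0, 0, 10, 0],
             [0, 0, 0, 0, 0, 0]],
            index=list("abcde"), columns=meta.index)
        lengths = pd.Series(1000, index=counts.index)
        out = ex.filter_counts(counts, meta, lengths)
        assert list(out.index) == ["a", "d"]

    def test_empty_matrix_passes_through(self):
        meta = _meta(["t1"], ["c1", "c2"], 2)
        counts = pd.DataFrame(columns=meta.index)
        lengths = pd.Series(dtype=int)
        assert ex.filter_counts(counts, meta, lengths).empty

    def test_filter_returns_submatrix_without_value_changes(self):
        spec = syn.CountsSpec(n_genes=500)
        counts, lengths, meta, _ = syn.gen_counts(spec, seed=1)
        out = ex.filter_counts(counts, meta, lengths)
        assert set(out.index) <= set(counts.index)
        pd.testing.assert_frame_equal(out, counts.loc[out.index])


class TestCpm:
    def test_single_sample_arithmetic(self):
        counts = pd.DataFrame({"s": [1, 3]}, index=["g1", "g2"])
        out = ex.cpm(counts)
        assert out["s"].tolist() == [250_000.0, 750_000.0]

    def test_all_zero_gene_finite_under_log(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 7]}, index=["g0", "g1"])
        out = ex.cpm(counts, log=True, prior=0.5)
        assert np.isfinite(out.loc["g0"]).all()
        assert (out.loc["g0"] == -1.0).all()  # log2(0.5)

    def test_scale_invariance_per_sample(self):
        counts = pd.DataFrame({"s1": [5, 15, 30], "s2": [1, 2, 3]})
        doubled = counts.copy()
        doubled["s1"] *= 2
        pd.testing.assert_frame_equal(ex.cpm(counts), ex.cpm(doubled))


class TestTau:
    def _tau_of_means(self, means):
        meta = _meta([f"t{i}" for i in range(len(means))], ["c1"], 1)
        expr = pd.DataFrame([means], index=["g"], columns=meta.index)
        return ex.tau(expr, meta).loc["g", "tau"]

    def test_single_tissue_expression_gives_one(self):
        assert self._tau_of_means([10, 0, 0]) == 1.0

    def test_uniform_expression_gives_zero(self):
        assert self._tau_of_means([7, 7, 7]) == 0.0

    def test_worked_example(self):
        # means (10, 5, 1): x = (1, .5, .1), tau = (0 + .5 + .9) / 2 = 0.70
        assert self._tau_of_means([10, 5, 1]) == pytest.approx(0.70)

    def test_single_tissue_design_rejected(self):
        meta = _meta(["t1"], ["c1"], 2)
        expr = pd.DataFrame([[1, 2]], index=["g"], columns=meta.index)
        with pytest.raises(ValueError):
            ex.tau(expr, meta)

    def test_all_zero_gene_flagged_undefined(self):
        meta = _meta(["t1", "t2"], ["c1"], 2)
        expr = pd.DataFrame([[0, 0, 0, 0], [1, 1, 2, 2]], index=["g0", "g1"],
                            columns=meta.index)
        out = ex.tau(expr, meta)
        assert out.loc["g0", "undefined"]
        assert np.isnan(out.loc["g0", "tau"])
        assert not out.loc["g1", "undefined"]

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2,
                    max_size=6))
    def test_tau_bounded_in_unit_interval(self, means):
        if max(means) <= 0:
            return
        t = self._tau_of_means(means)
        assert -1e-12 <= t <= 1 + 1e-12

    def test_invariant_to_tissue_library_scaling(self):
        spec = syn.CountsSpec(n_genes=300)
        counts, lengths, meta, _ = syn.gen_counts(spec, seed=2)
        scaled = counts.copy()
        t1 = meta.index[meta["tissue"] == meta["tissue"].iloc[0]]
        scaled[t1] = scaled[t1] * 3  # uniform depth change in one tissue
        a = ex.tau(ex.cpm(counts), meta)["tau"]
        b = ex.tau(ex.cpm(scaled), meta)["tau"]
        pd.testing.assert_series_equal(a, b)


class TestAssignSpecificity:
    def _assign(self, means):
        meta = _meta([f"t{i}" for i in range(len(means))], ["c1"], 1)
        expr = pd.DataFrame([means], index=["g"], columns=meta.index)
        return ex.assign_specificity(ex.tau(expr, meta))

    def test_threshold_is_inclusive(self):
        # means (10, 1, 0): tau = (0 + 0.9 + 1) / 2 = 0.95 exactly -> assigned
        out = self._assign([10, 1, 0])
        assert out.loc["g", "tau"] >= 0.95
        assert out.loc["g", "assigned_tissue"] == "t0"

    def test_just_below_threshold_not_assigned(self):
        out = self._assign([10, 1.02, 0])  # tau = 0.949
        assert out.loc["g", "tau"] < 0.95
        assert out.loc["g", "assigned_tissue"] is None

    def test_argmax_tie_left_unassigned(self):
        out = self._assign([10, 10, 0])
        assert out.loc["g", "max_tie"]
        assert out.loc["g", "assigned_tissue"] is None

    def test_planted_specific_genes_recovered(self):
        spec = syn.CountsSpec(n_genes=3000, tissue_specific_fraction=0.05,
                              specificity_fold=50, dispersion=0.1,
                              n_replicates=4)
        counts, lengths, meta, truth = syn.gen_counts(spec, seed=5)
        filt = ex.filter_counts(counts, meta, lengths)
        tab = ex.assign_specificity(ex.tau(ex.cpm(filt), meta))
        tg = pd.DataFrame(truth.genes).set_index("gene")
        called = set(tab.index[tab["assigned_tissue"].notna()])
        true_set = set(tg.index[tg["tissue_specific"]]) & set(filt.index)
        inter = called & true_set
        assert len(inter) / len(true_set) >= 0.95   # recall
        assert len(inter) / len(called) >= 0.90     # precision
        # assigned tissue matches the planted one
        hits = tab.loc[sorted(inter), "assigned_tissue"]
        assert (hits == tg.loc[sorted(inter), "specific_tissue"]).all()


class TestDETest:
    def test_identical_groups_give_null_result(self):
        meta = _meta(["t1"], ["c1", "c2"], 3)
        base = [50, 80, 20, 400, 7]
        counts = pd.DataFrame({s: base for s in meta.index},
                              index=[f"g{i}" for i in range(5)])
        res = ex.de_test(counts, meta, "t1")
        assert (res["log2fc"] == 0).all()
        assert (res["pvalue"] > 0.99).all()

    def test_fewer_than_two_replicates_rejected(self):
        meta = _meta(["t1"], ["c1", "c2"], {"c1": 3, "c2": 1})
        counts = pd.DataFrame(10, index=["g1"], columns=meta.index)
        with pytest.raises(ValueError):
            ex.de_test(counts, meta, "t1")

    def test_null_type_i_error_calibrated(self):
        fracs = []
        for seed in range(3):
            spec = syn.CountsSpec(n_genes=2000, tissues=("t1",),
                                  tissue_specific_fraction=0.0,
                                  de_fraction=0.0, dispersion=0.1,
                                  n_replicates=4)
            counts, _, meta, _ = syn.gen_counts(spec, seed=seed)
            res = ex.de_test(counts, meta, "t1")
            fracs.append((res["pvalue"] < 0.01).mean())
        assert 0.005 <= np.mean(fracs) <= 0.02

    def test_power_and_lfc_recovery(self):
        spec = syn.CountsSpec(n_genes=2000, tissues=("t1",),
                              tissue_specific_fraction=0.0, de_fraction=0.1,
                              de_log2fc=2.0, dispersion=0.1, n_replicates=4)
        counts, _, meta, truth = syn.gen_counts(spec, seed=7)
        res = ex.de_test(counts, meta, "t1")
        tg = pd.DataFrame(truth.genes).set_index("gene")
        de_true = tg.index[tg["de"]]
        assert res.loc[de_true, "de"].mean() >= 0.8
        strong = res.loc[de_true].query("mean_count >= 50")
        bias = (strong["log2fc"]
                - tg.loc[strong.index, "true_log2fc"]).mean()
        assert abs(bias) <= 0.1

    def test_agrees_with_edger_reference(self, tmp_path):
        """Independent oracle: the same matrix through edgeR's QL pipeline."""
        spec = syn.CountsSpec(n_genes=300, tissues=("t1",),
                              tissue_specific_fraction=0.0, de_fraction=0.2,
                              de_log2fc=1.5, dispersion=0.1)
        counts, _, meta, _ = syn.gen_counts(spec, seed=21)
        counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        meta.to_csv(tmp_path / "meta.tsv", sep="\t")
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent("""\
            suppressMessages(library(edgeR))
            counts <- read.delim("counts.tsv", row.names=1)
            meta <- read.delim("meta.tsv", row.names=1)
            y <- DGEList(counts=counts, group=factor(meta$condition))
            y <- calcNormFactors(y)
            design <- model.matrix(~factor(meta$condition))
            y <- estimateDisp(y, design)
            fit <- glmQLFit(y, design)
            tab <- topTags(glmQLFTest(fit, coef=2), n=Inf,
                           sort.by="none")$table
            write.table(tab, "edger.tsv", sep="\t", quote=FALSE)
        """))
        subprocess.run(["Rscript", script.name], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "edger.tsv", sep="\t", index_col=0)
        mine = ex.de_test(counts, meta, "t1")
        assert np.corrcoef(mine["log2fc"], ref["logFC"])[0, 1] > 0.99
        logp = np.corrcoef(np.log10(mine["pvalue"] + 1e-12),
                           np.log10(ref["PValue"] + 1e-12))[0, 1]
        assert logp > 0.9
        agree = ((mine["pvalue"] < 0.01) == (ref["PValue"] < 0.01)).mean()
        assert agree >= 0.95


class TestOverlapSummary:
    def _specific(self, genes_by_tissue, universe):
        rows = []
        for g in universe:
            t = next((t for t, gs in genes_by_tissue.items() if g in gs), None)
            rows.append((g, 0.99 if t else 0.1, t))
        df = pd.DataFrame(rows, columns=["gene", "tau", "assigned_tissue"]
                          ).set_index("gene")
        return df

    def test_disjoint_sets_overlap_zero(self):
        spec = self._specific({"t1": {"g1", "g2"}}, [f"g{i}" for i in range(6)])
        out = ex.overlap_summary(spec, {"g5"})
        assert (out["n_overlap"] == 0).all()

    def test_identical_sets_overlap_one(self):
        spec = self._specific({"t1": {"g1", "g2"}}, ["g1", "g2", "g3"])
        out = ex.overlap_summary(spec, {"g1", "g2"})
        row = out[out["tissue"] == "t1"].iloc[0]
        assert row["overlap_fraction"] == 1.0

    def test_independent_sets_overlap_near_product(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(4000)]
        spec_genes = set(rng.choice(universe, 400, replace=False))
        de_genes = set(rng.choice(universe, 800, replace=False))
        spec = self._specific({"t1": spec_genes}, universe)
        out = ex.overlap_summary(spec, de_genes)
        row = out[out["tissue"] == "t1"].iloc[0]
        expected = len(de_genes) / len(universe)
        sigma = np.sqrt(expected * (1 - expected) / len(spec_genes))
        assert abs(row["overlap_fraction"] - expected) < 4 * sigma


def test_zscore_matrix_rows_standardized():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.normal(5, 2, size=(20, 8)))
    z = ex.zscore_matrix(m)
    assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(z.std(axis=1), 1, atol=1e-12)
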