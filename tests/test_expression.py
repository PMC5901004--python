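"""RPKM, expression filter, TMM, sex-bias classification and summaries."""

import numpy as np
import pandas as pd
import pytest

from salixevol.expression import (
    ExpressionTable,
    classify_sex_bias,
    compute_rpkm,
    cross_class_contrast,
    expression_summaries,
    fc_class,
    filter_expressed,
    tmm_normalize,
)
from salixevol.simulate import SimulationConfig, simulate_expression


def make_table(counts: dict, lengths: dict, meta_rows: list) -> ExpressionTable:
    lengths = pd.Series(lengths)
    df = pd.DataFrame(counts)
    df.index = lengths.index[: len(df)]
    meta = pd.DataFrame(meta_rows, columns=["sample", "sex", "tissue", "individual"]).set_index("sample")
    return ExpressionTable(df, lengths, meta)


def six_sample_meta(tissue="catkin"):
    return [(f"{s}{i}", s, tissue, f"{s}{i}") for s in "MF" for i in (1, 2, 3)]


class TestRPKM:
    def test_definition(self):
        tab = make_table(
            {"M1": [10, 999990]},
            {"g1": 1000, "g2": 1000},
            [("M1", "M", "catkin", "M1"), ],
        )
        rpkm = compute_rpkm(tab)
        assert rpkm.loc["g1", "M1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        tab = make_table({"M1": [0, 100]}, {"g1": 500, "g2": 500},
                         [("M1", "M", "catkin", "M1")])
        assert compute_rpkm(tab).loc["g1", "M1"] == 0.0

    def test_scale_invariance_within_sample(self):
        counts = {"M1": [5, 20, 75]}
        tab1 = make_table(counts, {"g1": 100, "g2": 200, "g3": 300}, [("M1", "M", "catkin", "M1")])
        tab2 = make_table({"M1": [10, 40, 150]}, {"g1": 100, "g2": 200, "g3": 300},
                          [("M1", "M", "catkin", "M1")])
        pd.testing.assert_frame_equal(compute_rpkm(tab1), compute_rpkm(tab2))

    def test_zero_library_names_sample(self):
        tab = make_table({"M1": [0, 0], "M2": [1, 1]}, {"g1": 100, "g2": 100},
                         [("M1", "M", "catkin", "M1"), ("M2", "M", "catkin", "M2")])
        with pytest.raises(ValueError, match="M1"):
            compute_rpkm(tab)


class TestExpressionFilter:
    meta = pd.DataFrame(six_sample_meta(), columns=["sample", "sex", "tissue", "individual"]).set_index("sample")

    def rpkm_frame(self, male, female):
        return pd.DataFrame(
            [list(male) + list(female)],
            index=["g1"],
            columns=["M1", "M2", "M3", "F1", "F2", "F3"],
        )

    def test_two_of_three_males_suffice(self):
        rpkm = self.rpkm_frame((2.5, 2.1, 0.5), (0, 0, 0))
        assert "g1" in filter_expressed(rpkm, self.meta, "catkin")

    def test_below_threshold_everywhere_removed(self):
        rpkm = self.rpkm_frame((1.9,) * 3, (1.9,) * 3)
        assert len(filter_expressed(rpkm, self.meta, "catkin")) == 0

    def test_threshold_is_inclusive(self):
        rpkm = self.rpkm_frame((2.0, 2.0, 0.0), (0, 0, 0))
        assert "g1" in filter_expressed(rpkm, self.meta, "catkin")


class TestTMM:
    def base_table(self, b_scale=1.0, spike=None, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.poisson(rng.lognormal(4, 1, size=400)) + 1
        b = (a * b_scale).astype(int)
        if spike is not None:
            b = b.copy()
            idx = rng.choice(len(b), size=int(spike * len(b)), replace=False)
            b[idx] *= 10
        counts = {"S1": a, "S2": b}
        meta = [("S1", "M", "catkin", "M1"), ("S2", "F", "catkin", "F1")]
        lengths = pd.Series(500, index=pd.RangeIndex(400).astype(str))
        df = pd.DataFrame(counts); df.index = lengths.index
        return ExpressionTable(df, lengths,
                               pd.DataFrame(meta, columns=["sample", "sex", "tissue", "individual"]).set_index("sample"))

    def test_identical_samples_give_unit_factors(self):
        tab = self.base_table(1.0)
        f = tmm_normalize(tab, "catkin")
        assert np.allclose(f.values, 1.0, atol=1e-9)

    def test_pure_depth_difference_gives_equal_factors(self):
        tab = self.base_table(2.0)
        f = tmm_normalize(tab, "catkin")
        assert f["S1"] == pytest.approx(f["S2"], rel=1e-6)

    def test_trimming_absorbs_spiked_genes(self):
        # spiking 5% of S2's genes 10-fold inflates its library size; the
        # trimmed M-mean must pull the *effective* library size (lib x factor)
        # back so unspiked genes stay comparable across samples
        tab0, tab1 = self.base_table(1.0), self.base_table(1.0, spike=0.05)
        f0 = tmm_normalize(tab0, "catkin")
        f1 = tmm_normalize(tab1, "catkin")
        eff0 = tab0.counts.sum() * f0
        eff1 = tab1.counts.sum() * f1
        ratio0 = eff0["S2"] / eff0["S1"]
        ratio1 = eff1["S2"] / eff1["S1"]
        assert abs(ratio1 / ratio0 - 1) < 0.05

    def test_factors_match_edger_reference(self, tmp_path):
        # independent oracle: edgeR's calcNormFactors on the same matrix
        import subprocess

        rng = np.random.default_rng(8)
        n = 300
        base = rng.lognormal(4, 1, n)
        counts = pd.DataFrame({
            "S1": rng.poisson(base * 1.0), "S2": rng.poisson(base * 1.7),
            "S3": rng.poisson(base * 0.6), "S4": rng.poisson(base * 1.2),
        }).astype(int)
        counts.index = [f"g{i}" for i in range(n)]
        meta = pd.DataFrame(
            {"sample": ["S1", "S2", "S3", "S4"], "sex": ["M", "M", "F", "F"],
             "tissue": "catkin", "individual": list("abcd")}).set_index("sample")
        tab = ExpressionTable(counts, pd.Series(500, index=counts.index), meta)
        f = tmm_normalize(tab, "catkin")
        path = tmp_path / "c.tsv"
        counts.to_csv(path, sep="\t")
        r = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(edgeR)); '
             f'x<-as.matrix(read.delim("{path}",row.names=1)); '
             'cat(calcNormFactors(x, method="TMM"))'],
            capture_output=True, text=True, timeout=120,
        )
        ref = np.array([float(v) for v in r.stdout.split()])
        assert np.allclose(f.values, ref, atol=0.01)

    def test_all_zero_sample_errors(self):
        tab = self.base_table(1.0)
        tab.counts["S2"] = 0
        with pytest.raises(ValueError):
            tmm_normalize(tab, "catkin")


class TestClassification:
    def test_injected_strong_bias_called_mb(self):
        rng = np.random.default_rng(5)
        n = 400
        base = rng.lognormal(5, 0.5, n)
        counts = {}
        for s, sex, _, _ in six_sample_meta():
            mu = base.copy()
            if sex == "M":
                mu[0] *= 8  # injected log2FC = +3 on gene 0
            counts[s] = rng.poisson(mu)
        tab = make_table(counts, pd.Series(300, index=pd.RangeIndex(n).astype(str)),
                         six_sample_meta())
        tab.counts.index = pd.RangeIndex(n).astype(str)
        calls = classify_sex_bias(tab, "catkin")
        assert calls.loc["0", "category"] == "MB"
        assert calls.loc["0", "log2fc"] == pytest.approx(3.0, abs=0.5)

    def test_null_false_positive_rate(self):
        cfg = SimulationConfig(seed=21, n_genes_per_category=1500, sexbias_log2fc=0.0)
        tab = simulate_expression(cfg)
        calls = classify_sex_bias(tab, "catkin")
        assert (calls["category"] != "UB").mean() <= 0.05

    def test_bias_calls_require_both_fold_change_and_significance(self, expression_table):
        calls = classify_sex_bias(expression_table, "catkin")
        biased = calls[calls["category"] != "UB"]
        assert (biased["p_adj"] < 0.05).all()
        assert (biased["log2fc"].abs() > 1).all()
        unbiased = calls[calls["category"] == "UB"]
        assert ((unbiased["p_adj"] >= 0.05) | (unbiased["log2fc"].abs() <= 1)).all()

    def test_sex_swap_maps_mb_to_fb(self, expression_table):
        calls = classify_sex_bias(expression_table, "catkin")
        meta_sw = expression_table.sample_meta.copy()
        meta_sw["sex"] = meta_sw["sex"].map({"M": "F", "F": "M"})
        swapped = ExpressionTable(expression_table.counts, expression_table.gene_length_bp, meta_sw)
        calls_sw = classify_sex_bias(swapped, "catkin")
        assert np.allclose(calls["log2fc"], -calls_sw["log2fc"], atol=1e-9)
        assert (calls["category"].map({"MB": "FB", "FB": "MB", "UB": "UB"})
                == calls_sw["category"]).all()

    def test_bh_adjustment_properties(self, expression_table):
        calls = classify_sex_bias(expression_table, "catkin")
        assert (calls["p_adj"] >= calls["p"] - 1e-12).all()
        s = calls.sort_values("p")
        assert s["p_adj"].is_monotonic_increasing or np.all(np.diff(s["p_adj"]) >= -1e-12)

    def test_partition_exhaustive_and_disjoint(self, expression_table):
        calls = classify_sex_bias(expression_table, "catkin")
        assert set(calls["category"]) <= {"MB", "FB", "UB"}
        assert calls["category"].notna().all()


def test_fc_class_boundaries():
    assert [fc_class(x) for x in (-3.0, -2.9, -1.0, -0.99, 0.99, 1.0, 2.99, 3.0)] == [
        "FB_high", "FB_low", "FB_low", "UB", "UB", "MB_low", "MB_low", "MB_high"
    ]


class TestSummaries:
    def test_identical_expression_high_p(self):
        rng = np.random.default_rng(2)
        rpkm = pd.DataFrame(
            np.tile(rng.lognormal(2, 1, 50)[:, None], (1, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=["M1", "M2", "M3", "F1", "F2", "F3"],
        )
        meta = pd.DataFrame(six_sample_meta(), columns=["sample", "sex", "tissue", "individual"]).set_index("sample")
        calls = pd.DataFrame({"fc_class": ["UB"] * 50, "category": ["UB"] * 50},
                             index=rpkm.index)
        out = expression_summaries(calls, rpkm, meta, "catkin")
        assert out.loc[0, "wilcoxon_p"] > 0.99
        assert out.loc[0, "mean_male"] == pytest.approx(out.loc[0, "mean_female"])

    def test_single_gene_class_flagged_untested(self):
        rpkm = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g1"],
                            columns=["M1", "M2", "M3", "F1", "F2", "F3"])
        meta = pd.DataFrame(six_sample_meta(), columns=["sample", "sex", "tissue", "individual"]).set_index("sample")
        calls = pd.DataFrame({"fc_class": ["MB_high"], "category": ["MB"]}, index=["g1"])
        out = expression_summaries(calls, rpkm, meta, "catkin")
        assert not out.loc[0, "tested"]

    def test_injected_bias_separates_class_means(self, expression_table, truth):
        from salixevol.expression import compute_rpkm
        calls = classify_sex_bias(expression_table, "catkin")
        rpkm = compute_rpkm(expression_table)
        cats = pd.Series(truth.categories)
        mb_calls = calls[cats.reindex(calls.index) == "MB"]
        out = expression_summaries(mb_calls.assign(fc_class="MB"), rpkm,
                                   expression_table.sample_meta, "catkin")
        assert out.loc[0, "mean_male"] > out.loc[0, "mean_female"]
        p = cross_class_contrast(calls, rpkm, expression_table.sample_meta,
                                 "catkin", "MB", "M", "FB", "M")
        assert 0 <= p <= 1
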