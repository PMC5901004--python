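"""Generator contracts: ground-truth consistency, determinism, edge configs."""

import numpy as np
import pandas as pd
import pytest

from salixevol.genetics import SENSE_CODONS, STOP_CODONS
from salixevol.simulate import (
    FOCAL_TAXON,
    TAXA,
    SimulationConfig,
    replay_tip,
    simulate_expression,
    simulate_ortholog_set,
    simulate_site_table,
    simulate_null_branch_counts,
)


def small_config(**kw):
    base = dict(seed=7, n_genes_per_category=6, gene_length_codons=60)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_negative_branch_length(self):
        with pytest.raises(ValueError, match="branch lengths"):
            small_config(branch_lengths={"S.viminalis": -0.1})

    def test_rejects_saturating_focal_branch(self):
        bl = dict(SimulationConfig().branch_lengths)
        bl["S.viminalis"] = 7.0  # expected d_S ~ 7/3 > 2
        with pytest.raises(ValueError, match="saturation"):
            small_config(branch_lengths=bl)

    def test_rejects_single_individual(self):
        with pytest.raises(ValueError, match="individuals"):
            small_config(n_individuals_per_sex=1)

    def test_rejects_nonpositive_dispersion(self):
        with pytest.raises(ValueError, match="dispersion"):
            small_config(nb_dispersion=0.0)


class TestOrthologSet:
    def test_zero_omega_forbids_focal_nonsynonymous(self):
        cfg = small_config(
            n_genes_per_category=10,
            omega_by_category={"MB": 0.0, "UB": 0.2},
        )
        _, truth = simulate_ortholog_set(cfg)
        foc = truth.substitutions.query("branch == @FOCAL_TAXON")
        mb_genes = [g for g, c in truth.categories.items() if c == "MB"]
        mb = foc[foc["gene"].isin(mb_genes)]
        assert len(mb) == 0 or bool(mb["synonymous"].all())

    def test_zero_branch_lengths_give_identical_tips(self):
        cfg = small_config(branch_lengths={b: 0.0 for b in SimulationConfig().branch_lengths})
        alns, truth = simulate_ortholog_set(cfg)
        assert truth.substitutions.empty
        for aln in alns.values():
            seqs = set(aln.seqs.values())
            assert len(seqs) == 1

    def test_replay_reproduces_every_tip(self, alignments, truth):
        for gene in list(alignments)[:8]:
            for taxon in TAXA:
                assert replay_tip(truth, gene, taxon) == alignments[gene].seqs[taxon]

    def test_all_simulated_codons_are_sense(self, alignments):
        for aln in list(alignments.values())[:10]:
            for seq in aln.seqs.values():
                for i in range(0, len(seq), 3):
                    assert seq[i:i + 3] in SENSE_CODONS

    def test_determinism(self):
        cfg1, cfg2 = small_config(), small_config()
        a1, t1 = simulate_ortholog_set(cfg1)
        a2, t2 = simulate_ortholog_set(cfg2)
        assert list(a1) == list(a2)
        for g in a1:
            assert a1[g].seqs == a2[g].seqs
        pd.testing.assert_frame_equal(t1.substitutions, t2.substitutions)

    def test_coordinates_cover_all_genes(self, truth, alignments):
        assert set(truth.gene_coords["gene"]) == set(alignments)


class TestExpression:
    def test_leaf_carries_no_injected_bias(self):
        # strong catkin bias, many genes: catkin M/F means separate, leaf don't
        cfg = small_config(n_genes_per_category=40, sexbias_log2fc=3.0, seed=11)
        tab = simulate_expression(cfg)
        meta = tab.sample_meta
        mb = [g for g, c in dict(cfg.gene_ids()).items() if c == "MB"]
        for tissue, expect_biased in (("catkin", True), ("leaf", False)):
            m = [s for s in tab.counts.columns
                 if meta.loc[s, "tissue"] == tissue and meta.loc[s, "sex"] == "M"]
            f = [s for s in tab.counts.columns
                 if meta.loc[s, "tissue"] == tissue and meta.loc[s, "sex"] == "F"]
            ratio = (tab.counts.loc[mb, m].mean(axis=1) + 1) / (tab.counts.loc[mb, f].mean(axis=1) + 1)
            if expect_biased:
                assert np.log2(ratio).median() > 2.0
            else:
                assert abs(np.log2(ratio).median()) < 0.5

    def test_counts_shape_and_meta(self, expression_table, config):
        n_genes = 3 * config.n_genes_per_category
        assert expression_table.counts.shape == (n_genes, 4 * config.n_individuals_per_sex)
        assert set(expression_table.sample_meta["tissue"]) == {"catkin", "leaf"}


class TestSiteTable:
    def test_low_coverage_fails_downstream_rule(self):
        cfg = small_config(coverage_mean=5.0, seed=3)
        alns, truth = simulate_ortholog_set(cfg)
        table = simulate_site_table(alns, truth, cfg)
        frac_covered = (table["coverage"] >= 20).mean()
        assert frac_covered < 0.01

    def test_zero_snp_rate_gives_empty_truth(self):
        cfg = small_config(snp_rate_per_site=0.0, seed=4)
        alns, truth = simulate_ortholog_set(cfg)
        table = simulate_site_table(alns, truth, cfg)
        assert truth.snps.empty
        assert (table["alt_count"] == 0).all()

    def test_determinism_byte_identical(self):
        cfg = small_config(n_genes_per_category=2, seed=9)
        a1, t1 = simulate_ortholog_set(cfg)
        a2, t2 = simulate_ortholog_set(cfg)
        s1 = simulate_site_table(a1, t1, cfg).to_csv()
        s2 = simulate_site_table(a2, t2, cfg).to_csv()
        assert s1 == s2

    def test_coverage_never_below_allele_counts(self, site_table):
        assert (site_table["coverage"] >= site_table["ref_count"] + site_table["alt_count"]).all()


def test_null_branch_counts_are_exchangeable_shape():
    rng = np.random.default_rng(0)
    df = simulate_null_branch_counts(rng, 50)
    assert list(df.columns) == ["N", "S", "D_N", "D_S"]
    assert (df["N"] + df["S"] == 900).all()
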