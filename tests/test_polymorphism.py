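"""SNP validity rules, classification, and the codon-matching filter."""

import numpy as np
import pandas as pd
import pytest

from salixevol.masking import CodonAlignment
from salixevol.polymorphism import (
    classify_polymorphism,
    filter_snps,
    match_codons,
    mk_input_table,
    site_coverage_ok,
)

INDIVIDUALS = [("M1", "M"), ("M2", "M"), ("M3", "M"), ("F1", "F"), ("F2", "F"), ("F3", "F")]


def site_rows(gene, site, coverages, alt_counts, alt_base="C"):
    """One row per individual for a single site (site is 1-based)."""
    ci, p = divmod(site - 1, 3)
    rows = []
    for (ind, sex), cov, alt in zip(INDIVIDUALS, coverages, alt_counts):
        rows.append({
            "gene": gene, "codon_index": ci + 1, "codon_pos": p + 1, "site": site,
            "individual": ind, "sex": sex, "coverage": cov,
            "ref_count": cov - alt, "alt_count": alt,
            "alt_base": alt_base if any(alt_counts) else ".",
        })
    return rows


class TestFilterSNPs:
    def test_coverage_19_everywhere_rejected(self):
        t = pd.DataFrame(site_rows("g1", 1, [19] * 6, [8] * 6))
        assert len(filter_snps(t)) == 0

    def test_low_maf_rejected(self):
        # pooled MAF 0.15 < 0.20
        t = pd.DataFrame(site_rows("g1", 1, [40] * 6, [6] * 6))
        assert len(filter_snps(t)) == 0

    def test_all_rules_satisfied_accepted(self):
        # coverage 25 in 2/3 males, pooled MAF 0.25, >=3 supporting reads
        covs = [25, 25, 10, 10, 10, 10]
        alts = [12, 11, 2, 0, 0, 0]  # pooled: 25/90
        t = pd.DataFrame(site_rows("g1", 1, covs, alts))
        out = filter_snps(t)
        assert len(out) == 1
        assert out.loc[0, "maf"] == pytest.approx(25 / 90)

    def test_support_below_three_reads_rejected(self):
        covs = [25, 25, 25, 25, 25, 25]
        alts = [2, 0, 0, 0, 0, 0]
        t = pd.DataFrame(site_rows("g1", 1, covs, alts))
        assert len(filter_snps(t)) == 0

    def test_monotone_in_thresholds(self, site_table):
        sub = site_table[site_table["gene"].isin(site_table["gene"].unique()[:10])]
        base = filter_snps(sub, min_cov=20, min_maf=0.20)
        stricter_cov = filter_snps(sub, min_cov=25, min_maf=0.20)
        stricter_maf = filter_snps(sub, min_cov=20, min_maf=0.30)
        base_keys = set(zip(base["gene"], base["site"]))
        assert set(zip(stricter_cov["gene"], stricter_cov["site"])) <= base_keys
        assert set(zip(stricter_maf["gene"], stricter_maf["site"])) <= base_keys

    def test_detected_snps_match_injected_truth(self, site_table, truth):
        found = filter_snps(site_table)
        key = truth.snps.set_index(["gene", "codon_index", "codon_pos"])
        assert len(found) > 0
        for _, row in found.iterrows():
            k = (row["gene"], row["codon_index"], row["codon_pos"])
            assert k in key.index  # no false positives
            assert key.loc[k, "alt_base"] == row["alt_base"]


class TestClassification:
    @pytest.mark.parametrize(
        "codon,pos,alt,label,stop",
        [
            ("GTT", 3, "C", "synonymous", False),     # Val -> Val
            ("GTT", 1, "A", "nonsynonymous", False),  # Val -> Ile
            ("TAT", 3, "A", "nonsynonymous", True),   # Tyr -> stop
        ],
    )
    def test_examples(self, codon, pos, alt, label, stop):
        assert classify_polymorphism(codon, pos, alt) == (label, stop)

    def test_classification_matches_truth_labels(self, site_table, truth, alignments):
        found = filter_snps(site_table)
        key = truth.snps.set_index(["gene", "codon_index", "codon_pos"])
        for _, row in found.iterrows():
            ref = alignments[row["gene"]].seqs["S.viminalis"]
            ci = int(row["codon_index"]) - 1
            codon = ref[3 * ci: 3 * ci + 3]
            label, _ = classify_polymorphism(codon, int(row["codon_pos"]), row["alt_base"])
            truth_syn = bool(key.loc[(row["gene"], row["codon_index"], row["codon_pos"]),
                                     "synonymous"])
            assert (label == "synonymous") == truth_syn


class TestMatchCodons:
    def make_aln(self, n=4):
        seqs = {t: "AAA" * n for t in
                ["S.viminalis", "S.suchowensis", "P.tremula", "P.tremuloides", "P.trichocarpa"]}
        return CodonAlignment("g1", seqs, gap_stripped=True)

    def table_with_coverage(self, per_site_cov: list[int]):
        rows = []
        for site, cov in enumerate(per_site_cov, start=1):
            rows += site_rows("g1", site, [cov] * 6, [0] * 6)
        return pd.DataFrame(rows)

    def test_one_low_coverage_site_excludes_codon(self):
        t = self.table_with_coverage([25, 25, 19] + [25] * 9)
        matched = match_codons(self.make_aln(), t)
        assert not matched[0] and matched[1:].all()

    def test_fully_covered_clean_codon_retained(self):
        t = self.table_with_coverage([25] * 12)
        assert match_codons(self.make_aln(), t).all()

    def test_masked_codon_excluded(self):
        aln = self.make_aln()
        aln.mask["P.tremula"][2] = True
        t = self.table_with_coverage([25] * 12)
        matched = match_codons(aln, t)
        assert not matched[2] and matched[[0, 1, 3]].all()


class TestMatchedCounts:
    def test_shared_site_basis_and_conservation(self, alignments, site_table):
        sub = {g: alignments[g] for g in list(alignments)[:12]}
        mk = mk_input_table(sub, site_table)
        assert len(mk) > 0
        assert np.allclose(mk["N"] + mk["S"], 3 * mk["n_matched_codons"])
        assert np.allclose(mk["p_N"], mk["P_N"] / mk["N"])
        assert np.allclose(mk["p_S"], mk["P_S"] / mk["S"])

    def test_recovered_ratio_tracks_injected_snps(self, alignments, site_table, truth):
        mk = mk_input_table(alignments, site_table)
        pn, ps = mk["P_N"].sum(), mk["P_S"].sum()
        n = pn + ps
        assert n > 0
        # detected composition within binomial error of the injected one
        # (filtering is blind to the syn/nonsyn label)
        p_true = 1.0 - truth.snps["synonymous"].mean()
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(pn / n - p_true) < 4 * se
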