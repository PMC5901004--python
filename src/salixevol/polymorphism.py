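"""SNP validity rules, synonymous/nonsynonymous classification and the
divergence-polymorphism codon-matching filter.

Polymorphism is scored within the focal species' individuals from a per-site,
per-individual table of coverage and allele counts.  A site is a valid SNP
when (a) coverage is at least ``min_cov`` in at least half the individuals of
at least one sex, (b) the pooled minor-allele frequency (read counts pooled
across all individuals at the site) is at least ``min_maf``, and (c) the
alternative allele has at least ``min_reads`` supporting reads.

For McDonald-Kreitman-style contrasts the divergence and polymorphism data
must share a site basis, so both are recomputed over "matched" codons: all
three positions pass the coverage rule, the codon survived gap stripping, and
no taxon is masked or ambiguous there.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from .divergence import focal_branch_substitutions
from .genetics import AA_OF, STOP_CODONS
from .masking import CodonAlignment

FOCAL_TAXON = "S.viminalis"


def site_coverage_ok(table: pd.DataFrame, min_cov: int = 20) -> pd.Series:
    """Per (gene, site): True when coverage >= min_cov in at least
    ceil(n_sex/2) individuals of at least one sex."""
    t = table.assign(covered=table["coverage"] >= min_cov)
    per_sex = t.groupby(["gene", "site", "sex"], sort=False)["covered"].agg(["sum", "count"])
    need = np.ceil(per_sex["count"] / 2)
    ok = (per_sex["sum"] >= need).groupby(level=["gene", "site"]).any()
    ok.name = "coverage_ok"
    return ok


def filter_snps(
    table: pd.DataFrame,
    min_cov: int = 20,
    min_maf: float = 0.20,
    min_reads: int = 3,
) -> pd.DataFrame:
    """Valid SNPs as one row per (gene, site).

    Read counts are pooled across all individuals at the site; the pooled
    minor-allele frequency and alt support are tested against ``min_maf`` and
    ``min_reads``.  (Pooling over all reads — rather than only over
    coverage-passing individuals — keeps the filter monotone: raising any
    threshold can only remove SNPs.)  Returns columns gene, codon_index,
    codon_pos, site, ref_reads, alt_reads, maf, alt_base.
    """
    cov_ok = site_coverage_ok(table, min_cov)
    cand = table[table["alt_base"] != "."]
    if cand.empty:
        return pd.DataFrame(
            columns=["gene", "codon_index", "codon_pos", "site",
                     "ref_reads", "alt_reads", "maf", "alt_base"]
        )
    pooled = cand.groupby(["gene", "site"], sort=False).agg(
        codon_index=("codon_index", "first"),
        codon_pos=("codon_pos", "first"),
        ref_reads=("ref_count", "sum"),
        alt_reads=("alt_count", "sum"),
        alt_base=("alt_base", "first"),
    )
    total = pooled["ref_reads"] + pooled["alt_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(pooled["ref_reads"], pooled["alt_reads"]) / total
    pooled["maf"] = maf.fillna(0.0)
    ok = (
        pooled.index.isin(cov_ok.index[cov_ok])
        & (pooled["maf"] >= min_maf)
        & (pooled["alt_reads"] >= min_reads)
    )
    out = pooled[ok].reset_index()
    return out[["gene", "codon_index", "codon_pos", "site",
                "ref_reads", "alt_reads", "maf", "alt_base"]]


def classify_polymorphism(
    ref_codon: str, codon_pos: int, alt_base: str
) -> tuple[str, bool]:
    """Classify one SNP against its reference codon.

    codon_pos is 1-based within the codon.  Returns (label, stop_flag) with
    label 'synonymous' or 'nonsynonymous'; an alt allele creating a stop codon
    is nonsynonymous with the flag set.  SNPs in codons carrying another
    variant are still classified against the reference codon (each variant
    contributes independently).
    """
    ref_codon = ref_codon.upper()
    if ref_codon in STOP_CODONS or any(ch not in "ACGT" for ch in ref_codon):
        raise ValueError(f"cannot classify SNP in codon {ref_codon}")
    p = codon_pos - 1
    alt_codon = ref_codon[:p] + alt_base.upper() + ref_codon[p + 1:]
    if alt_codon in STOP_CODONS:
        return "nonsynonymous", True
    label = "synonymous" if AA_OF[alt_codon] == AA_OF[ref_codon] else "nonsynonymous"
    return label, False


def match_codons(
    aln: CodonAlignment,
    table: pd.DataFrame,
    min_cov: int = 20,
) -> np.ndarray:
    """Boolean selection of codon columns usable by both analyses.

    A codon is matched when all three of its sites pass the coverage rule and
    the codon column is clean in the alignment (survived gap stripping,
    unmasked and unambiguous in every taxon).
    """
    sub = table[table["gene"] == aln.gene]
    n = aln.n_codons
    ok_sites = np.zeros(3 * n, dtype=bool)
    if not sub.empty:
        cov_ok = site_coverage_ok(sub, min_cov)
        sites = cov_ok.index.get_level_values("site").to_numpy()
        vals = cov_ok.to_numpy()
        in_range = sites <= 3 * n
        ok_sites[sites[in_range] - 1] = vals[in_range]
    codon_cov = ok_sites.reshape(-1, 3).all(axis=1)
    return codon_cov & aln.clean_codon_columns()


def mk_input_table(
    alignments: dict[str, CodonAlignment],
    site_table: pd.DataFrame,
    min_cov: int = 20,
    min_maf: float = 0.20,
    min_reads: int = 3,
    max_ds: float = 2.0,
) -> pd.DataFrame:
    """Per-gene matched divergence and polymorphism counts.

    For every gene, divergence (D_N, D_S) and sites (N, S) are recomputed over
    the matched codon set, and valid SNPs falling in matched codons are
    classified to give P_N and P_S — so the N and S entering d_N/p_N (and
    d_S/p_S) are identical by construction.  Genes with no matched codons or
    with saturated d_S (> max_ds) are excluded.

    Columns: N, S, D_N, D_S, P_N, P_S, p_N, p_S, d_N, d_S, n_matched_codons,
    n_stop_snps.
    """
    snps = filter_snps(site_table, min_cov, min_maf, min_reads)
    rows = []
    for gene, aln in alignments.items():
        matched = match_codons(aln, site_table, min_cov)
        if not matched.any():
            continue
        bc = focal_branch_substitutions(aln, codon_subset=matched)
        if bc.n_codons == 0 or bc.S <= 0:
            continue
        if bc.d_S > max_ds:
            continue
        ref = aln.seqs[FOCAL_TAXON].upper()
        pn = ps = n_stop = 0
        gsnps = snps[snps["gene"] == gene]
        for _, row in gsnps.iterrows():
            ci = int(row["codon_index"]) - 1
            if ci >= aln.n_codons or not matched[ci]:
                continue
            cod = ref[3 * ci: 3 * ci + 3]
            label, stop = classify_polymorphism(cod, int(row["codon_pos"]), row["alt_base"])
            n_stop += stop
            if label == "synonymous":
                ps += 1
            else:
                pn += 1
        rows.append(
            (gene, bc.N, bc.S, bc.D_N, bc.D_S, pn, ps,
             pn / bc.N, ps / bc.S, bc.d_N, bc.d_S, bc.n_codons, n_stop)
        )
    df = pd.DataFrame(
        rows,
        columns=["gene", "N", "S", "D_N", "D_S", "P_N", "P_S",
                 "p_N", "p_S", "d_N", "d_S", "n_matched_codons", "n_stop_snps"],
    ).set_index("gene")
    return df
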