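"""Valid SNPs, syn/nonsyn classification, and the matched count table.

Applies the coverage/MAF/support rules, writes the valid SNPs as a minimal
VCF, and builds the per-gene table in which divergence and polymorphism
share an identical (N, S) site basis — the McDonald-Kreitman input.
"""

import pandas as pd

from common import SCRATCH, ensure_dirs
from salixevol import io
from salixevol.polymorphism import classify_polymorphism, filter_snps, mk_input_table


def main() -> None:
    ensure_dirs()
    indir = SCRATCH / "alignments_masked"
    alignments = {p.stem: io.read_alignment_fasta(p) for p in sorted(indir.glob("*.fasta"))}
    sites = io.read_site_table(SCRATCH / "site_table.tsv")

    snps = filter_snps(sites)
    keep, labels = [], []
    for i, r in snps.iterrows():
        aln = alignments[r["gene"]]
        ci = int(r["codon_index"]) - 1
        codon = aln.masked_seq("S.viminalis")[3 * ci: 3 * ci + 3]
        if any(ch not in "ACGT" for ch in codon):
            continue  # SNP falls in a masked codon: unclassifiable, dropped
        keep.append(i)
        labels.append(classify_polymorphism(codon, int(r["codon_pos"]), r["alt_base"])[0])
    snps = snps.loc[keep].reset_index(drop=True)
    io.write_snps_vcf(snps, pd.Series(labels), SCRATCH / "valid_snps.vcf")

    mk = mk_input_table(alignments, sites)
    mk.to_csv(SCRATCH / "matched_counts_per_gene.tsv", sep="\t")
    pn = mk["P_N"].sum() / mk["N"].sum()
    ps = mk["P_S"].sum() / mk["S"].sum()
    print(f"{len(snps)} valid SNPs ({labels.count('synonymous')} synonymous)")
    print(f"{len(mk)} genes with matched divergence+polymorphism data; "
          f"p_N = {pn:.4f}, p_S = {ps:.4f}, p_N/p_S = {pn / ps:.3f}")


if __name__ == "__main__":
    main()
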