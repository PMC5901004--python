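"""Readers and writers for the pipeline's on-disk formats.

FASTA (one file per ortholog, 5 records), Newick tree files, counts and
sample-metadata TSVs, site-table TSVs, ground-truth TSVs, a BED file for the
nonrecombining region and a minimal VCF for valid SNPs.  All gene-internal
coordinates are 1-based; codon positions run 1-3.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionTable
from .masking import CodonAlignment


def write_alignment_fasta(aln: CodonAlignment, path: str | os.PathLike) -> None:
    """Write one ortholog alignment; masked codons render as NNN."""
    records = [
        SeqRecord(Seq(aln.masked_seq(t)), id=t, description="")
        for t in aln.taxa
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | os.PathLike, gene: str | None = None) -> CodonAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    seqs = {r.id: str(r.seq).upper() for r in records}
    name = gene or Path(path).stem
    aln = CodonAlignment(name, seqs, gap_stripped=not any("-" in s for s in seqs.values()))
    for taxon, seq in seqs.items():
        for i in range(aln.n_codons):
            if seq[3 * i: 3 * i + 3] == "NNN":
                aln.mask[taxon][i] = True
    return aln


def write_ortholog_set(alignments: dict[str, CodonAlignment], outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gene, aln in alignments.items():
        write_alignment_fasta(aln, outdir / f"{gene}.fasta")


def write_tree(newick: str, path: str | os.PathLike) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def write_expression(table: ExpressionTable, counts_path, meta_path, lengths_path=None) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.sample_meta.to_csv(meta_path, sep="\t")
    if lengths_path is not None:
        table.gene_length_bp.rename("length_bp").to_csv(lengths_path, sep="\t")


def read_expression(counts_path, meta_path, lengths_path) -> ExpressionTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)["length_bp"]
    return ExpressionTable(counts, lengths, meta)


def write_site_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"alt_base": str})


def write_bed(intervals: pd.DataFrame, path) -> None:
    """intervals: columns chrom, start, end (0-based half-open)."""
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                       names=["chrom", "start", "end"])


def write_snps_vcf(snps: pd.DataFrame, classifications: pd.Series, path) -> None:
    """Minimal VCF for valid SNPs: CHROM=gene, POS=1-based CDS position.

    ``classifications`` maps (gene, site) rows to 'synonymous'/'nonsynonymous'
    aligned with ``snps`` (filter_snps output, plus a ref base column if
    available).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="SYN or NONSYN">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (_, row), cls in zip(snps.iterrows(), classifications):
            tag = "SYN" if cls == "synonymous" else "NONSYN"
            ref = row.get("ref_base", "N")
            fh.write(
                f"{row['gene']}\t{int(row['site'])}\t.\t{ref}\t{row['alt_base']}"
                f"\t.\tPASS\tCLASS={tag}\n"
            )


def write_ground_truth(truth, subs_path, snps_path=None, coords_path=None) -> None:
    sub = truth.substitutions.copy()
    sub["codon_index"] = sub["codon_index"] + 1  # 1-based on disk
    sub.to_csv(subs_path, sep="\t", index=False)
    if snps_path is not None and truth.snps is not None:
        truth.snps.to_csv(snps_path, sep="\t", index=False)
    if coords_path is not None:
        truth.gene_coords.to_csv(coords_path, sep="\t", index=False)
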