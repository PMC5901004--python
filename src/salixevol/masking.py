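"""Codon-alignment container, gap stripping and two-pass sliding-window masking.

Poorly aligned stretches inflate apparent nonsynonymous divergence, so before
any substitution counting each taxon's sequence is screened with two sliding
windows: a long window (15 codons, mask when more than 7 codons disagree in
amino acid with the column majority) catching exon-boundary misalignment, then
a short window (4 codons, more than 2 disagreements) catching short error
bursts.  Masked codons render as ``NNN`` and are ignored downstream.  After
masking, genes whose clean length falls below 300 bp are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genetics import AA_OF, STOP_CODONS

GAP_CHARS = set("-.")


@dataclass
class CodonAlignment:
    """A codon-aligned ortholog group.

    seqs maps taxon name to an aligned nucleotide string (length divisible by
    3, same length for all taxa).  mask holds, per taxon, a boolean array over
    codon columns; True means the codon is masked and is emitted as NNN.
    """

    gene: str
    seqs: dict[str, str]
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    gap_stripped: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene}: aligned sequences differ in length")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"{self.gene}: alignment length {length} not divisible by 3")
        for taxon in self.seqs:
            if taxon not in self.mask:
                self.mask[taxon] = np.zeros(length // 3, dtype=bool)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.seqs.values()))) // 3

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)

    def codon(self, taxon: str, i: int) -> str:
        return self.seqs[taxon][3 * i: 3 * i + 3]

    def masked_seq(self, taxon: str) -> str:
        """Sequence with masked codons replaced by NNN."""
        seq = self.seqs[taxon]
        m = self.mask[taxon]
        return "".join("NNN" if m[i] else seq[3 * i: 3 * i + 3] for i in range(self.n_codons))

    def clean_codon_columns(self) -> np.ndarray:
        """Columns where no taxon is masked, gapped or ambiguous."""
        keep = np.ones(self.n_codons, dtype=bool)
        for taxon, seq in self.seqs.items():
            for i in range(self.n_codons):
                if keep[i]:
                    cod = seq[3 * i: 3 * i + 3]
                    if self.mask[taxon][i] or any(ch not in "ACGT" for ch in cod.upper()):
                        keep[i] = False
        return keep


def strip_gaps(aln: CodonAlignment) -> CodonAlignment:
    """Remove every codon column containing a gap character in any taxon.

    Column-wise removal keeps all taxa in frame.  Masks are carried over for
    the surviving columns.  Returns a new alignment with ``gap_stripped=True``
    (empty alignments are legal and simply have zero columns).
    """
    n = aln.n_codons
    keep = np.ones(n, dtype=bool)
    for seq in aln.seqs.values():
        for i in range(n):
            if keep[i] and any(ch in GAP_CHARS for ch in seq[3 * i: 3 * i + 3]):
                keep[i] = False
    idx = np.flatnonzero(keep)
    seqs = {
        t: "".join(s[3 * i: 3 * i + 3] for i in idx) for t, s in aln.seqs.items()
    }
    mask = {t: aln.mask[t][keep].copy() for t in aln.seqs}
    return CodonAlignment(aln.gene, seqs, mask, gap_stripped=True)


def _column_aas(aln: CodonAlignment) -> list[list[str | None]]:
    """Per taxon, per column: amino acid, or None for masked/ambiguous codons."""
    out = []
    for taxon in aln.taxa:
        seq = aln.seqs[taxon].upper()
        row: list[str | None] = []
        for i in range(aln.n_codons):
            cod = seq[3 * i: 3 * i + 3]
            if aln.mask[taxon][i] or any(ch not in "ACGT" for ch in cod):
                row.append(None)
            elif cod in STOP_CODONS:
                row.append("*")
            else:
                row.append(AA_OF[cod])
        out.append(row)
    return out


def _mask_pass(aln: CodonAlignment, window: int, max_nonsyn: int) -> CodonAlignment:
    n = aln.n_codons
    if n == 0:
        return aln
    w = min(window, n)  # window clipped to alignment length
    taxa = aln.taxa
    aas = _column_aas(aln)
    # nonsyn indicator per taxon x column against the column majority of the others
    flags = np.zeros((len(taxa), n), dtype=bool)
    col_counts = [Counter(row[i] for row in aas if row[i] is not None) for i in range(n)]
    for k in range(len(taxa)):
        for i in range(n):
            aa = aas[k][i]
            if aa is None:
                continue
            counts = col_counts[i].copy()
            counts[aa] -= 1
            if counts[aa] == 0:
                del counts[aa]
            if not counts:
                continue
            ranked = counts.most_common(2)
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                continue  # majority tie: scored conservatively, not nonsynonymous
            if aa != ranked[0][0]:
                flags[k, i] = True
    new_mask = {t: aln.mask[t].copy() for t in taxa}
    for k, taxon in enumerate(taxa):
        counts = np.convolve(flags[k].astype(int), np.ones(w, dtype=int), mode="valid")
        for start in np.flatnonzero(counts > max_nonsyn):
            new_mask[taxon][start:start + w] = True
    return CodonAlignment(aln.gene, dict(aln.seqs), new_mask, aln.gap_stripped)


def mask_two_pass(
    aln: CodonAlignment,
    pass1: tuple[int, int] = (15, 7),
    pass2: tuple[int, int] = (4, 2),
) -> CodonAlignment:
    """Two-pass sliding-window masking.

    Each pass slides a ``window``-codon window one codon at a time over each
    taxon's sequence and counts codons whose amino acid differs from the column
    majority amino acid of the other taxa (majority ties and uncountable codons
    are not scored).  Windows with strictly more than ``max_nonsyn`` such
    codons are masked whole for that taxon; overlapping masked windows union.
    The second pass runs on the output of the first, so codons masked in pass 1
    no longer contribute to pass-2 window counts.
    """
    if not aln.gap_stripped:
        raise ValueError("mask_two_pass requires a gap-stripped alignment")
    out = _mask_pass(aln, *pass1)
    out = _mask_pass(out, *pass2)
    return out


def length_filter(aln: CodonAlignment, min_bp: int = 300) -> bool:
    """True when the alignment's clean (unmasked, ungapped, unambiguous)
    length is at least ``min_bp``; exactly ``min_bp`` passes."""
    clean = int(aln.clean_codon_columns().sum())
    return 3 * clean >= min_bp
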