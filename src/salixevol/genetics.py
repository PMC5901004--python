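"""Codon-level primitives shared by the simulator and the divergence/polymorphism code.

Codons are handled both as 3-letter strings and as integers in 0..63
(``idx = 16*b1 + 4*b2 + b3`` with A,C,G,T -> 0..3).  All site and substitution
counting follows the Nei–Gojobori (1986) counting conventions:

* a codon position contributes ``f`` synonymous sites, where ``f`` is the
  fraction of the single-nucleotide changes at that position that are
  synonymous, with changes to stop codons excluded from both numerator and
  denominator;
* substitutions between codons differing at several positions are averaged
  over all mutational pathways (orderings of the single changes) that do not
  pass through a stop codon, with equal weights.  If every ordering passes
  through a stop codon, all orderings are used and steps into or out of a
  stop are counted as nonsynonymous.

The pairwise tables are precomputed once per process for all 64x64 codon
pairs so per-gene counting is a vectorised table lookup.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_table = CodonTable.unambiguous_dna_by_id[1]  # universal code

STOP_CODONS = frozenset(_table.stop_codons)
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]

#: codon string -> one-letter amino acid ('*' for stop)
AA_OF = {c: ("*" if c in STOP_CODONS else _table.forward_table[c]) for c in CODONS}

#: integer codon index -> amino acid code (stop = -1), amino acids numbered arbitrarily
_AA_NAMES = sorted({aa for aa in AA_OF.values() if aa != "*"})
AA_CODE = {aa: i for i, aa in enumerate(_AA_NAMES)}
AA_CODE["*"] = -1
AA_INT = np.array([AA_CODE[AA_OF[c]] for c in CODONS], dtype=np.int8)

IS_STOP = np.array([c in STOP_CODONS for c in CODONS], dtype=bool)


def codon_index(codon: str) -> int:
    return 16 * BASE_INDEX[codon[0]] + 4 * BASE_INDEX[codon[1]] + BASE_INDEX[codon[2]]


def index_codon(idx: int) -> str:
    return BASES[(idx >> 4) & 3] + BASES[(idx >> 2) & 3] + BASES[idx & 3]


# neighbour table: NEIGHBOR[c, pos, base] = codon index with position pos set to base
NEIGHBOR = np.empty((64, 3, 4), dtype=np.int8)
for _c in range(64):
    _b = [(_c >> 4) & 3, (_c >> 2) & 3, _c & 3]
    for _p in range(3):
        for _nb in range(4):
            _bb = list(_b)
            _bb[_p] = _nb
            NEIGHBOR[_c, _p, _nb] = 16 * _bb[0] + 4 * _bb[1] + _bb[2]


def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """NG86 site counts for one sense codon.

    Returns ``(n_sites, s_sites)`` with ``n_sites + s_sites == 3``.  Changes to
    stop codons are excluded from both the numerator and the denominator of the
    per-position synonymous fraction.

    Raises ``ValueError`` on a stop codon.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = AA_OF[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            non_stop += 1
            if AA_OF[alt] == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return 3.0 - s, s


def _diff_positions(c1: str, c2: str) -> list[int]:
    return [i for i in range(3) if c1[i] != c2[i]]


def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) substitution counts c1->c2.

    Averages over all orderings of the single-nucleotide differences that avoid
    stop-codon intermediates (equal weights); if no ordering avoids stops, all
    orderings are used with stop steps scored nonsynonymous.  The endpoint
    codons themselves must be sense codons.
    """
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        raise ValueError("pathway counts defined for sense codons only")
    diffs = _diff_positions(c1, c2)
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for through, steps in paths if not through]
    if not usable:
        usable = [steps for _, steps in paths]
    dn = ds = 0.0
    for steps in usable:
        for a, b in steps:
            if AA_OF[a] != "*" and AA_OF[a] == AA_OF[b]:
                ds += 1
            else:
                dn += 1
    return dn / len(usable), ds / len(usable)


@lru_cache(maxsize=1)
def pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(DN, DS, NSITES, SSITES) lookup arrays.

    ``DN[i, j]``/``DS[i, j]`` are pathway-averaged substitution counts between
    codon indices i and j (NaN if either is a stop); ``NSITES[i]``/``SSITES[i]``
    are the NG86 site counts of codon i (NaN for stops).
    """
    dn = np.full((64, 64), np.nan)
    ds = np.full((64, 64), np.nan)
    ns = np.full(64, np.nan)
    ss = np.full(64, np.nan)
    for i, ci in enumerate(CODONS):
        if ci in STOP_CODONS:
            continue
        ns[i], ss[i] = syn_nonsyn_sites(ci)
        for j, cj in enumerate(CODONS):
            if cj in STOP_CODONS:
                continue
            dn[i, j], ds[i, j] = pathway_counts(ci, cj)
    return dn, ds, ns, ss


def seq_to_codon_indices(seq: str) -> np.ndarray:
    """Translate a DNA string to an array of codon indices; codons containing
    anything outside ACGT (gaps, N) map to -1."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        code[arr == ord(b)] = i
    cod = code.reshape(-1, 3)
    ok = (cod >= 0).all(axis=1)
    idx = 16 * cod[:, 0].astype(np.int16) + 4 * cod[:, 1] + cod[:, 2]
    idx[~ok] = -1
    return idx


def codon_indices_to_seq(idx: np.ndarray) -> str:
    """Inverse of :func:`seq_to_codon_indices`; -1 renders as ``NNN``."""
    out = []
    for i in idx:
        out.append("NNN" if i < 0 else index_codon(int(i)))
    return "".join(out)
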