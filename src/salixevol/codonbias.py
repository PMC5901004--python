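"""Effective number of codons (ENC / Nc), Wright's codon-usage-bias measure.

For each amino-acid family with n observed codons and usage proportions p_i,
the family homozygosity is F = (n * sum(p_i^2) - 1)/(n - 1).  With the
universal code (2 single-codon amino acids, 9 twofold, 1 threefold, 5
fourfold and 3 sixfold families),

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

where Fk is the average F over observed families of degeneracy k.  Nc runs
from 20 (one codon per amino acid, extreme bias) to 61 (uniform usage, no
bias) and is insensitive to sequence length.  Finite samples can push the
raw value above 61, so it is capped there.

Missing-family rules: families observed with fewer than two codons (F
undefined) or with F <= 0 (all singletons) are dropped from their class
average; a missing threefold class (Ile absent) is recovered as
F3 = (F2 + F4)/2; if a twofold/fourfold/sixfold class is entirely absent the
gene's Nc is undefined and flagged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import AA_OF, STOP_CODONS

#: amino acid -> synonymous-family degeneracy under the universal code
FAMILY_SIZE: dict[str, int] = {}
for _c, _aa in AA_OF.items():
    if _aa != "*":
        FAMILY_SIZE[_aa] = FAMILY_SIZE.get(_aa, 0) + 1

#: number of families per degeneracy class (2 single, 9 two, 1 three, 5 four, 3 six)
CLASS_COUNTS = Counter(FAMILY_SIZE.values())


@dataclass
class ENCResult:
    gene: str
    nc: float                      # NaN when undefined
    defined: bool
    codon_counts: Counter = field(default_factory=Counter)
    f_by_class: dict[int, float] = field(default_factory=dict)


def _family_f(counts: list[int]) -> float | None:
    n = sum(counts)
    if n < 2:
        return None
    p = np.asarray(counts, dtype=float) / n
    return (n * float((p ** 2).sum()) - 1.0) / (n - 1.0)


def enc(seq: str, gene: str = "") -> ENCResult:
    """Nc for one in-frame coding sequence.

    Codons containing non-ACGT characters and stop codons are skipped.
    """
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError(f"{gene or 'sequence'}: length not divisible by 3")
    counts: Counter = Counter()
    for i in range(0, len(seq), 3):
        cod = seq[i:i + 3]
        if any(ch not in "ACGT" for ch in cod) or cod in STOP_CODONS:
            continue
        counts[cod] += 1

    by_aa: dict[str, Counter] = {}
    for cod, k in counts.items():
        by_aa.setdefault(AA_OF[cod], Counter())[cod] = k

    f_values: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam_counts in by_aa.items():
        size = FAMILY_SIZE[aa]
        if size == 1:
            continue
        # include zero counts for unobserved codons of an observed family
        vals = list(fam_counts.values())
        f = _family_f(vals)
        if f is None or f <= 0:
            continue
        f_values[size].append(f)

    fbar: dict[int, float] = {
        k: float(np.mean(v)) for k, v in f_values.items() if v
    }
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if not all(k in fbar for k in (2, 3, 4, 6)):
        return ENCResult(gene, float("nan"), False, counts, fbar)
    nc = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return ENCResult(gene, min(nc, 61.0), True, counts, fbar)


def enc_table(sequences: dict[str, str]) -> pd.DataFrame:
    """Per-gene Nc table; undefined genes carry NaN with defined=False."""
    rows = [(g, r.nc, r.defined) for g, r in
            ((g, enc(s, g)) for g, s in sequences.items())]
    return pd.DataFrame(rows, columns=["gene", "Nc", "defined"]).set_index("gene")


def enc_category_contrast(
    enc_values: pd.Series,
    categories: pd.Series,
    pair: tuple[str, str],
    reps: int = 1000,
    rng: np.random.Generator | None = None,
):
    """Permutation test on the difference of mean Nc between two categories
    (same engine and p-value convention as the divergence contrasts)."""
    from .catstats import mean_stat, permutation_contrast

    cats = categories.reindex(enc_values.index)
    a = enc_values[cats == pair[0]].dropna()
    b = enc_values[cats == pair[1]].dropna()
    df_a = pd.DataFrame({"Nc": a})
    df_b = pd.DataFrame({"Nc": b})
    return permutation_contrast(
        df_a, df_b, mean_stat("Nc"), reps=reps, rng=rng,
        statistic_name="mean_Nc", names=pair,
    )
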