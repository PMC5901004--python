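"""Per-gene McDonald-Kreitman tests, positive-selection calls and DoS.

Genes with any 2x2 margin below six are excluded; positive selection needs a
significant two-sided Fisher p and d_N/d_S > p_N/p_S.  Category contrasts:
Fisher on positive counts, Fisher on DoS > 0 counts, Wilcoxon on DoS values.
"""

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from salixevol.selection import category_selection_contrasts, mk_table


def main() -> None:
    ensure_dirs()
    counts = pd.read_csv(SCRATCH / "matched_counts_per_gene.tsv", sep="\t", index_col=0)
    calls = pd.read_csv(SCRATCH / "sexbias_calls_catkin.tsv", sep="\t", index_col=0)
    cats = calls["category"].reindex(counts.index).dropna()
    counts = counts.loc[cats.index]

    mk = mk_table(counts)
    mk.to_csv(SCRATCH / "mk_per_gene.tsv", sep="\t")
    contrasts = category_selection_contrasts(mk, cats)
    contrasts.to_csv(RESULTS / "selection_contrasts.tsv", sep="\t")

    inc = mk["included"]
    print(f"{inc.sum()} of {len(mk)} genes pass the margin rule; "
          f"{int(mk['positive_selection'].sum())} under positive selection")
    print(contrasts.round(4).to_string())


if __name__ == "__main__":
    main()
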