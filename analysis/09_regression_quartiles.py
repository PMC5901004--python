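"""Expression-level confounder checks on the divergence contrast.

(a) sum-aggregated d_N/d_S by expression quartile within each bias class;
(b) OLS of per-gene d_N/d_S on mean log2(RPKM+1) and the signed five-group
degree-of-sex-bias code, with interaction.
"""

import numpy as np
import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs
from salixevol import io
from salixevol.expression import compute_rpkm
from salixevol.regression import dnds_regression, quartile_dnds


def main() -> None:
    ensure_dirs()
    counts = pd.read_csv(SCRATCH / "matched_counts_per_gene.tsv", sep="\t", index_col=0)
    calls = pd.read_csv(SCRATCH / "sexbias_calls_catkin.tsv", sep="\t", index_col=0)
    table = io.read_expression(SCRATCH / "counts.tsv", SCRATCH / "sample_meta.tsv",
                               SCRATCH / "gene_lengths.tsv")
    rpkm = compute_rpkm(table)
    catkin = [s for s in rpkm.columns if table.sample_meta.loc[s, "tissue"] == "catkin"]
    expr = np.log2(rpkm[catkin] + 1).mean(axis=1)

    shared = counts.index.intersection(calls.index)
    counts = counts.loc[shared]
    quart = quartile_dnds(counts, calls["category"].loc[shared], expr, reps=1000, seed=3)
    quart.to_csv(RESULTS / "quartile_dnds.tsv", sep="\t", index=False)

    rep = dnds_regression(counts, calls["fc_class"].loc[shared], expr)
    out = pd.DataFrame({"beta": rep.params, "p": rep.pvalues})
    out.loc["adj_r2", "beta"] = rep.adj_r2
    out.to_csv(RESULTS / "dnds_regression.tsv", sep="\t")
    print(quart.round(4).to_string(index=False))
    print(f"\nOLS (n={rep.n}, {rep.n_excluded_zero_ds} genes dropped for d_S=0):")
    print(out.round(4).to_string())


if __name__ == "__main__":
    main()
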