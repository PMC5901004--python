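"""Generate the synthetic study with known ground truth.

Writes per-ortholog FASTA alignments, the species tree, expression counts
with sample metadata, the per-site coverage/allele table, the ground-truth
event log and the nonrecombining-Z BED to scratch/data/.
"""

import pandas as pd

from common import SCRATCH, STUDY, ensure_dirs
from salixevol import io
from salixevol.simulate import (
    ROOTED_NEWICK,
    UNROOTED_NEWICK,
    simulate_expression,
    simulate_ortholog_set,
    simulate_site_table,
)


def main() -> None:
    ensure_dirs()
    alignments, truth = simulate_ortholog_set(STUDY)
    expr = simulate_expression(STUDY)
    sites = simulate_site_table(alignments, truth, STUDY)

    io.write_ortholog_set(alignments, SCRATCH / "alignments")
    io.write_tree(ROOTED_NEWICK, SCRATCH / "species_tree_rooted.nwk")
    io.write_tree(UNROOTED_NEWICK, SCRATCH / "species_tree_unrooted.nwk")
    io.write_expression(expr, SCRATCH / "counts.tsv", SCRATCH / "sample_meta.tsv",
                        SCRATCH / "gene_lengths.tsv")
    io.write_site_table(sites, SCRATCH / "site_table.tsv")
    io.write_ground_truth(truth, SCRATCH / "truth_substitutions.tsv",
                          SCRATCH / "truth_snps.tsv", SCRATCH / "gene_coords.tsv")
    io.write_bed(pd.DataFrame({"chrom": ["Z"], "start": [3_500_000], "end": [8_800_000]}),
                 SCRATCH / "nonrecombining_z.bed")
    pd.Series(truth.categories, name="category").rename_axis("gene").to_csv(
        SCRATCH / "truth_categories.tsv", sep="\t")

    n_genes = len(alignments)
    n_snps = len(truth.snps)
    foc = truth.substitutions.query("branch == 'S.viminalis'")
    print(f"simulated {n_genes} ortholog groups "
          f"({STUDY.gene_length_codons} codons each) on the 5-taxon tree")
    print(f"focal-branch events: {len(foc)} "
          f"({foc['synonymous'].mean():.0%} synonymous)")
    print(f"injected segregating variants: {n_snps} "
          f"({truth.snps['synonymous'].mean():.0%} synonymous)")


if __name__ == "__main__":
    main()
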