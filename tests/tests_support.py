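"""Small fixture builders shared between test modules."""

import pandas as pd

INDIVIDUALS = [("M1", "M"), ("M2", "M"), ("M3", "M"), ("F1", "F"), ("F2", "F"), ("F3", "F")]


def snp_site_table(coverages, alt_counts, gene="g1", site=1, alt_base="C") -> pd.DataFrame:
    """Site table rows for a single site across the six individuals."""
    ci, p = divmod(site - 1, 3)
    rows = []
    for (ind, sex), cov, alt in zip(INDIVIDUALS, coverages, alt_counts):
        rows.append({
            "gene": gene, "codon_index": ci + 1, "codon_pos": p + 1, "site": site,
            "individual": ind, "sex": sex, "coverage": cov,
            "ref_count": cov - alt, "alt_count": alt,
            "alt_base": alt_base if any(alt_counts) else ".",
        })
    return pd.DataFrame(rows)
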