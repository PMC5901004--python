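"""McDonald-Kreitman tests, positive-selection calls and the DoS statistic.

Each gene's 2x2 table contrasts fixed substitutions (D_N, D_S) with
segregating polymorphisms (P_N, P_S), nonsynonymous vs synonymous, over an
identical site basis.  Genes with any table margin (row or column sum) below
six are excluded — the test has essentially no power there.  A significant
Fisher p with d_N/d_S > p_N/p_S flags positive selection.  DoS =
D_N/(D_N+D_S) - P_N/(P_N+P_S) gives a per-gene direction of selection
(positive: adaptive; zero: neutral; negative: purifying / segregating
deleterious variation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MKResult:
    gene: str
    D_N: int
    D_S: int
    P_N: int
    P_S: int
    fisher_p: float
    included: bool
    positive_selection: bool
    dos: float  # NaN when undefined


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def mk_test(
    gene: str,
    d_n: float,
    d_s: float,
    p_n: int,
    p_s: int,
    alpha: float = 0.05,
    min_margin: int = 6,
) -> MKResult:
    """MK test for one gene.

    Pathway-averaged substitution counts may be fractional; they are rounded
    half-up for the contingency table (polymorphism counts are integral).
    Inclusion requires every row and column sum of the 2x2 table to be at
    least ``min_margin``.  The Fisher test is two-sided; direction comes from
    the cross-product condition D_N * P_S > P_N * D_S (equivalent to
    d_N/d_S > p_N/p_S on the shared site basis).
    """
    DN, DS = _round_half_up(d_n), _round_half_up(d_s)
    PN, PS = int(p_n), int(p_s)
    table = np.array([[DN, DS], [PN, PS]])
    margins = [DN + DS, PN + PS, DN + PN, DS + PS]
    included = all(m >= min_margin for m in margins)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    positive = bool(included and p < alpha and DN * PS > PN * DS)
    dn_tot, pn_tot = DN + DS, PN + PS
    dos = (
        DN / dn_tot - PN / pn_tot if dn_tot > 0 and pn_tot > 0 else float("nan")
    )
    return MKResult(gene, DN, DS, PN, PS, float(p), included, positive, dos)


def dos(d_n: float, d_s: float, p_n: float, p_s: float) -> float:
    """DoS = D_N/(D_N+D_S) - P_N/(P_N+P_S); raises when either sum is zero."""
    if d_n + d_s <= 0 or p_n + p_s <= 0:
        raise ValueError("DoS undefined: zero substitutions or polymorphisms")
    return d_n / (d_n + d_s) - p_n / (p_n + p_s)


def mk_table(counts: pd.DataFrame, alpha: float = 0.05, min_margin: int = 6) -> pd.DataFrame:
    """Run the MK test on every row of a matched count table.

    ``counts`` needs columns D_N, D_S, P_N, P_S (mk_input_table output).
    Returns per-gene columns fisher_p, included, positive_selection, DoS.
    """
    rows = []
    for gene, r in counts.iterrows():
        res = mk_test(str(gene), r["D_N"], r["D_S"], int(r["P_N"]), int(r["P_S"]),
                      alpha=alpha, min_margin=min_margin)
        rows.append((gene, res.D_N, res.D_S, res.P_N, res.P_S,
                     res.fisher_p, res.included, res.positive_selection, res.dos))
    return pd.DataFrame(
        rows,
        columns=["gene", "D_N_int", "D_S_int", "P_N", "P_S",
                 "fisher_p", "included", "positive_selection", "DoS"],
    ).set_index("gene")


def category_selection_contrasts(
    mk: pd.DataFrame,
    categories: pd.Series,
    baseline: str = "UB",
    compare: tuple[str, ...] = ("MB", "FB"),
) -> pd.DataFrame:
    """Category-level positive-selection and DoS contrasts against a baseline.

    Per compared category: (a) Fisher exact test on counts of
    positive-selection genes vs the rest (included genes only); (b) the same
    on DoS > 0 counts; (c) a two-sided Wilcoxon rank-sum test on per-gene DoS
    values.  Empty or degenerate comparisons are emitted with tested=False.
    """
    cats = categories.reindex(mk.index)
    rows = []
    base_inc = mk[(cats == baseline) & mk["included"]]
    base_dos = mk.loc[cats == baseline, "DoS"].dropna()
    for cat in compare:
        sub_inc = mk[(cats == cat) & mk["included"]]
        sub_dos = mk.loc[cats == cat, "DoS"].dropna()
        row: dict[str, object] = {"category": cat, "baseline": baseline,
                                  "n_included": len(sub_inc),
                                  "n_positive": int(sub_inc["positive_selection"].sum()),
                                  "n_dos": len(sub_dos),
                                  "n_dos_positive": int((sub_dos > 0).sum()),
                                  "mean_dos": float(sub_dos.mean()) if len(sub_dos) else np.nan,
                                  "tested": False}
        if len(sub_inc) and len(base_inc):
            t = [[int(sub_inc["positive_selection"].sum()),
                  int((~sub_inc["positive_selection"]).sum())],
                 [int(base_inc["positive_selection"].sum()),
                  int((~base_inc["positive_selection"]).sum())]]
            row["fisher_p_positive"] = float(stats.fisher_exact(t)[1])
            row["tested"] = True
        if len(sub_dos) and len(base_dos):
            t = [[int((sub_dos > 0).sum()), int((sub_dos <= 0).sum())],
                 [int((base_dos > 0).sum()), int((base_dos <= 0).sum())]]
            row["fisher_p_dos_positive"] = float(stats.fisher_exact(t)[1])
            if len(sub_dos) > 1 and len(base_dos) > 1:
                row["wilcoxon_p_dos"] = float(
                    stats.mannwhitneyu(sub_dos, base_dos, alternative="two-sided").pvalue
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")
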