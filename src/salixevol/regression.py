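"""Expression-level confounder analyses for the divergence results.

Highly expressed genes tend to have lower d_N/d_S, so the category contrasts
are backed by (a) sum-aggregated d_N/d_S within expression quartiles per bias
class and (b) an ordinary least-squares regression of per-gene d_N/d_S on
mean expression and an ordinal degree-of-sex-bias code, with interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .catstats import DNDS_STAT, aggregate, bootstrap_ci

#: five ordered fold-change groups -> signed ordinal code (negative = female-biased)
SIGNED_CODES = {"FB_high": -2, "FB_low": -1, "UB": 0, "MB_low": 1, "MB_high": 2}
#: magnitude coding: how far from unbiased, direction ignored
MAGNITUDE_CODES = {"FB_high": 2, "FB_low": 1, "UB": 0, "MB_low": 1, "MB_high": 2}


@dataclass
class RegressionReport:
    params: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    n: int
    n_excluded_zero_ds: int


def quartile_dnds(
    genes: pd.DataFrame,
    categories: pd.Series,
    expression: pd.Series,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sum-aggregated d_N/d_S per expression quartile within each bias class.

    ``expression`` is mean log2(RPKM+1) per gene; quartile cuts are taken
    within each class.  Classes with fewer than 4 genes are skipped; empty
    cells are emitted with NaN and flagged.
    """
    rng = np.random.default_rng(seed)
    cats = categories.reindex(genes.index)
    expr = expression.reindex(genes.index)
    rows = []
    for cat in pd.unique(cats.dropna()):
        sub = genes[cats == cat]
        e = expr[cats == cat]
        if len(sub) < 4:
            continue
        q = pd.qcut(e.rank(method="first"), 4, labels=[1, 2, 3, 4])
        for quart in (1, 2, 3, 4):
            cell = sub[q == quart]
            row = {"category": cat, "quartile": quart, "n_genes": len(cell)}
            if len(cell) == 0:
                row.update({"dnds": np.nan, "skipped": True})
            else:
                row["dnds"] = aggregate(cell, DNDS_STAT)
                row["skipped"] = False
                if len(cell) >= 2:
                    lo, hi = bootstrap_ci(cell, DNDS_STAT, reps=reps, rng=rng)
                    row["ci_low"], row["ci_high"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)


def dnds_regression(
    genes: pd.DataFrame,
    fc_classes: pd.Series,
    expression: pd.Series,
    coding: str = "signed",
) -> RegressionReport:
    """OLS of per-gene d_N/d_S on expression level and degree of sex-bias.

    Genes with d_S = 0 (per-gene ratio undefined) are excluded and counted.
    ``coding`` selects the bias-degree code: 'signed' maps the five
    fold-change groups to -2..+2 (negative beta then means lower d_N/d_S
    toward male bias); 'magnitude' maps them to 0/1/2.  The model includes
    the expression x bias interaction.  Raises on a rank-deficient design,
    naming the collinear term.
    """
    codes = {"signed": SIGNED_CODES, "magnitude": MAGNITUDE_CODES}[coding]
    dnds = genes["D_N"] / genes["N"] * np.where(genes["d_S"] > 0, genes["S"] / genes["D_S"], np.nan)
    ok = np.isfinite(dnds)
    n_excluded = int((~ok).sum())
    y = dnds[ok]
    x1 = expression.reindex(genes.index)[ok]
    x2 = fc_classes.reindex(genes.index)[ok].map(codes).astype(float)
    X = pd.DataFrame({
        "expression": x1,
        "bias_degree": x2,
        "expression:bias_degree": x1 * x2,
    })
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        terms = X.drop(columns="const")
        degenerate = [c for c in terms.columns if terms[c].nunique() <= 1]
        if not degenerate:
            corr = terms.corr().abs()
            np.fill_diagonal(corr.values, 0)
            degenerate = list(corr.stack().idxmax())
        raise ValueError(f"rank-deficient design; collinear term(s): {degenerate}")
    fit = sm.OLS(y, X).fit()
    return RegressionReport(
        params=fit.params,
        pvalues=fit.pvalues,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
        n_excluded_zero_ds=n_excluded,
    )
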