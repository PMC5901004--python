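"""Sum-aggregated category statistics, bootstrap CIs, permutation contrasts
and genomic stratification.

Category-level rates are always ratios of sums over genes (never means of
per-gene ratios): d_N = sum D_N / sum N, and d_N/d_S is the ratio of two such
aggregates.  This avoids the explosion of per-gene ratios at small d_S and
weights genes by their information content.  Resampling (bootstrap over genes,
permutation of category labels) recomputes the aggregate each time, with the
gene as the resampling unit throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: a statistic is (columns it sums, function of the column-sums dict -> value);
#: the dict also carries "__n", the number of genes in the (re)sample.
StatSpec = tuple[Sequence[str], Callable[[dict[str, float]], float]]


def ratio_stat(num: str, den: str) -> StatSpec:
    """sum(num)/sum(den) — e.g. d_N from (D_N, N)."""
    return ((num, den), lambda s: s[num] / s[den] if s[den] > 0 else np.nan)


def ratio_of_ratios_stat(num1: str, den1: str, num2: str, den2: str) -> StatSpec:
    """(sum(num1)/sum(den1)) / (sum(num2)/sum(den2)) — e.g. d_N/d_S."""
    cols = (num1, den1, num2, den2)

    def f(s: dict[str, float]) -> float:
        if s[den1] <= 0 or s[den2] <= 0 or s[num2] <= 0:
            return np.nan
        return (s[num1] / s[den1]) / (s[num2] / s[den2])

    return (cols, f)


def mean_stat(col: str) -> StatSpec:
    """Unweighted per-gene mean — used for DoS and ENC summaries."""
    return ((col,), lambda s: s[col] / s["__n"] if s["__n"] > 0 else np.nan)


DNDS_STAT = ratio_of_ratios_stat("D_N", "N", "D_S", "S")
PNPS_STAT = ratio_of_ratios_stat("P_N", "N", "P_S", "S")


def aggregate(genes: pd.DataFrame, stat: StatSpec) -> float:
    """Evaluate a sum-based statistic on a gene table."""
    cols, f = stat
    if len(genes) == 0:
        return float("nan")
    sums = {c: float(genes[c].sum()) for c in cols}
    sums["__n"] = float(len(genes))
    return float(f(sums))


def bootstrap_ci(
    genes: pd.DataFrame,
    stat: StatSpec,
    reps: int = 1000,
    level: float = 95.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a sum-based statistic.

    Genes are resampled with replacement ``reps`` times and the aggregate is
    recomputed on each resample; returns the (2.5%, 97.5%) percentiles at the
    default level.
    """
    if len(genes) < 2:
        raise ValueError("bootstrap needs at least 2 genes")
    if rng is None:
        rng = np.random.default_rng()
    cols, f = stat
    X = genes[list(cols)].to_numpy(float)
    n = len(genes)
    idx = rng.integers(0, n, size=(reps, n))
    sums = X[idx].sum(axis=1)  # reps x len(cols)
    vals = np.empty(reps)
    for r in range(reps):
        d = {c: sums[r, k] for k, c in enumerate(cols)}
        d["__n"] = float(n)
        vals[r] = f(d)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.nanpercentile(vals, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


@dataclass
class ContrastResult:
    statistic: str
    group_a: str
    group_b: str
    observed_diff: float
    p: float
    method: str
    n_a: int
    n_b: int


def permutation_contrast(
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    stat: StatSpec,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    statistic_name: str = "",
    names: tuple[str, str] = ("A", "B"),
) -> ContrastResult:
    """Two-sided permutation test on the difference of group aggregates.

    Category labels are shuffled ``reps`` times preserving group sizes and the
    absolute difference of aggregates is recomputed;
    p = (1 + #{|diff_perm| >= |diff_obs|}) / (reps + 1).
    """
    if len(genes_a) == 0 or len(genes_b) == 0:
        raise ValueError("both groups must be nonempty")
    if rng is None:
        rng = np.random.default_rng()
    cols, f = stat
    obs = aggregate(genes_a, stat) - aggregate(genes_b, stat)
    if not np.isfinite(obs):
        # statistic undefined in a group (e.g. zero denominator): no test
        return ContrastResult(
            statistic_name or "+".join(cols), names[0], names[1],
            float("nan"), float("nan"), "permutation",
            len(genes_a), len(genes_b),
        )
    Xa = genes_a[list(cols)].to_numpy(float)
    Xb = genes_b[list(cols)].to_numpy(float)
    X = np.vstack([Xa, Xb])
    n, na = len(X), len(Xa)
    total = X.sum(axis=0)

    count = 0
    for _ in range(reps):
        pick = rng.permutation(n)[:na]
        sa = X[pick].sum(axis=0)
        da = {c: sa[k] for k, c in enumerate(cols)}
        da["__n"] = float(na)
        db = {c: total[k] - sa[k] for k, c in enumerate(cols)}
        db["__n"] = float(n - na)
        diff = f(da) - f(db)
        # undefined resampled statistics count as extreme (conservative)
        if not np.isfinite(diff) or abs(diff) >= abs(obs) - 1e-12:
            count += 1
    p = (1 + count) / (reps + 1)
    return ContrastResult(
        statistic_name or "+".join(cols),
        names[0], names[1], float(obs), float(p), "permutation",
        len(genes_a), len(genes_b),
    )


def stratify(gene_coords: pd.DataFrame, bed: pd.DataFrame) -> pd.Series:
    """Assign each gene to 'nonrecombining_Z' or 'autosomes_PAR'.

    ``gene_coords`` needs columns gene, chrom, start, end; ``bed`` is a BED
    interval set (chrom, start, end, 0-based half-open) defining the
    nonrecombining region.  A gene overlapping any interval is Z-linked
    nonrecombining; everything else (including the pseudoautosomal Z) is
    pooled with the autosomes.  Genes lacking coordinates are absent from the
    result (callers treat them as excluded).
    """
    out = {}
    for _, g in gene_coords.iterrows():
        hit = False
        for _, iv in bed.iterrows():
            if g["chrom"] == iv["chrom"] and g["start"] < iv["end"] and g["end"] > iv["start"]:
                hit = True
                break
        out[g["gene"]] = "nonrecombining_Z" if hit else "autosomes_PAR"
    return pd.Series(out, name="stratum")


TABLE1_STATS: dict[str, StatSpec] = {
    "d_N": ratio_stat("D_N", "N"),
    "d_S": ratio_stat("D_S", "S"),
    "d_N/d_S": DNDS_STAT,
    "p_N": ratio_stat("P_N", "N"),
    "p_S": ratio_stat("P_S", "S"),
    "p_N/p_S": PNPS_STAT,
}


def build_category_table(
    genes: pd.DataFrame,
    categories: pd.Series,
    strata: pd.Series | None = None,
    stats: dict[str, StatSpec] | None = None,
    reps: int = 1000,
    seed: int = 0,
    baseline: str = "UB",
    contrast_pairs: Sequence[tuple[str, str]] = (("MB", "UB"), ("FB", "UB"), ("MB", "FB")),
) -> pd.DataFrame:
    """Stratum x category x statistic summary with bootstrap CIs and
    permutation p-values against the stated contrasts.

    ``genes`` is the per-gene matched count table (mk_input_table output plus
    any extra per-gene columns such as DoS or ENC referenced by ``stats``).
    Contrast p-values are attached to the first-named category of each pair
    (the baseline row carries no p).
    """
    if stats is None:
        stats = {k: v for k, v in TABLE1_STATS.items()
                 if all(c in genes.columns for c in v[0])}
    rng = np.random.default_rng(seed)
    cats = categories.reindex(genes.index)
    strat = (
        strata.reindex(genes.index)
        if strata is not None
        else pd.Series("all", index=genes.index)
    )
    rows = []
    for stratum in strat.dropna().unique():
        in_str = genes[strat == stratum]
        c_str = cats[strat == stratum]
        pvals: dict[tuple[str, str, str], float] = {}
        for name, spec in stats.items():
            for a, b in contrast_pairs:
                ga, gb = in_str[c_str == a], in_str[c_str == b]
                if len(ga) == 0 or len(gb) == 0:
                    continue
                res = permutation_contrast(
                    ga, gb, spec, reps=reps, rng=rng,
                    statistic_name=name, names=(a, b),
                )
                pvals[(name, a, b)] = res.p
        for cat in pd.unique(c_str.dropna()):
            sub = in_str[c_str == cat]
            if len(sub) == 0:
                continue
            row: dict[str, object] = {
                "stratum": stratum, "category": cat, "n_genes": len(sub)
            }
            for name, spec in stats.items():
                row[name] = aggregate(sub, spec)
                if len(sub) >= 2:
                    lo, hi = bootstrap_ci(sub, spec, reps=reps, rng=rng)
                    row[f"{name}_ci_low"], row[f"{name}_ci_high"] = lo, hi
                for a, b in contrast_pairs:
                    if a == cat and b == baseline and (name, a, b) in pvals:
                        row[f"{name}_p_vs_{baseline}"] = pvals[(name, a, b)]
            rows.append(row)
        for name in stats:
            if (name, "MB", "FB") in pvals:
                rows.append({
                    "stratum": stratum, "category": "MB_vs_FB", "n_genes": 0,
                    f"{name}_p_MB_vs_FB": pvals[(name, "MB", "FB")],
                })
    return pd.DataFrame(rows)
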