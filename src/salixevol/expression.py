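"""Expression quantification, filtering, TMM normalization and sex-bias calls.

The classification contract: a gene is male-biased (MB) when its log2 M:F
normalized expression exceeds 1 with BH-adjusted p < .05, female-biased (FB)
when it is below -1 with adjusted p < .05, and unbiased (UB) otherwise.  The
differential test is a negative-binomial exact-style test with a single
common dispersion estimated by the method of moments across genes — a
documented stand-in whose contract is per-gene BH-corrected p-values, not
bit-compatibility with any particular DE package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("UB", "MB", "FB")
FC_CLASSES = ("FB_high", "FB_low", "UB", "MB_low", "MB_high")


@dataclass
class ExpressionTable:
    """Gene x sample read counts plus gene lengths and sample metadata.

    counts: DataFrame indexed by gene, columns are sample ids.
    gene_length_bp: Series indexed by gene (bp, > 0).
    sample_meta: DataFrame indexed by sample with columns sex ('M'/'F'),
        tissue, individual.
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if (self.gene_length_bp.reindex(self.counts.index) <= 0).any():
            raise ValueError("gene lengths must be positive")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad_sex = set(self.sample_meta["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")

    def samples_in(self, tissue: str) -> list[str]:
        meta = self.sample_meta
        return [s for s in self.counts.columns if meta.loc[s, "tissue"] == tissue]


def compute_rpkm(table: ExpressionTable) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads:
    ``1e9 * count / (length_bp * library_size)``."""
    lib = table.counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    lengths = table.gene_length_bp.reindex(table.counts.index)
    return 1e9 * table.counts.div(lengths, axis=0).div(lib, axis=1)


def filter_expressed(
    rpkm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    tissue: str,
    threshold: float = 2.0,
) -> pd.Index:
    """Genes expressed above ``threshold`` RPKM (inclusive) in at least
    ceil(n/2) individuals of at least one sex, within one tissue."""
    retained = np.zeros(len(rpkm), dtype=bool)
    any_sex = False
    for sex in ("M", "F"):
        samples = [
            s for s in rpkm.columns
            if sample_meta.loc[s, "tissue"] == tissue and sample_meta.loc[s, "sex"] == sex
        ]
        if len(samples) < 2:
            continue
        any_sex = True
        need = math.ceil(len(samples) / 2)
        retained |= (rpkm[samples].values >= threshold).sum(axis=1) >= need
    if not any_sex:
        raise ValueError(f"need at least 2 individuals per sex in tissue {tissue!r}")
    return rpkm.index[retained]


def tmm_normalize(
    table: ExpressionTable,
    tissue: str,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors for one tissue's samples.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions.  Gene-wise log ratios (M) and
    average log abundances (A) against the reference are doubly trimmed (30%
    of each tail on M, 5% on A) and the factor is 2**(precision-weighted mean
    M), with weights from the delta-method binomial variances.  Factors are
    rescaled to geometric mean 1.
    """
    samples = table.samples_in(tissue)
    if len(samples) < 2:
        raise ValueError(f"TMM needs at least 2 samples in tissue {tissue!r}")
    counts = table.counts[samples]
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError(f"all-zero sample(s): {list(lib.index[lib == 0])}")
    frac75 = counts.div(lib, axis=1).quantile(0.75)
    ref = (frac75 - frac75.mean()).abs().idxmin()

    xr = counts[ref].to_numpy(float)
    nr = float(lib[ref])
    factors = {}
    for s in samples:
        if s == ref:
            factors[s] = 1.0
            continue
        xs = counts[s].to_numpy(float)
        ns = float(lib[s])
        ok = (xs > 0) & (xr > 0)
        if not ok.any():
            factors[s] = 1.0
            continue
        ps, pr = xs[ok] / ns, xr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = 1.0 / ((ns - xs[ok]) / (ns * xs[ok]) + (nr - xr[ok]) / (nr * xr[ok]))
        n = len(m)
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abundance_trim, 1 - abundance_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        factors[s] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    f = pd.Series(factors).reindex(samples)
    return f / np.exp(np.log(f).mean())


def fc_class(log2fc: float) -> str:
    """Five ordered fold-change classes on the log2 M:F scale."""
    if log2fc <= -3:
        return "FB_high"
    if log2fc <= -1:
        return "FB_low"
    if log2fc < 1:
        return "UB"
    if log2fc < 3:
        return "MB_low"
    return "MB_high"


def _common_dispersion(y: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across genes.

    y: genes x samples matrix on a common library-size scale.  Per gene and
    group, phi = (var - mean)/mean^2; the common value is the median over
    informative gene-groups, floored at 1e-4.
    """
    phis = []
    for g in np.unique(groups):
        sub = y[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v[ok] - m[ok]) / m[ok] ** 2
        phis.append(phi)
    if not phis:
        return 0.1
    allphi = np.concatenate(phis)
    allphi = allphi[np.isfinite(allphi)]
    if not len(allphi):
        return 0.1
    return float(max(np.median(allphi), 1e-4))


def _exact_nb_pvalue(ya: int, yb: int, phi: float, n_per_group: int) -> float:
    """Two-sided exact-style NB test for equality of two group sums.

    Under a common per-sample mean and dispersion phi, each group sum is
    NB(mean t/2, dispersion phi/n).  Conditioning on t = ya + yb, the p-value
    sums P(k, t-k) over outcomes no more likely than the observed one.  For
    large t a normal approximation to the same conditional distribution is
    used.
    """
    t = ya + yb
    if t == 0:
        return 1.0
    mean = t / 2.0
    disp = phi / n_per_group
    if disp <= 0:
        disp = 1e-8
    size = 1.0 / disp
    p_nb = size / (size + mean)
    if t <= 5000:
        k = np.arange(t + 1)
        logp = stats.nbinom.logpmf(k, size, p_nb) + stats.nbinom.logpmf(t - k, size, p_nb)
        logp -= logp.max()
        prob = np.exp(logp)
        prob /= prob.sum()
        obs = prob[ya]
        return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))
    var = 2 * (mean + disp * mean ** 2)  # var of ya - yb given independence
    z = (ya - yb) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def classify_sex_bias(
    table: ExpressionTable,
    tissue: str,
    genes: pd.Index | None = None,
    alpha: float = 0.05,
    lfc: float = 1.0,
    pseudo: float = 0.25,
    norm_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene sex-bias calls for one tissue.

    Returns a DataFrame indexed by gene with columns log2fc, p, p_adj,
    category, fc_class.  log2fc is computed from mean normalized abundances
    with a pseudo-offset of ``pseudo`` counts.  ``genes`` restricts testing to
    a pre-filtered set (expression filter); default tests all genes.
    """
    samples = table.samples_in(tissue)
    meta = table.sample_meta.loc[samples]
    for sex in ("M", "F"):
        if (meta["sex"] == sex).sum() < 2:
            raise ValueError(f"fewer than 2 {sex} individuals in tissue {tissue!r}")
    if norm_factors is None:
        norm_factors = tmm_normalize(table, tissue)
    counts = table.counts[samples]
    if genes is not None:
        counts = counts.loc[genes]
    lib = table.counts[samples].sum(axis=0)
    eff = lib * norm_factors.reindex(samples)
    ref = np.exp(np.log(eff).mean())  # geometric-mean effective library size
    y = counts.to_numpy(float) * (ref / eff.to_numpy(float))[None, :]
    is_male = (meta["sex"] == "M").to_numpy()
    phi = _common_dispersion(y, is_male.astype(int))

    ym = y[:, is_male].sum(axis=1).round().astype(np.int64)
    yf = y[:, ~is_male].sum(axis=1).round().astype(np.int64)
    n_m, n_f = int(is_male.sum()), int((~is_male).sum())
    pvals = np.array([
        _exact_nb_pvalue(int(a), int(b), phi, (n_m + n_f) / 2)
        for a, b in zip(ym, yf)
    ])
    mean_m = y[:, is_male].mean(axis=1)
    mean_f = y[:, ~is_male].mean(axis=1)
    log2fc = np.log2((mean_m + pseudo) / (mean_f + pseudo))
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    category = np.where(
        (log2fc > lfc) & (p_adj < alpha), "MB",
        np.where((log2fc < -lfc) & (p_adj < alpha), "FB", "UB"),
    )
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "p_adj": p_adj,
            "category": category,
            "fc_class": [fc_class(x) for x in log2fc],
        },
        index=counts.index,
    )
    out.index.name = "gene"
    return out


def expression_summaries(
    calls: pd.DataFrame,
    rpkm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    tissue: str,
    by: str = "fc_class",
) -> pd.DataFrame:
    """Per-class mean male/female expression with a male-vs-female rank test.

    Expression per gene and sex is the mean over individuals of
    log2(RPKM + 1).  For each class the two-sided Wilcoxon rank-sum test
    compares the per-gene male values against the per-gene female values;
    single-gene classes report the summary with ``tested=False``.
    """
    msam = [s for s in rpkm.columns
            if sample_meta.loc[s, "tissue"] == tissue and sample_meta.loc[s, "sex"] == "M"]
    fsam = [s for s in rpkm.columns
            if sample_meta.loc[s, "tissue"] == tissue and sample_meta.loc[s, "sex"] == "F"]
    male = np.log2(rpkm[msam] + 1).mean(axis=1)
    female = np.log2(rpkm[fsam] + 1).mean(axis=1)
    rows = []
    for cls, sub in calls.groupby(by, observed=True):
        g = sub.index
        mvals, fvals = male.reindex(g).dropna(), female.reindex(g).dropna()
        row = {
            by: cls,
            "n_genes": len(g),
            "mean_male": float(mvals.mean()) if len(mvals) else np.nan,
            "mean_female": float(fvals.mean()) if len(fvals) else np.nan,
        }
        if len(mvals) > 1 and len(fvals) > 1:
            stat = stats.mannwhitneyu(mvals, fvals, alternative="two-sided")
            row["wilcoxon_p"] = float(stat.pvalue)
            row["tested"] = True
        else:
            row["wilcoxon_p"] = np.nan
            row["tested"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def cross_class_contrast(
    calls: pd.DataFrame,
    rpkm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    tissue: str,
    class_a: str,
    sex_a: str,
    class_b: str,
    sex_b: str,
) -> float:
    """Wilcoxon rank-sum p for e.g. MB-gene male expression vs FB-gene female
    expression (the cross contrasts of the class summary figure)."""
    def sex_expr(sex: str) -> pd.Series:
        ss = [s for s in rpkm.columns
              if sample_meta.loc[s, "tissue"] == tissue and sample_meta.loc[s, "sex"] == sex]
        return np.log2(rpkm[ss] + 1).mean(axis=1)

    a = sex_expr(sex_a).reindex(calls.index[calls["category"] == class_a]).dropna()
    b = sex_expr(sex_b).reindex(calls.index[calls["category"] == class_b]).dropna()
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
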