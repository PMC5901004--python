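"""Synthetic data with known ground truth for the full pipeline.

Three generators share one configuration object:

* codon alignments for the fixed 5-taxon topology
  ``((S.viminalis,S.suchowensis),((P.tremula,P.tremuloides),P.trichocarpa))``,
  evolved root-to-tips under a mutate/accept codon process (candidate
  single-nucleotide changes accepted with relative weight 1 if synonymous and
  omega if nonsynonymous; stop codons rejected), with every accepted change
  recorded per branch;
* negative-binomially dispersed read counts for 3 male + 3 female individuals
  in two tissues, with sex-biased effects injected in the reproductive tissue
  (catkin) only;
* per-site, per-individual coverage and allele-count tables with segregating
  synonymous/nonsynonymous variants at known positions.

The mutate/accept process is chosen so that counting-based (NG86-style)
estimation is asymptotically calibrated: with ``ts_tv_ratio = 1`` candidate
changes are uniform over the three alternative bases, matching the
equal-weight site-counting convention.  Branch lengths are expected candidate
events per codon; the expected synonymous divergence on a branch is roughly
one third of its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .genetics import (
    AA_INT,
    AA_OF,
    IS_STOP,
    NEIGHBOR,
    SENSE_CODONS,
    STOP_CODONS,
    codon_index,
    codon_indices_to_seq,
    index_codon,
)
from .masking import CodonAlignment

FOCAL_TAXON = "S.viminalis"
TAXA = ("S.viminalis", "S.suchowensis", "P.tremula", "P.tremuloides", "P.trichocarpa")
ROOTED_NEWICK = "((S.viminalis,S.suchowensis),((P.tremula,P.tremuloides),P.trichocarpa));"
UNROOTED_NEWICK = "((S.viminalis,S.suchowensis),P.trichocarpa,(P.tremula,P.tremuloides));"

#: branch name (child node) -> parent node, in simulation (pre-)order
BRANCHES = {
    "salix_anc": "root",
    "S.viminalis": "salix_anc",
    "S.suchowensis": "salix_anc",
    "pop_anc": "root",
    "trem_anc": "pop_anc",
    "P.tremula": "trem_anc",
    "P.tremuloides": "trem_anc",
    "P.trichocarpa": "pop_anc",
}

#: path of branches from the root to each tip
TIP_PATHS = {
    "S.viminalis": ("salix_anc", "S.viminalis"),
    "S.suchowensis": ("salix_anc", "S.suchowensis"),
    "P.tremula": ("pop_anc", "trem_anc", "P.tremula"),
    "P.tremuloides": ("pop_anc", "trem_anc", "P.tremuloides"),
    "P.trichocarpa": ("pop_anc", "P.trichocarpa"),
}

# Default branch lengths (candidate events per codon).  The focal branch is
# set so expected synonymous divergence matches the study system's scale
# (d_S ~ 0.015); the other branches are deliberately shallower than the real
# willow/poplar split, keeping the simulation in the regime where parsimony
# ancestor misassignment is negligible (<0.1% of codons) and the counting
# estimator is calibrated.  Deeper trees are legal configurations but push
# the estimator outside its validated operating range.
DEFAULT_BRANCH_LENGTHS = {
    "salix_anc": 0.06,
    "S.viminalis": 0.045,   # focal: expected d_S ~ 0.015
    "S.suchowensis": 0.05,
    "pop_anc": 0.12,
    "trem_anc": 0.05,
    "P.tremula": 0.03,
    "P.tremuloides": 0.03,
    "P.trichocarpa": 0.07,
}


@dataclass
class SimulationConfig:
    """Study conditions for all three generators; see module docstring.

    omega_by_category and codon_bias_profile are keyed by the gene categories
    being emulated (default UB/MB/FB); branch_lengths are candidate
    single-nucleotide events per codon per branch.
    """

    seed: int = 0
    n_genes_per_category: int = 200
    gene_length_codons: int = 300
    omega_by_category: dict[str, float] = field(
        default_factory=lambda: {"UB": 0.22, "MB": 0.195, "FB": 0.21}
    )
    branch_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_LENGTHS)
    )
    ts_tv_ratio: float = 1.0
    sexbias_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    n_individuals_per_sex: int = 3
    # candidate-variant rate per CDS site; after the purifying thinning of
    # nonsynonymous candidates and the MAF filter, the realized synonymous
    # polymorphism rate lands near the study system's p_S ~ 0.01
    snp_rate_per_site: float = 0.02
    coverage_mean: float = 30.0
    codon_bias_profile: dict[str, float] = field(
        default_factory=lambda: {"UB": 1.35, "MB": 1.2, "FB": 1.35}
    )
    frac_nonrecombining: float = 0.02

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.omega_by_category.values()):
            raise ValueError("omega must be >= 0 for every category")
        if any(t < 0 for t in self.branch_lengths.values()):
            raise ValueError("branch lengths must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be > 0")
        if self.n_individuals_per_sex < 2:
            raise ValueError("need at least 2 individuals per sex")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts/tv ratio must be > 0")
        if any(w < 0 or not np.isfinite(w) for w in self.codon_bias_profile.values()):
            raise ValueError("codon bias weights must be finite and non-negative")
        if not (0 <= self.snp_rate_per_site < 1):
            raise ValueError("snp_rate_per_site must be in [0, 1)")
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")
        # saturation guard: expected focal-branch d_S ~ t/3 (see module docstring)
        t_focal = self.branch_lengths.get(FOCAL_TAXON, 0.0)
        if t_focal / 3.0 > 2.0:
            raise ValueError(
                f"focal branch length {t_focal} implies expected d_S > 2 (saturation)"
            )

    @property
    def categories(self) -> list[str]:
        return list(self.omega_by_category)

    def gene_ids(self) -> list[tuple[str, str]]:
        """Deterministic (gene id, category) list shared by all generators."""
        out = []
        k = 0
        for cat in self.categories:
            for _ in range(self.n_genes_per_category):
                k += 1
                out.append((f"g{k:05d}", cat))
        return out


@dataclass
class GroundTruth:
    """Everything the generators decided, for oracle-style checks."""

    categories: dict[str, str]
    root_sequences: dict[str, np.ndarray]
    substitutions: pd.DataFrame  # gene, branch, event, codon_index, from_codon, to_codon, synonymous
    gene_coords: pd.DataFrame    # gene, chrom, start, end
    snps: pd.DataFrame | None = None

    def focal_counts(self, gene: str) -> tuple[int, int]:
        """(true nonsynonymous, true synonymous) substitution counts on the
        focal (S. viminalis) branch."""
        sub = self.substitutions
        sel = sub[(sub["gene"] == gene) & (sub["branch"] == FOCAL_TAXON)]
        syn = int(sel["synonymous"].sum())
        return len(sel) - syn, syn


def _root_codon_probs(weight: float) -> np.ndarray:
    """Stationary codon probabilities: within each synonymous family the
    alphabetically first codon is 'preferred' and carries relative weight
    ``weight`` (>=1 means biased toward it); others weight 1."""
    fam: dict[int, list[str]] = {}
    for c in SENSE_CODONS:
        fam.setdefault(int(AA_INT[codon_index(c)]), []).append(c)
    w = np.zeros(64)
    for codons in fam.values():
        for j, c in enumerate(sorted(codons)):
            w[codon_index(c)] = weight if j == 0 else 1.0
    return w / w.sum()


def _evolve_branch(
    seq: list[int],
    t: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
) -> list[tuple[int, int, int, bool]]:
    """Mutate ``seq`` in place along one branch; return accepted events as
    (codon_index, from_codon, to_codon, synonymous)."""
    L = len(seq)
    n_att = rng.poisson(t * L)
    if n_att == 0:
        return []
    pos_codon = rng.integers(0, L, n_att)
    pos_in = rng.integers(0, 3, n_att)
    u_base = rng.random(n_att)
    u_acc = rng.random(n_att)
    p_ts = kappa / (kappa + 2.0)
    acc_scale = max(1.0, omega)
    aa = AA_INT
    neigh = NEIGHBOR
    events = []
    for j in range(n_att):
        ci = int(pos_codon[j])
        c = seq[ci]
        p = int(pos_in[j])
        b = (c >> (2 * (2 - p))) & 3
        u = u_base[j]
        if u < p_ts:
            nb = b ^ 2  # transition partner
        elif u < p_ts + (1 - p_ts) / 2:
            nb = b ^ 1
        else:
            nb = b ^ 3
        c2 = int(neigh[c, p, nb])
        if IS_STOP[c2]:
            continue
        syn = aa[c] == aa[c2]
        w = (1.0 if syn else omega) / acc_scale
        if u_acc[j] < w:
            seq[ci] = c2
            events.append((ci, c, c2, bool(syn)))
    return events


def simulate_ortholog_set(
    config: SimulationConfig,
) -> tuple[dict[str, CodonAlignment], GroundTruth]:
    """Evolve one codon alignment per gene on the fixed 5-taxon tree.

    Per gene, a root sequence is drawn from the category's stationary codon
    frequencies and evolved down every branch in pre-order; the focal
    (S. viminalis) branch uses the gene category's omega, all other branches
    the 'UB' omega.  Every accepted change is recorded in the ground truth,
    along with genomic coordinates placing a fraction of genes in the
    nonrecombining Z interval (3.5-8.8 Mbp) and the rest on autosomes.
    """
    rng = np.random.default_rng([config.seed, 0])
    L = config.gene_length_codons
    kappa = config.ts_tv_ratio
    omega_other = config.omega_by_category.get("UB", next(iter(config.omega_by_category.values())))
    probs = {cat: _root_codon_probs(w) for cat, w in config.codon_bias_profile.items()}
    default_probs = _root_codon_probs(1.0)

    alignments: dict[str, CodonAlignment] = {}
    categories: dict[str, str] = {}
    roots: dict[str, np.ndarray] = {}
    subs_rows = []
    coord_rows = []
    nrz_cursor, aut_cursor = 3_500_000, 1_000_000
    for gene, cat in config.gene_ids():
        categories[gene] = cat
        root = rng.choice(64, size=L, p=probs.get(cat, default_probs)).astype(np.int16)
        roots[gene] = root.copy()
        node_seqs: dict[str, list[int]] = {"root": list(map(int, root))}
        for branch, parent in BRANCHES.items():
            seq = list(node_seqs[parent])
            omega = (
                config.omega_by_category[cat] if branch == FOCAL_TAXON else omega_other
            )
            events = _evolve_branch(seq, config.branch_lengths[branch], omega, kappa, rng)
            node_seqs[branch] = seq
            for k, (ci, c_from, c_to, syn) in enumerate(events):
                subs_rows.append((gene, branch, k, ci, index_codon(c_from), index_codon(c_to), syn))
        alignments[gene] = CodonAlignment(
            gene,
            {t: codon_indices_to_seq(np.array(node_seqs[t])) for t in TAXA},
            gap_stripped=True,
        )
        # genomic placement: a small fraction inside the nonrecombining Z window
        if rng.random() < config.frac_nonrecombining:
            start = nrz_cursor
            nrz_cursor += 3 * L + 2000
            if nrz_cursor > 8_800_000 - 3 * L:
                nrz_cursor = 3_500_000  # wrap; interval is what matters, not uniqueness
            coord_rows.append((gene, "Z", start, start + 3 * L))
        else:
            coord_rows.append((gene, "chr1", aut_cursor, aut_cursor + 3 * L))
            aut_cursor += 3 * L + 2000
    substitutions = pd.DataFrame(
        subs_rows,
        columns=["gene", "branch", "event", "codon_index", "from_codon", "to_codon", "synonymous"],
    )
    coords = pd.DataFrame(coord_rows, columns=["gene", "chrom", "start", "end"])
    truth = GroundTruth(categories, roots, substitutions, coords)
    return alignments, truth


def replay_tip(truth: GroundTruth, gene: str, taxon: str) -> str:
    """Rebuild a tip sequence by replaying recorded substitutions from the
    root; must equal the simulated alignment sequence exactly."""
    seq = list(map(int, truth.root_sequences[gene]))
    sub = truth.substitutions
    for branch in TIP_PATHS[taxon]:
        sel = sub[(sub["gene"] == gene) & (sub["branch"] == branch)].sort_values("event")
        for _, row in sel.iterrows():
            ci = int(row["codon_index"])
            if index_codon(seq[ci]) != row["from_codon"]:
                raise AssertionError(
                    f"{gene}/{branch}: replay mismatch at codon {ci}"
                )
            seq[ci] = codon_index(row["to_codon"])
    return codon_indices_to_seq(np.array(seq))


def simulate_expression(config: SimulationConfig) -> ExpressionTable:
    """NB-dispersed counts for 2 tissues x 2 sexes x n individuals.

    MB genes get +sexbias_log2fc (log2) in catkin males, FB genes the same
    bias toward females; leaf carries no injected bias for any gene.  Library
    size factors vary moderately between samples.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = config.gene_ids()
    n_ind = config.n_individuals_per_sex
    samples, meta_rows = [], []
    for tissue in ("catkin", "leaf"):
        for sex in ("M", "F"):
            for i in range(1, n_ind + 1):
                sid = f"{tissue}_{sex}{i}"
                samples.append(sid)
                meta_rows.append((sid, sex, tissue, f"{sex}{i}"))
    meta = pd.DataFrame(meta_rows, columns=["sample", "sex", "tissue", "individual"]).set_index("sample")

    base = np.exp(rng.normal(4.0, 1.2, size=len(genes)))  # per-gene baseline mean count
    libfac = rng.uniform(0.8, 1.25, size=len(samples))
    phi = config.nb_dispersion
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for gi, (gene, cat) in enumerate(genes):
        for si, sid in enumerate(samples):
            tissue = meta.loc[sid, "tissue"]
            sex = meta.loc[sid, "sex"]
            mu = base[gi] * libfac[si]
            if tissue == "catkin":
                if cat == "MB":
                    mu *= 2 ** (config.sexbias_log2fc / 2 * (1 if sex == "M" else -1))
                elif cat == "FB":
                    mu *= 2 ** (config.sexbias_log2fc / 2 * (1 if sex == "F" else -1))
            r = 1.0 / phi
            counts[gi, si] = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=[g for g, _ in genes], columns=samples)
    df.index.name = "gene"
    lengths = pd.Series(3 * config.gene_length_codons, index=df.index, name="length_bp")
    return ExpressionTable(df, lengths, meta)


def simulate_site_table(
    alignments: dict[str, CodonAlignment],
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-site, per-individual coverage and allele counts for the focal
    species' individuals, with injected segregating variants.

    Candidate variant sites arise at ``snp_rate_per_site``; a nonsynonymous
    candidate survives with probability omega of its gene's category
    (purifying selection on segregating variation), so the realized rate is
    lower than the candidate rate.  Alternative allele counts among the 2n
    chromosomes follow the neutral 1/k frequency spectrum; per-individual
    coverage is Poisson and read counts split binomially by allele dosage.
    The injected variants are appended to ``truth.snps``.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_ind = config.n_individuals_per_sex * 2
    individuals = [f"M{i+1}" for i in range(config.n_individuals_per_sex)] + [
        f"F{i+1}" for i in range(config.n_individuals_per_sex)
    ]
    sexes = ["M"] * config.n_individuals_per_sex + ["F"] * config.n_individuals_per_sex
    chroms = 2 * n_ind
    k_support = np.arange(1, chroms)
    sfs = (1.0 / k_support) / (1.0 / k_support).sum()

    rows = []
    snp_rows = []
    for gene, aln in alignments.items():
        seq = aln.seqs[FOCAL_TAXON].upper()
        L_nt = len(seq)
        omega = config.omega_by_category[truth.categories[gene]]
        coverage = rng.poisson(config.coverage_mean, size=(L_nt, n_ind))
        alt_counts = np.zeros((L_nt, n_ind), dtype=np.int64)
        alt_base = np.array(["."] * L_nt, dtype=object)
        n_cand = rng.binomial(L_nt, config.snp_rate_per_site)
        cand_sites = rng.choice(L_nt, size=n_cand, replace=False)
        for site in sorted(map(int, cand_sites)):
            ci, p = divmod(site, 3)
            cod = seq[3 * ci: 3 * ci + 3]
            if any(ch not in "ACGT" for ch in cod):
                continue
            alts = [b for b in "ACGT" if b != cod[p]]
            alts = [b for b in alts if (cod[:p] + b + cod[p + 1:]) not in STOP_CODONS]
            if not alts:
                continue
            alt = alts[rng.integers(0, len(alts))]
            alt_cod = cod[:p] + alt + cod[p + 1:]
            syn = AA_OF[cod] == AA_OF[alt_cod]
            if not syn and rng.random() >= omega:
                continue  # purged by selection
            k = int(rng.choice(k_support, p=sfs))
            carriers = rng.permutation(chroms)[:k]
            dosage = np.bincount(carriers // 2, minlength=n_ind)
            a = rng.binomial(coverage[site], dosage / 2.0)
            alt_counts[site] = a
            alt_base[site] = alt
            snp_rows.append((gene, ci + 1, p + 1, cod[p], alt, bool(syn), k / chroms))
        for ii, ind in enumerate(individuals):
            rows.append(
                pd.DataFrame(
                    {
                        "gene": gene,
                        "codon_index": np.arange(L_nt) // 3 + 1,
                        "codon_pos": np.arange(L_nt) % 3 + 1,
                        "site": np.arange(1, L_nt + 1),
                        "individual": ind,
                        "sex": sexes[ii],
                        "coverage": coverage[:, ii],
                        "ref_count": coverage[:, ii] - alt_counts[:, ii],
                        "alt_count": alt_counts[:, ii],
                        "alt_base": alt_base,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    snps = pd.DataFrame(
        snp_rows,
        columns=["gene", "codon_index", "codon_pos", "ref_base", "alt_base", "synonymous", "true_af"],
    )
    truth.snps = snps if truth.snps is None else pd.concat([truth.snps, snps], ignore_index=True)
    return table


def simulate_null_branch_counts(
    rng: np.random.Generator,
    n_genes: int,
    length_codons: int = 300,
    omega: float = 0.2,
    ds_level: float = 0.015,
    nonsyn_site_frac: float = 0.75,
) -> pd.DataFrame:
    """Exchangeable gene-level substitution counts for calibration studies.

    Draws per-gene (N, S, D_N, D_S) from a common Poisson model: every gene
    shares the same omega and synonymous rate, so any two groups drawn from it
    satisfy the permutation-test null.
    """
    total = 3 * length_codons
    N = np.full(n_genes, nonsyn_site_frac * total)
    S = total - N
    D_S = rng.poisson(S * ds_level)
    D_N = rng.poisson(N * ds_level * omega)
    return pd.DataFrame({"N": N, "S": S, "D_N": D_N, "D_S": D_S},
                        index=[f"n{i:05d}" for i in range(n_genes)])
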