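"""Shared configuration and paths for the numbered analysis scripts.

Heavy intermediates (alignments, site tables) go under scratch/; only compact
summary tables land in results/.
"""

from pathlib import Path

from salixevol.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

#: the synthetic study: three categories at Table-1-like omegas, sex-biased
#: expression in catkin only, weaker codon bias for male-biased genes
STUDY = SimulationConfig(
    seed=20180122,
    n_genes_per_category=100,
    gene_length_codons=400,
    codon_bias_profile={"UB": 1.6, "MB": 1.2, "FB": 1.6},
)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
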