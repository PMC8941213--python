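"""Shared paths and the study configuration for the analysis scripts.

All steps read and write under scratch/analysis/ so intermediate data can
be regenerated at will; summary tables each step prints are its findings.
"""

from pathlib import Path

from metaprot import SimConfig

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "analysis"

SIM_DIR = OUT / "sim"
GROUPS_TSV = OUT / "protein_groups.tsv"
MATRIX_TSV = OUT / "quant_matrix.tsv"
RESULTS_TSV = OUT / "differential_results.tsv"

# The emulated study: 8 healthy vs 10 UC biological replicates, a database
# of near-duplicate protein families, 30 planted differential groups at a
# 4-fold (log2 = 2) effect.
STUDY_CONFIG = SimConfig(seed=2021)


def outdir() -> Path:
    OUT.mkdir(parents=True, exist_ok=True)
    return OUT
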