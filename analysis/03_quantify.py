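"""Build the group x sample intensity matrix: match-between-runs transfer,
shared-peptide exclusion, the three-rule missing-value filter, and the
calibrated glog normalization."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from metaprot import quant
from metaprot.cluster import read_groups_tsv
from metaprot.simulate import read_psm_tables
from common import GROUPS_TSV, MATRIX_TSV, SIM_DIR, outdir


def main() -> None:
    outdir()
    psms = read_psm_tables(SIM_DIR / "psms")
    groups = read_groups_tsv(GROUPS_TSV)
    cohorts = (pd.read_csv(SIM_DIR / "samples.tsv", sep="\t")
               .set_index("sample")["cohort"])

    before = (psms["peptide"].str.len() > 0).sum()
    psms = quant.match_between_runs(psms, ppm_tol=10, rt_window_min=15)
    transferred = int(psms["mbr"].sum())
    pep_map = quant.build_peptide_group_map(psms, groups)
    n_shared = int(pep_map["shared"].sum())

    matrix = quant.aggregate_intensities(psms, pep_map, cohorts)
    n_raw = matrix.values.shape[0]
    matrix = quant.filter_missing(matrix, min_nonnull=4)
    n_kept = matrix.values.shape[0]
    matrix = quant.normalize_glog(matrix)
    quant.write_matrix(matrix, MATRIX_TSV)
    quant.peptide_intensity_table(psms, pep_map).to_csv(
        MATRIX_TSV.with_name("peptide_intensities.tsv"), sep="\t",
        index=False)

    print(f"{before} identified PSMs; match-between-runs transferred "
          f"{transferred} identifications (10 ppm, 15 min)")
    print(f"{len(pep_map)} peptides mapped; {n_shared} shared across "
          f"groups and excluded from quantification")
    print(f"{n_raw} quantified groups; {n_kept} pass the missing-value "
          f"filter ({n_raw - n_kept} removed)")
    print(f"wrote normalized matrix {MATRIX_TSV}")


if __name__ == "__main__":
    main()
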